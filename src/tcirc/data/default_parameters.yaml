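# Default mouse parameterization of the T cell recirculation model.
# mu15ex has no published value; 0.064 1/h (= mu13ex) is the package default,
# calibrated against the published CCR7-fraction AUC scan (docs/methods.md).
EC50_pro: 1000000.0
V_blood: 2.15
V_inf_thymus: 3130.0
V_liver: 1.93
V_ln: 0.113
V_lung: 0.204
V_regln: 0.113
V_spleen: 0.127
Vmax_pro: 12281.0
f_ccr7: 0.75
f_ccr7_ex: 0.75
k_apo: 0.004
k_deg: 0.84
kdel3: 3.55
kdel4: 72.06
kdel5: 3.55
kdel6: 3.55
koff3: 0.17
koff4: 0.63
koff5: 0.2
koff6: 0.077
mass_liver: 1.013
mass_lung: 0.13
mass_spleen: 0.106
mu12: 2.66
mu12ex: 3.99
mu13: 0.92
mu13ex: 0.064
mu14: 1.05
mu15: 2.4
mu15ex: 0.064
mu16: 0.048
mu16ex: 8.6e-05
mu21: 2.31
mu25: 0.51
mu31: 0.17
mu41: 0.63
mu45: 0.54
mu51: 0.2
mu65: 0.077
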