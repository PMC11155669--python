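# tcirc — T cell recirculation kinetics in mouse

`tcirc` is a physiologically-based compartmental model of T cell
trafficking in the mouse, built for preclinical cellular-kinetics work on
adoptive T cell therapies (TIL, TCR-engineered, CAR-T).  It answers two
coupled questions with one 16-state ODE system:

* **Homeostasis** — where do endogenous T cells sit at steady state?
  Thymic output, CCR7-gated lymph-node entry through high endothelial
  venules, afferent-lymphatic routing from lung and liver, splenic
  homeostatic proliferation (Michaelis–Menten), and blood apoptosis
  balance into organ-specific steady-state concentrations.
* **Cellular PK** — where do intravenously infused T cells go?  A bolus
  into blood redistributes through the same anatomy with its own entry
  rates, lung degradation, and intra-organ delay pools that capture the
  prolonged residence of transferred cells in spleen, liver and lymph
  nodes.  The infused subsystem is linear, so exposure scales exactly
  with dose.

The package provides the ODE core (with an exact matrix-exponential
propagator for the infused subsystem), dosing scenarios with
non-compartmental metrics (Cmax, Tmax, trapezoid AUC, trough, and the
biodistribution coefficient BC = AUC_organ/AUC_blood), two-stage
maximum-likelihood calibration with log-normal errors and pharmacometric
diagnostics (RSE, WRES), LHS/PRCC global and fold-change local
sensitivity analyses, and seeded synthetic-data generators that emulate
the calibration inputs.  See `docs/methods.md` for the model and all
numerical choices.

## Worked example

```python
from tcirc import ParameterSet, Scenario, endogenous_steady_state, simulate, pk_metrics

params = ParameterSet()          # packaged mouse calibration

ss = endogenous_steady_state(params)
print(f"spleen {ss[2] / params.physiology.V_spleen:.3g} cells/ml")
print(f"blood  {ss[0] / params.physiology.V_blood:.3g} cells/ml")

traj = simulate(Scenario(dose=20e6, f_ccr7_ex=0.9, horizon=360.0), params)
m = pk_metrics(traj)
print(f"spleen AUC {m.loc['spleen', 'auc']:.4g} cells/ml*h, "
      f"BC {m.loc['spleen', 'bc']:.1f}")
```

prints

```
spleen 1.59e+08 cells/ml
blood  1.72e+06 cells/ml
spleen AUC 6.881e+09 cells/ml*h, BC 110.1
```

i.e. endogenous T cells concentrate ~100-fold in lymphoid tissue relative
to blood, and a 20-million-cell infusion that is 90% CCR7+ accumulates a
spleen exposure ~110× its blood exposure over 15 days.

The same operations are scriptable from the shell:

```bash
tcirc simulate --dose 20e6 --fccr7ex 0.75 --horizon 360 --out traj.csv
tcirc scan-dose --out dose_scan.csv
tcirc scan-ccr7 --dose 20e6 --out ccr7_scan.csv
tcirc sa-global --n 1000 --repeats 20 --seed 1 --out prcc.csv
tcirc make-fixtures --seed 1 --outdir fixtures/
tcirc reproduce-paper        # desk-scale reference table, pass/fail
```

The `analysis/` directory holds the numbered study drivers
(steady state → calibration → validation → sensitivity → scenario scans);
each writes tidy tables under `results/` and prints what it found.

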