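#!/usr/bin/env python
"""Global PRCC and local fold-change sensitivity of the model.

Global: endogenous steady-state concentrations vs [0.5x, 2x] parameter
ranges, Latin hypercube sampling, desk scale 1000 samples x 20 repeats
(the full-scale published analysis used 5000 x 200; pass --paper-scale
to the CLI for that).  Local: x0.5 / x2 one-at-a-time perturbations of
the infused-cell kinetic parameters, effect on per-organ AUC and Cmax.
"""

from pathlib import Path

from tcirc import GlobalSAConfig, ParameterSet, default_global_bounds, local_sensitivity
from tcirc.sensitivity import prcc_global

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

params = ParameterSet()
cfg = GlobalSAConfig(bounds=default_global_bounds(params),
                     n_samples=1000, n_repeats=20, seed=1)
prcc_df = prcc_global(params, cfg)
prcc_df.to_csv(OUT / "prcc.csv", index=False)

g = prcc_df.set_index(["parameter", "output"])
r13 = abs(g.loc[("mu13", "spleen"), "prcc"]) / abs(g.loc[("mu13", "blood"), "prcc"])
r31 = abs(g.loc[("mu31", "spleen"), "prcc"]) / abs(g.loc[("mu31", "blood"), "prcc"])
print("Global sensitivity (PRCC, 1000 x 20):")
print(f"  spleen-vs-blood impact ratio: mu13 {r13:.1f}x, mu31 {r31:.1f}x "
      f"(published: about 4x)")
for par in ("V_inf_thymus", "k_apo", "Vmax_pro"):
    vals = {o: g.loc[(par, o), "prcc"] for o in ("blood", "spleen", "ln")}
    print(f"  {par}: " + ", ".join(f"{o} {v:+.2f}" for o, v in vals.items()))

local_df = local_sensitivity(params, dose=20e6)
local_df.to_csv(OUT / "local_sensitivity.csv", index=False)
l = local_df.set_index(["parameter", "factor", "organ", "metric"])
print("Local sensitivity (x2 perturbation, relative AUC change):")
for par, organ in (("mu13ex", "spleen"), ("mu14", "liver"), ("mu16ex", "regln"),
                   ("kdel3", "spleen"), ("koff3", "spleen"), ("mu12ex", "blood")):
    print(f"  {par:>7} -> {organ:>6}: {l.loc[(par, 2.0, organ, 'auc'), 'rel_change']:+.2f}")
print(f"Wrote {OUT / 'prcc.csv'}, {OUT / 'local_sensitivity.csv'}")
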