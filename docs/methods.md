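# Methods

## Model

`tcirc` implements a physiologically-based compartmental model of T cell
recirculation in the mouse.  Sixteen state variables (cell numbers) track
two populations that do not interact:

* **Endogenous T cells** in six anatomical compartments — blood, lungs,
  spleen, liver, a generalized lymph-node (LN) compartment and a regional
  LN compartment.  Sources: thymic output into blood at a constant rate
  `V_inf_thymus` (cells/h) and antigen-independent homeostatic
  proliferation in the spleen with a Michaelis–Menten rate
  `Vmax_pro * T_spleen / (EC50_pro + T_spleen)`.  The single sink is
  first-order apoptosis in blood (`k_apo`).
* **Infused (exogenous) T cells**: an intravenous bolus into blood, the
  same six compartments plus four intra-organ *delay pools* (spleen,
  liver, both LN compartments) that exchange linearly with the organ's
  free pool (`kdel*` in, `koff*` out) and reproduce the prolonged
  residence of transferred cells in lymphoid organs and liver.  Sinks:
  blood apoptosis (shared `k_apo`) and first-order degradation in the
  lungs (`k_deg`), representing clearance by alveolar macrophages.
  Infused cells have no proliferation source: mechanisms of
  antigen-driven activation are out of scope, so the subsystem is linear
  and every infused-cell trajectory scales exactly with dose.

All migration is first order.  Entry into the two LN compartments through
high endothelial venules is restricted to CCR7+ cells: the blood→LN rates
are multiplied by the CCR7+ fraction (`f_ccr7` endogenous, `f_ccr7_ex`
infused) and the blood→lung/liver rates by its complement.  Spleen entry
is *not* CCR7-gated.  Lung- and liver-exiting cells also reach the
generalized LN compartment through afferent lymphatics (`mu25`, `mu45`);
regional LNs drain into the generalized compartment (`mu65`), which
returns cells to blood at the thoracic-duct rate (`mu51`).
Organ-to-blood rates are shared between the two populations; blood-to-organ
entry rates are population specific (`mu12ex`, `mu13ex`, `mu15ex`,
`mu16ex`), reflecting altered trafficking of ex-vivo-manufactured cells.

Observables are concentrations (cells/ml): pool / organ volume, where the
infused-cell observable adds the delay pool to the free pool (a
radiolabel cannot distinguish the two).  Units throughout: cells, hours,
ml; per-gram assay data convert through organ mass at an assumed tissue
density of 1 g/ml.

## Parameters

The packaged defaults (`tcirc/data/default_parameters.yaml`) are the
published mouse calibration: migration rate constants of order 0.05–4 /h,
`k_apo` = 0.004 /h, `k_deg` = 0.84 /h, delay constants `kdel3` = `kdel5` =
`kdel6` = 3.55 /h, `kdel4` = 72.06 /h with exits tied to the organ-exit
rates (`koff3` = `mu31` etc.), thymic output 3.13e3 cells/h,
`Vmax_pro` = 12 281 cells/h (the source table prints no unit; cells/h is
the only choice dimensionally consistent with its equation),
`EC50_pro` = 1e6 cells, and CCR7+ fractions 0.75.

Two constants have no published value:

* **`mu15ex`** (infused cells, blood → generalized LNs).  The package
  default is 0.064 /h, equal to the printed `mu13ex`.  This was fixed by a
  one-dimensional calibration against the published CCR7-fraction scan's
  generalized-LN AUC column (best fit 0.062 /h, statistically
  indistinguishable from 0.064); loading a parameter file that omits it
  triggers an explicit warning naming the default.  It is also estimated
  in stage 2 of the calibration, where it is the least identifiable of
  the six free parameters (RSE ≈ 35–45% on a single synthetic dataset).
* **`V_regln`** (regional LN compartment volume), defaulting to `V_ln`
  (0.113 ml).  Regional-LN concentrations scale inversely with it.

## Numerics

* **Integration**: `scipy.integrate.solve_ivp` with LSODA, rtol 1e-8,
  atol 1e-3 cells.  Metrics are read off a dense grid (7201 points per
  horizon by default); halving the step changes trapezoid AUCs by <0.1%.
* **Infused-cell fast path**: the infused subsystem is linear and time
  invariant, so the package also propagates it exactly with matrix
  exponentials (`propagate_exogenous`).  This is the computational route
  for stage-2 calibration and local sensitivity, and it cross-checks the
  stiff solver in the tests (<1e-6 relative disagreement).
* **Endogenous steady state**: the six equilibrium equations reduce
  exactly to a scalar root problem in the blood pool (closed forms for
  the one-in/one-out pools, a quadratic for the spleen, and the
  whole-body balance `V_inf_thymus + proliferation = k_apo * T_blood`),
  solved with Brent's method and cross-checked against 80,000-h
  integration.  With zero thymic output the zero state is always an
  equilibrium; the solver returns the positive
  proliferation-sustained equilibrium when one exists, the zero state
  otherwise, and raises a diagnostic when production cannot be balanced
  (e.g. `k_apo` = 0 with positive sources).
* **Bolus handling**: `Tex_blood(0+) = dose`; blood Cmax therefore equals
  `dose / V_blood` exactly.  Infusions of finite duration are not
  modelled.
* **AUC window**: the published scan tables do not state their
  integration horizon; the package default is 0–360 h (the horizon at
  which the published lung troughs are quoted), exposed as an argument.

## Calibration

Fixed-effects maximum likelihood with log-normal residuals (median = model
prediction; per-record `sigma = sqrt(log(1+cv^2))`, or a shared fixed
sigma).  Optimization is multi-start L-BFGS-B on log-parameters within
±100-fold box bounds; starts are jittered log-uniformly within ±10-fold of
the nominal values.  Stage 1 fits the endogenous parameters
(`mu12..mu16`, `mu25`, `mu45`, `k_apo`, `Vmax_pro`) to steady-state
concentrations, with the organ-exit rates held at their half-life-derived
values and an optional soft penalty pulling the afferent share of LN
inflow toward 10%.  Stage 2 freezes stage 1 and fits `mu12ex`, `mu13ex`,
`mu15ex`, `mu16ex`, `kdel3` (tied to `kdel5`, `kdel6`) and `kdel4` to
bolus kinetic curves.  Whether thymic output is fitted or fixed is a
caller choice (fixed by default); both modes are supported by passing a
custom free-parameter list.

Diagnostics: RSE (%) from a central-finite-difference Hessian of the
negative log-likelihood on the log scale (the inverse-information
diagonal is then directly the squared relative error; non-positive
curvature flags a parameter as not identifiable), with the conventional
<50% acceptability bar; WRES = (y − E[y]) / sd[y] on the observation
scale using the closed-form log-normal mean and variance, with a seeded
simulation-based option.  The observation variance matrix is assumed
diagonal.

## Synthetic data

The generators emulate the statistical structure of the calibration
inputs, not any particular published dataset: one steady-state record per
organ (blood, lung, spleen, liver, generalized LN); bolus kinetic curves
at {0.5, 1, 2, 4, 8, 24, 48, 72} h in blood, lung, spleen, liver and
regional LN with cv = 20% log-normal noise (the sources report figure
error bars only, so the cv is a stand-in); a default kinetic dose of
20e6 cells (the original transfer experiment's dose was not reported; the
published spleen peak ~12.6e6 cells/ml at 9 h is consistent with ~20e6
under this model, which computes 12.8e6 at 9.1 h); and a thymectomy decay
series of the spleen over 2000 h at cv = 10%.  Per-gram units and the
empirical assay scale factor ω (published average 2.7) are applied on
request and inverted by `apply_omega_scaling` / `per_gram_to_cells_per_ml`.

What passing tests on these data do **not** show: recovery from the real
digitized measurements (unavailable), inter-animal variability (no random
effects are simulated or fitted), assay-specific noise physics
(radiolabel decay, PET resolution), or any interaction between the two
cell populations.

## Sensitivity analyses

Global: Latin hypercube samples (scipy's `qmc.LatinHypercube`) of the
endogenous parameters within [0.5×, 2×] of their defaults (the published
description of the bounds is ambiguous; this reading is documented as an
interpretation; fraction upper bounds are clipped at 1).  Output =
steady-state concentration per organ, computed by the exact root solve
rather than 80,000-h integration (equivalent and ~10^3× faster).  PRCC by
the rank-residual method: rank-transform everything, regress parameter
and output ranks on the remaining parameters, correlate the residuals.
Desk-scale default 1000 samples × 20 repeats (published full scale:
5000 × 200, available via `--paper-scale`); the repeat standard deviation
/ sqrt(repeats) is reported as the standard error.  Proliferation
parameters are sampled within the same bound scheme as the rest.

Local: one-at-a-time ×0.5 / ×2 perturbations of the infused-cell kinetic
parameters; effect = relative change of per-organ infused-cell AUC and
Cmax over 0–360 h, computed with the exact linear propagator.  Perturbing
endogenous-only parameters (e.g. thymic output) changes nothing, by the
uncoupling of the populations.

## Known limitations

* The printed regional-LN parameters are internally inconsistent with the
  published regional-LN outputs: with the tabulated blood→regional-LN
  entry rate (8.6e-5 /h), total lifetime inflow for a 20e6-cell dose is
  bounded by ~3.6e4 cells, so the published regional-LN peak
  (0.5e6 cells/ml ≈ 5.6e4 cells) and AUC column are unreachable by
  roughly an order of magnitude.  The package follows the tabulated rate;
  regional-LN outputs should be treated as qualitative.
* The model treats the two populations as fully uncoupled; competition
  for niches/cytokines and antigen-driven expansion are out of scope.
* CD4/CD8 subsets are lumped; human scaling and tumor compartments are
  not included.
* A single-LN variant (no regional compartment) can be emulated by
  setting `mu16`/`mu16ex` to 0, but is not separately maintained — the
  published model selection discarded it.

## Desk-scale choices

Test and analysis problem sizes are the package's own defaults: 1000 × 20
PRCC, 20-seed recovery experiments with 3 optimizer starts, 100 randomized
draws for the invariant suites, 200 × 40 residuals for the WRES coverage
check (chosen so the ±2 coverage of the log-normal error model, ~95.7%,
is resolved with a comfortable statistical margin against the 95%
criterion).  All randomness is seeded; identical seeds give bit-identical
outputs.
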