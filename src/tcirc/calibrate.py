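"""Two-stage maximum-likelihood calibration and fit diagnostics.

Stage 1 fits the endogenous migration/homeostasis parameters to
steady-state tissue concentrations; stage 2 freezes those and fits the
infused-cell entry rates and delay constants to bolus kinetic curves.
Observations are modelled as log-normal around the model median
(fixed-effects only; no inter-animal random effects).  Diagnostics follow
pharmacometric practice: relative standard errors (RSE, %) from the
inverse observed information, and weighted residuals
WRES = (y - E[y]) / sd[y] on the observation scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import model
from .parameters import ParameterSet
from .synthetic import validate_observations

__all__ = [
    "ErrorModel",
    "FitResult",
    "predictions",
    "log_likelihood",
    "fit_ml",
    "fit_stage1_endogenous",
    "fit_stage2_exogenous",
    "relative_standard_errors",
    "weighted_residuals",
    "apply_omega_scaling",
    "STAGE1_FREE",
    "STAGE2_FREE",
]

#: default free parameters of the two stages
STAGE1_FREE = ("mu12", "mu13", "mu14", "mu15", "mu16", "mu25", "mu45", "k_apo", "Vmax_pro")
STAGE2_FREE = ("mu12ex", "mu13ex", "mu15ex", "mu16ex", "kdel3", "kdel4")

#: acceptability threshold on RSE (%) used for model-selection flags
RSE_ACCEPTABLE_PCT = 50.0


@dataclass(frozen=True)
class ErrorModel:
    """Log-normal residual error.

    sigma : log-scale standard deviation shared across records; when None,
        each record's own coefficient of variation sets its sigma via
        sigma = sqrt(log(1 + cv^2)).
    """

    sigma: float | None = None

    def __post_init__(self):
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    def sigmas(self, data: pd.DataFrame) -> np.ndarray:
        if self.sigma is not None:
            return np.full(len(data), float(self.sigma))
        cv = data["cv"].to_numpy(dtype=float)
        if np.any(~(cv > 0)):
            raise ValueError("all records need cv > 0 when ErrorModel.sigma is None")
        return np.sqrt(np.log1p(cv ** 2))


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    params: ParameterSet                 # full set at the optimum
    estimates: dict[str, float]          # fitted values of the free parameters
    free: tuple[str, ...]
    loglik: float
    data: pd.DataFrame
    error: ErrorModel
    fixed: dict[str, float]              # values held fixed during the fit
    converged: bool
    n_starts: int
    tie_lymphoid_delays: bool = False
    rse: dict[str, float] | None = None  # filled by relative_standard_errors
    at_bounds: list = field(default_factory=list)  # parameters pinned at a box bound
    start_logliks: list = field(default_factory=list)

    @property
    def rse_acceptable(self) -> bool | None:
        """True when every fitted parameter has RSE below the 50% bar."""
        if self.rse is None:
            return None
        vals = [v for v in self.rse.values()]
        if any(np.isnan(v) for v in vals):
            return False
        return all(v < RSE_ACCEPTABLE_PCT for v in vals)


# ---------------------------------------------------------------------------
# predictions and likelihood
# ---------------------------------------------------------------------------

def predictions(params: ParameterSet, data: pd.DataFrame) -> np.ndarray:
    """Model median (cells/ml) for every observation record.

    Protocols: 'steady-state' rows are evaluated at the endogenous
    equilibrium; 'bolus' rows by exact propagation of the infused-cell
    subsystem for the row's dose; 'thymectomy' rows by integrating the
    endogenous system from its steady state with thymic output removed.
    Values must be on the cells/ml scale (convert per-gram / ω-scaled data
    first).
    """
    validate_observations(data)
    if (data["unit"] != "cells_per_ml").any():
        raise ValueError("predictions require cells/ml records; convert assay units first")
    pred = np.full(len(data), np.nan)
    pos = {idx: i for i, idx in enumerate(data.index)}

    ss_mask = data["protocol"] == "steady-state"
    if ss_mask.any():
        ss = model.endogenous_steady_state(params)
        conc = model.observed_concentrations(ss[:, None], params, "endogenous")
        for idx, row in data[ss_mask].iterrows():
            pred[pos[idx]] = conc[row["organ"]][0]

    bolus = data[data["protocol"] == "bolus"]
    for dose, grp in bolus.groupby("dose"):
        times = np.sort(grp["time_h"].unique())
        pools = model.propagate_exogenous(params, float(dose), times)
        full = np.zeros((model.N_STATES, times.size))
        full[6:16] = pools.T
        conc = model.observed_concentrations(full, params, "exogenous")
        tindex = {t: j for j, t in enumerate(times)}
        for idx, row in grp.iterrows():
            pred[pos[idx]] = conc[row["organ"]][tindex[row["time_h"]]]

    thx = data[data["protocol"] == "thymectomy"]
    if len(thx):
        y0 = model.endogenous_steady_state(params)
        p0 = params.replace(V_inf_thymus=0.0)
        times = np.sort(thx["time_h"].unique())
        t_eval = times if times[0] > 0 else times
        sol = model.integrate(p0, y0, (0.0, float(times[-1])), t_eval=t_eval,
                              rtol=1e-8, atol=1e-3)
        conc = model.observed_concentrations(sol.y, p0, "endogenous")
        tindex = {t: j for j, t in enumerate(sol.t)}
        for idx, row in thx.iterrows():
            pred[pos[idx]] = conc[row["organ"]][tindex[row["time_h"]]]

    if np.isnan(pred).any():
        bad = data.loc[np.isnan(pred[[pos[i] for i in data.index]]), "protocol"].unique()
        raise ValueError(f"unhandled protocol(s) in observation table: {list(bad)}")
    return pred


def log_likelihood(params: ParameterSet, data: pd.DataFrame,
                   error: ErrorModel = ErrorModel()) -> float:
    """Log-normal log-likelihood of the data given the model median.

    Raises ``ValueError`` on nonpositive predictions (log-normal density
    undefined there).
    """
    pred = predictions(params, data)
    if np.any(pred <= 0):
        raise ValueError("model prediction <= 0 at an observation; log-normal undefined")
    y = data["value"].to_numpy(dtype=float)
    sig = error.sigmas(data)
    z = (np.log(y) - np.log(pred)) / sig
    return float(np.sum(-np.log(y * sig * np.sqrt(2 * np.pi)) - 0.5 * z ** 2))


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _afferent_fraction(params: ParameterSet) -> float:
    """Share of LN inflow arriving via afferent lymphatics (vs HEVs) at the
    endogenous steady state."""
    ss = model.endogenous_steady_state(params)
    Tb, lung, liver = ss[0], ss[1], ss[3]
    afferent = params.mu25 * lung + params.mu45 * liver
    hev = params.f_ccr7 * (params.mu15 + params.mu16) * Tb
    total = afferent + hev
    return afferent / total if total > 0 else np.nan


def _apply_free(base: ParameterSet, free: tuple[str, ...], log_theta: np.ndarray,
                tie_lymphoid_delays: bool) -> ParameterSet:
    upd = {name: float(np.exp(v)) for name, v in zip(free, log_theta)}
    if tie_lymphoid_delays and "kdel3" in upd:
        upd["kdel5"] = upd["kdel3"]
        upd["kdel6"] = upd["kdel3"]
    return base.replace(**upd)


def fit_ml(data: pd.DataFrame, base_params: ParameterSet, free,
           *, error: ErrorModel = ErrorModel(), n_starts: int = 5, seed: int = 0,
           bounds_fold: float = 100.0, start_fold: float = 10.0,
           tie_lymphoid_delays: bool = False,
           afferent_penalty_weight: float = 0.0,
           afferent_target: float = 0.10,
           maxiter: int = 300) -> FitResult:
    """Multi-start local maximization of the log-likelihood.

    Free parameters are optimized on the log scale within ``bounds_fold``
    of their starting values; starts are jittered log-uniformly within
    ``start_fold``.  ``tie_lymphoid_delays`` enforces kdel5 = kdel6 = kdel3
    (the published convention for the lymphoid delay constants).  The
    optional soft penalty pulls the afferent share of LN inflow toward
    ``afferent_target`` at the endogenous steady state.
    """
    free = tuple(free)
    validate_observations(data)
    theta0 = np.array([np.log(getattr(base_params, n)) for n in free])
    if not np.all(np.isfinite(theta0)):
        raise ValueError("free parameters must start strictly positive")
    lb, ub = theta0 - np.log(bounds_fold), theta0 + np.log(bounds_fold)
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        try:
            p = _apply_free(base_params, free, x, tie_lymphoid_delays)
            ll = log_likelihood(p, data, error)
        except (ValueError, model.SteadyStateError, model.SolverError):
            return 1e12
        pen = 0.0
        if afferent_penalty_weight > 0:
            pen = afferent_penalty_weight * (_afferent_fraction(p) - afferent_target) ** 2
        return -ll + pen

    best = None
    start_lls = []
    for k in range(n_starts):
        x0 = theta0 if k == 0 else theta0 + rng.uniform(
            -np.log(start_fold), np.log(start_fold), size=len(free))
        x0 = np.clip(x0, lb, ub)
        res = minimize(objective, x0, method="L-BFGS-B",
                       bounds=list(zip(lb, ub)), options={"maxiter": maxiter})
        start_lls.append(-float(res.fun))
        if best is None or res.fun < best.fun:
            best = res

    p_opt = _apply_free(base_params, free, best.x, tie_lymphoid_delays)
    fixed = {k: v for k, v in base_params.as_flat_dict().items() if k not in free}
    at_bounds = [n for n, x, lo, hi in zip(free, best.x, lb, ub)
                 if x - lo < 1e-6 or hi - x < 1e-6]
    return FitResult(
        params=p_opt,
        estimates={n: float(np.exp(v)) for n, v in zip(free, best.x)},
        free=free,
        loglik=float(log_likelihood(p_opt, data, error)),
        data=data, error=error, fixed=fixed,
        converged=bool(best.success or best.fun < 1e11),
        n_starts=n_starts, tie_lymphoid_delays=tie_lymphoid_delays,
        at_bounds=at_bounds, start_logliks=start_lls,
    )


def fit_stage1_endogenous(data: pd.DataFrame, params: ParameterSet | None = None,
                          free=STAGE1_FREE, **kwargs) -> FitResult:
    """Stage 1: endogenous migration/homeostasis parameters from
    steady-state tissue concentrations (organ-to-blood rates held fixed at
    their half-life-derived values)."""
    base = params if params is not None else ParameterSet()
    return fit_ml(data, base, free, **kwargs)


def fit_stage2_exogenous(data: pd.DataFrame, stage1: FitResult | ParameterSet,
                         free=STAGE2_FREE, **kwargs) -> FitResult:
    """Stage 2: infused-cell entry rates and delay constants from bolus
    kinetic curves, with all stage-1 (endogenous) parameters frozen and
    the lymphoid delay constants tied (kdel3 = kdel5 = kdel6)."""
    base = stage1.params if isinstance(stage1, FitResult) else stage1
    kwargs.setdefault("tie_lymphoid_delays", True)
    return fit_ml(data, base, free, **kwargs)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def relative_standard_errors(fit: FitResult, step: float = 1e-3) -> dict[str, float]:
    """RSE (%) per fitted parameter from the observed information.

    The Hessian of -loglik is finite-differenced on the log-parameter
    scale, so sqrt of the inverse diagonal is directly the relative
    standard error.  Parameters whose curvature is not positive definite
    are flagged NaN (not identifiable).  The result is stored on the fit.
    """
    free = fit.free
    x_opt = np.array([np.log(fit.estimates[n]) for n in free])

    def nll(x):
        p = _apply_free(fit.params, free, x, fit.tie_lymphoid_delays)
        return -log_likelihood(p, fit.data, fit.error)

    k = len(free)
    H = np.empty((k, k))
    f0 = nll(x_opt)
    for i in range(k):
        ei = np.zeros(k); ei[i] = step
        H[i, i] = (nll(x_opt + ei) - 2 * f0 + nll(x_opt - ei)) / step ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = step
            ej = np.zeros(k); ej[j] = step
            H[i, j] = H[j, i] = (
                nll(x_opt + ei + ej) - nll(x_opt + ei - ej)
                - nll(x_opt - ei + ej) + nll(x_opt - ei - ej)
            ) / (4 * step ** 2)

    rse = {}
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("nonpositive variance")
        for n, v in zip(free, diag):
            rse[n] = float(100.0 * np.sqrt(v))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        for n, v in zip(free, np.diag(cov)):
            rse[n] = float(100.0 * np.sqrt(v)) if v > 0 else float("nan")
    fit.rse = rse
    return rse


def weighted_residuals(fit: FitResult, data: pd.DataFrame | None = None,
                       method: str = "analytic", n_sim: int = 1000,
                       seed: int = 0) -> np.ndarray:
    """WRES = (y - E[y]) / sd[y] per observation, on the observation scale.

    With the log-normal error model (median = model prediction m):
    E[y] = m*exp(sigma^2/2) and Var[y] = m^2*exp(sigma^2)(exp(sigma^2)-1).
    ``method='simulation'`` estimates E and sd by seeded Monte-Carlo draws
    from the fitted error model instead of the closed forms.
    """
    if data is None:
        data = fit.data
    pred = predictions(fit.params, data)
    sig = fit.error.sigmas(data)
    y = data["value"].to_numpy(dtype=float)
    if method == "analytic":
        ey = pred * np.exp(sig ** 2 / 2)
        sd = pred * np.sqrt(np.exp(sig ** 2) * (np.exp(sig ** 2) - 1.0))
    elif method == "simulation":
        rng = np.random.default_rng(seed)
        draws = pred[None, :] * np.exp(sig[None, :] * rng.standard_normal((n_sim, len(y))))
        ey = draws.mean(axis=0)
        sd = draws.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return (y - ey) / sd


def apply_omega_scaling(data: pd.DataFrame, omega: float) -> pd.DataFrame:
    """Multiply observed concentrations by the assay scale factor ω,
    recording the cumulative factor per record."""
    if not omega > 0:
        raise ValueError("omega must be > 0")
    out = data.copy()
    out["value"] = out["value"] * omega
    out["omega"] = out["omega"] * omega
    return out
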