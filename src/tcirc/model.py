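"""Core state-space model: right-hand side, steady state, integration.

The model tracks two uncoupled T cell populations over six anatomical
compartments (blood, lungs, spleen, liver, generalized LNs, regional LNs):

* the resident (endogenous) population, sourced by thymic output and by
  saturating homeostatic proliferation in the spleen, with first-order
  apoptosis in blood; and
* the infused (exogenous) population, a bolus into blood with no sources,
  eliminated by blood apoptosis and lung degradation, and retarded in
  spleen, liver and both LN compartments by linear intra-organ delay pools.

All migration is first order.  CCR7+ fractions gate entry into the LN
compartments through high endothelial venules; spleen entry is not gated.
The infused-cell subsystem is linear and time invariant, which the package
exploits through an exact matrix-exponential propagator.

State layout (cells): 6 endogenous pools, 6 infused free pools, 4 infused
delay pools — see ``STATE_NAMES``.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import brentq

from .parameters import ORGANS, ParameterSet

__all__ = [
    "STATE_NAMES",
    "N_STATES",
    "SteadyStateError",
    "SolverError",
    "derivative",
    "net_production_rate",
    "endogenous_steady_state",
    "steady_state_by_integration",
    "exogenous_transition_matrix",
    "propagate_exogenous",
    "integrate",
    "observed_concentrations",
]

STATE_NAMES = (
    "T_blood", "T_lung", "T_spleen", "T_liver", "T_ln", "T_regln",
    "Tex_blood", "Tex_lung", "Tex_spleen", "Tex_liver", "Tex_ln", "Tex_regln",
    "Tex_del_spleen", "Tex_del_liver", "Tex_del_ln", "Tex_del_regln",
)
N_STATES = len(STATE_NAMES)

# index blocks
ENDO = slice(0, 6)
EXO = slice(6, 12)
DELAY = slice(12, 16)
# delay pool order: spleen, liver, ln, regln -> paired free-pool organ index
_DELAY_ORGAN = (2, 3, 4, 5)


class SteadyStateError(RuntimeError):
    """No admissible endogenous equilibrium exists for these parameters."""


class SolverError(RuntimeError):
    """ODE integration failed; carries the time of failure."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


def _rhs(y: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Unchecked right-hand side, cells/h."""
    f, fx = p.f_ccr7, p.f_ccr7_ex
    (Tb, Tlu, Tsp, Tli, Tln, Trl,
     Xb, Xlu, Xsp, Xli, Xln, Xrl,
     Dsp, Dli, Dln, Drl) = y
    pro = p.Vmax_pro * Tsp / (p.EC50_pro + Tsp)
    d = np.empty(N_STATES)
    # endogenous
    out_b = (1 - f) * p.mu12 + p.mu13 + (1 - f) * p.mu14 + f * p.mu15 + f * p.mu16
    d[0] = (p.V_inf_thymus - Tb * out_b
            + p.mu21 * Tlu + p.mu41 * Tli + p.mu51 * Tln + p.mu31 * Tsp
            - p.k_apo * Tb)
    d[1] = (1 - f) * p.mu12 * Tb - (p.mu21 + p.mu25) * Tlu
    d[2] = p.mu13 * Tb - p.mu31 * Tsp + pro
    d[3] = (1 - f) * p.mu14 * Tb - (p.mu41 + p.mu45) * Tli
    d[4] = f * p.mu15 * Tb + p.mu45 * Tli + p.mu25 * Tlu - p.mu51 * Tln + p.mu65 * Trl
    d[5] = f * p.mu16 * Tb - p.mu65 * Trl
    # infused
    out_xb = ((1 - fx) * p.mu12ex + (1 - fx) * p.mu14 + p.mu13ex
              + fx * p.mu15ex + fx * p.mu16ex)
    d[6] = (-Xb * out_xb + p.mu21 * Xlu + p.mu41 * Xli + p.mu51 * Xln + p.mu31 * Xsp
            - p.k_apo * Xb)
    d[7] = (1 - fx) * p.mu12ex * Xb - (p.mu21 + p.mu25 + p.k_deg) * Xlu
    d[8] = p.mu13ex * Xb - p.mu31 * Xsp - p.kdel3 * Xsp + p.koff3 * Dsp
    d[9] = ((1 - fx) * p.mu14 * Xb - (p.mu41 + p.mu45) * Xli
            + p.koff4 * Dli - p.kdel4 * Xli)
    d[10] = (fx * p.mu15ex * Xb + p.mu45 * Xli + p.mu25 * Xlu - p.mu51 * Xln
             - p.kdel5 * Xln + p.koff5 * Dln + p.mu65 * Xrl)
    d[11] = fx * p.mu16ex * Xb - p.mu65 * Xrl - p.kdel6 * Xrl + p.koff6 * Drl
    # delay pools
    d[12] = p.kdel3 * Xsp - p.koff3 * Dsp
    d[13] = p.kdel4 * Xli - p.koff4 * Dli
    d[14] = p.kdel5 * Xln - p.koff5 * Dln
    d[15] = p.kdel6 * Xrl - p.koff6 * Drl
    return d


def derivative(state: np.ndarray, params: ParameterSet, *, neg_tol: float = 1e-6) -> np.ndarray:
    """Time derivative (cells/h) of the 16-component state.

    Raises ``ValueError`` for state components negative beyond
    ``neg_tol * max(1, |state|)`` — a sign of solver misconfiguration.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} components, got shape {y.shape}")
    floor = -neg_tol * max(1.0, float(np.max(np.abs(y))))
    if np.any(y < floor):
        bad = [STATE_NAMES[i] for i in np.where(y < floor)[0]]
        raise ValueError(f"negative state components beyond tolerance: {bad}")
    return _rhs(y, params)


def net_production_rate(state: np.ndarray, params: ParameterSet) -> float:
    """Net whole-body cell production (cells/h): thymic influx + spleen
    proliferation − blood apoptosis − lung degradation.  All migration
    terms cancel pairwise, so this equals the sum of all 16 derivative
    components."""
    y = np.asarray(state, dtype=float)
    pro = params.Vmax_pro * y[2] / (params.EC50_pro + y[2])
    return (params.V_inf_thymus + pro
            - params.k_apo * (y[0] + y[6]) - params.k_deg * y[7])


# ---------------------------------------------------------------------------
# endogenous steady state
# ---------------------------------------------------------------------------

def _spleen_equilibrium(Tb: float, p: ParameterSet) -> float:
    """Nonnegative root of mu13*Tb − mu31*s + Vmax*s/(EC50+s) = 0 in s."""
    a = p.mu31
    if a <= 0:
        raise SteadyStateError("mu31 must be positive for a spleen equilibrium")
    b = p.mu31 * p.EC50_pro - p.mu13 * Tb - p.Vmax_pro
    c = -p.mu13 * Tb * p.EC50_pro
    disc = b * b - 4 * a * c
    s = (-b + np.sqrt(disc)) / (2 * a)
    return max(s, 0.0)


def _linear_pools(Tb: float, s: float, p: ParameterSet) -> np.ndarray:
    """Closed-form equilibria of the one-in/one-out endogenous pools."""
    f = p.f_ccr7
    lung = (1 - f) * p.mu12 * Tb / (p.mu21 + p.mu25)
    liver = (1 - f) * p.mu14 * Tb / (p.mu41 + p.mu45)
    regln = f * p.mu16 * Tb / p.mu65 if p.mu65 > 0 else 0.0
    ln = (f * p.mu15 * Tb + p.mu45 * liver + p.mu25 * lung + p.mu65 * regln) / p.mu51
    return np.array([Tb, lung, s, liver, ln, regln])


def endogenous_steady_state(params: ParameterSet) -> np.ndarray:
    """Equilibrium of the endogenous subsystem (infused pools zero).

    The six equilibrium equations reduce exactly to a scalar root problem
    in the blood pool: at equilibrium every linear pool is a closed form in
    ``T_blood``, the spleen pool solves a quadratic, and summing all six
    equations leaves ``V_inf_thymus + proliferation − k_apo·T_blood = 0``.
    The root is bracketed and solved with Brent's method.

    Returns the full 16-component state (infused pools zero).  Raises
    :class:`SteadyStateError` when production cannot balance apoptosis.
    """
    p = params
    if p.mu51 <= 0 or p.mu21 + p.mu25 <= 0 or p.mu41 + p.mu45 <= 0:
        raise SteadyStateError("organ exit rates must be positive")

    def resid(Tb: float) -> float:
        s = _spleen_equilibrium(Tb, p)
        pro = p.Vmax_pro * s / (p.EC50_pro + s)
        return p.V_inf_thymus + pro - p.k_apo * Tb

    if p.k_apo <= 0:
        if p.V_inf_thymus > 0 or p.Vmax_pro > 0:
            raise SteadyStateError(
                "k_apo = 0: thymic/proliferative production cannot be balanced")
        return np.zeros(N_STATES)

    hi = 2.0 * (p.V_inf_thymus + p.Vmax_pro) / p.k_apo + 1.0
    if p.V_inf_thymus > 0:
        lo = min(1e-9 * hi, 1.0)
    else:
        # zero state is always an equilibrium; look for a positive one
        lo = None
        for cand in np.geomspace(1e-6 * hi, hi * 0.99, 60):
            if resid(cand) > 0:
                lo = cand
                break
        if lo is None:
            return np.zeros(N_STATES)  # zero is the unique equilibrium
    Tb = brentq(resid, lo, hi, xtol=1e-12, rtol=1e-14, maxiter=200)
    s = _spleen_equilibrium(Tb, p)
    out = np.zeros(N_STATES)
    out[ENDO] = _linear_pools(Tb, s, p)
    return out


def steady_state_by_integration(
    params: ParameterSet, horizon: float = 80_000.0, y0: np.ndarray | None = None,
    rtol: float = 1e-10, atol: float = 1e-6,
) -> np.ndarray:
    """Long-horizon integration to equilibrium (cross-check / fallback)."""
    if y0 is None:
        y0 = np.zeros(N_STATES)
        y0[0] = max(params.V_inf_thymus, 1.0)
    sol = integrate(params, y0, (0.0, horizon), rtol=rtol, atol=atol)
    return sol.y[:, -1]


# ---------------------------------------------------------------------------
# infused-cell linear subsystem
# ---------------------------------------------------------------------------

def exogenous_transition_matrix(params: ParameterSet, f_ccr7_ex: float | None = None) -> np.ndarray:
    """System matrix A of the 10-state linear infused-cell subsystem,
    state order = free pools (blood, lung, spleen, liver, ln, regln) then
    delay pools (spleen, liver, ln, regln); dx/dt = A x."""
    p = params
    fx = p.f_ccr7_ex if f_ccr7_ex is None else f_ccr7_ex
    A = np.zeros((10, 10))
    out_b = ((1 - fx) * p.mu12ex + (1 - fx) * p.mu14 + p.mu13ex
             + fx * p.mu15ex + fx * p.mu16ex + p.k_apo)
    A[0, 0] = -out_b
    A[0, 1], A[0, 2], A[0, 3], A[0, 4] = p.mu21, p.mu31, p.mu41, p.mu51
    A[1, 0] = (1 - fx) * p.mu12ex
    A[1, 1] = -(p.mu21 + p.mu25 + p.k_deg)
    A[2, 0] = p.mu13ex
    A[2, 2] = -(p.mu31 + p.kdel3)
    A[2, 6] = p.koff3
    A[3, 0] = (1 - fx) * p.mu14
    A[3, 3] = -(p.mu41 + p.mu45 + p.kdel4)
    A[3, 7] = p.koff4
    A[4, 0] = fx * p.mu15ex
    A[4, 1], A[4, 3], A[4, 5] = p.mu25, p.mu45, p.mu65
    A[4, 4] = -(p.mu51 + p.kdel5)
    A[4, 8] = p.koff5
    A[5, 0] = fx * p.mu16ex
    A[5, 5] = -(p.mu65 + p.kdel6)
    A[5, 9] = p.koff6
    A[6, 2], A[6, 6] = p.kdel3, -p.koff3
    A[7, 3], A[7, 7] = p.kdel4, -p.koff4
    A[8, 4], A[8, 8] = p.kdel5, -p.koff5
    A[9, 5], A[9, 9] = p.kdel6, -p.koff6
    return A


def propagate_exogenous(
    params: ParameterSet, dose: float, times: np.ndarray,
    f_ccr7_ex: float | None = None,
) -> np.ndarray:
    """Exact infused-cell pools at the requested times (matrix exponential).

    ``times`` must be nondecreasing and start at >= 0.  Returns an
    ``(len(times), 10)`` array in the subsystem state order.  Exact for
    this linear time-invariant subsystem (no truncation error), hence both
    the fast path for calibration and the oracle against the ODE solver.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0) or (t.size and t[0] < 0):
        raise ValueError("times must be a nondecreasing 1-D array of nonnegative hours")
    A = exogenous_transition_matrix(params, f_ccr7_ex)
    x = np.zeros(10)
    x[0] = dose
    out = np.empty((t.size, 10))
    prev = 0.0
    cache: dict[float, np.ndarray] = {}
    for i, ti in enumerate(t):
        dt = ti - prev
        if dt > 0:
            P = cache.get(dt)
            if P is None:
                P = expm(A * dt)
                cache[dt] = P
            x = P @ x
        out[i] = x
        prev = ti
    return out


# ---------------------------------------------------------------------------
# integration and observation
# ---------------------------------------------------------------------------

def integrate(
    params: ParameterSet,
    y0: np.ndarray,
    t_span: tuple[float, float],
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-3,
    method: str = "LSODA",
    dense_output: bool = False,
):
    """Stiff-capable integration of the full 16-state system."""
    sol = solve_ivp(
        lambda t, y: _rhs(y, params), t_span, np.asarray(y0, dtype=float),
        method=method, t_eval=t_eval, rtol=rtol, atol=atol,
        dense_output=dense_output,
    )
    if not sol.success:
        raise SolverError(f"integration failed: {sol.message}", t_fail=float(sol.t[-1]) if sol.t.size else None)
    return sol


def observed_concentrations(pools: np.ndarray, params: ParameterSet, population: str) -> dict[str, np.ndarray]:
    """Observable per-organ concentrations (cells/ml) from pool trajectories.

    ``pools`` is (16, n) in ``STATE_NAMES`` order.  For infused cells the
    observable pools are free + delay (a radiolabel cannot distinguish the
    sub-pools); for endogenous cells the free pool alone.
    """
    ph = params.physiology
    vols = np.array([ph.V_blood, ph.V_lung, ph.V_spleen, ph.V_liver, ph.V_ln, ph.V_regln])
    pools = np.asarray(pools, dtype=float)
    if population == "endogenous":
        block = pools[ENDO]
    elif population == "exogenous":
        block = pools[EXO].copy()
        for d_idx, organ_idx in enumerate(_DELAY_ORGAN):
            block[organ_idx] += pools[12 + d_idx]
    else:
        raise ValueError(f"population must be 'endogenous' or 'exogenous', got {population!r}")
    return {organ: block[i] / vols[i] for i, organ in enumerate(ORGANS)}
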