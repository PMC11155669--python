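"""Seeded synthetic observation datasets.

The published model was calibrated to digitized figure data that were
never deposited: steady-state CD3+ concentrations in five mouse tissues,
radiolabeled-cell kinetic curves over ~0-72 h in five organs, and
externally measured (PET-style) series on a different radioactivity scale.
This module generates datasets with the same statistical structure —
log-normal multiplicative noise around the model median, per-gram assay
units convertible through organ mass at density 1 g/ml, and an empirical
scale factor ω for external assays — so the calibration and diagnostics
machinery is testable end to end with known ground truth.

All generators are deterministic given (params, spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model
from .parameters import ParameterSet
from .simulate import thymectomy_scenario

__all__ = [
    "NoiseSpec",
    "AssaySpec",
    "OBSERVATION_COLUMNS",
    "validate_observations",
    "read_observations",
    "write_observations",
    "make_steady_state_dataset",
    "make_kinetic_dataset",
    "make_thymectomy_dataset",
    "per_gram_to_cells_per_ml",
]

#: canonical observation-table schema (the calibration module reads this)
OBSERVATION_COLUMNS = (
    "organ", "population", "protocol", "time_h",
    "value", "unit", "cv", "dose", "omega",
)

#: default kinetic sampling design: organs and timepoints of the
#: radiolabeled-transfer experiments the model was fitted to
KINETIC_ORGANS = ("blood", "lung", "spleen", "liver", "regln")
KINETIC_TIMEPOINTS = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 72.0)
STEADY_STATE_ORGANS = ("blood", "lung", "spleen", "liver", "ln")


@dataclass(frozen=True)
class NoiseSpec:
    """Log-normal multiplicative noise: value = median * exp(sigma*Z),
    sigma = sqrt(log(1 + cv^2))."""

    cv: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not self.cv > 0:
            raise ValueError("cv must be > 0")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.cv ** 2)))


@dataclass(frozen=True)
class AssaySpec:
    """Measurement convention of the emulated assay.

    unit : 'cells_per_ml' (direct) or 'counts_per_gram' (radioactivity per
        gram of tissue; converted via organ mass assuming density 1 g/ml)
    omega : scale factor applied to emitted values, emulating external
        assays whose readout sits on a different radioactivity scale;
        recover the cells/ml scale with
        ``calibrate.apply_omega_scaling(df, 1/omega)``.
    """

    unit: str = "cells_per_ml"
    omega: float = 1.0

    def __post_init__(self):
        if self.unit not in ("cells_per_ml", "counts_per_gram"):
            raise ValueError(f"unknown assay unit {self.unit!r}")
        if not self.omega > 0:
            raise ValueError("omega must be > 0")


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    if (df["value"] <= 0).any():
        raise ValueError("observation values must be > 0 (log-normal support)")
    kin = df["time_h"].notna()
    if (df.loc[kin, "time_h"] < 0).any():
        raise ValueError("observation times must be >= 0")
    return df


def read_observations(path) -> pd.DataFrame:
    return validate_observations(pd.read_csv(path))


def write_observations(df: pd.DataFrame, path) -> None:
    validate_observations(df).to_csv(path, index=False)


def _lognormal_factors(n: int, noise: NoiseSpec) -> np.ndarray:
    rng = np.random.default_rng(noise.seed)
    return np.exp(noise.sigma * rng.standard_normal(n))


def _per_gram_factor(organ: str, params: ParameterSet) -> float:
    """cells/ml -> cells/g: conc*V/mass, density 1 g/ml; blood has no
    tabulated mass, so 1 ml is taken as 1 g."""
    ph = params.physiology
    table = {"lung": ph.V_lung / ph.mass_lung,
             "spleen": ph.V_spleen / ph.mass_spleen,
             "liver": ph.V_liver / ph.mass_liver}
    return table.get(organ, 1.0)


def per_gram_to_cells_per_ml(df: pd.DataFrame, params: ParameterSet) -> pd.DataFrame:
    """Convert counts-per-gram rows back to cells/ml (omega untouched)."""
    out = df.copy()
    mask = out["unit"] == "counts_per_gram"
    factors = out.loc[mask, "organ"].map(lambda o: _per_gram_factor(o, params))
    out.loc[mask, "value"] = out.loc[mask, "value"] / factors
    out.loc[mask, "unit"] = "cells_per_ml"
    return out


def make_steady_state_dataset(params: ParameterSet, noise: NoiseSpec,
                              organs=STEADY_STATE_ORGANS) -> pd.DataFrame:
    """One noisy steady-state endogenous concentration record per organ;
    the record median is the model steady state."""
    ss = model.endogenous_steady_state(params)
    conc = model.observed_concentrations(ss[:, None], params, "endogenous")
    median = np.array([conc[o][0] for o in organs])
    values = median * _lognormal_factors(len(organs), noise)
    return validate_observations(pd.DataFrame({
        "organ": organs, "population": "endogenous", "protocol": "steady-state",
        "time_h": np.nan, "value": values, "unit": "cells_per_ml",
        "cv": noise.cv, "dose": np.nan, "omega": 1.0,
    }))


def make_kinetic_dataset(params: ParameterSet, dose: float = 20e6,
                         timepoints=KINETIC_TIMEPOINTS,
                         noise: NoiseSpec = NoiseSpec(),
                         assay: AssaySpec = AssaySpec(),
                         organs=KINETIC_ORGANS) -> pd.DataFrame:
    """Noisy infused-cell concentration curves after an intravenous bolus.

    The noiseless median is the exact model trajectory (free + delay pool
    per organ volume).  With ``assay.unit == 'counts_per_gram'`` values are
    converted through organ mass at density 1 g/ml; ``assay.omega``
    rescales the emitted values, emulating external radioactivity scales.
    """
    t = np.asarray(sorted(timepoints), dtype=float)
    pools = model.propagate_exogenous(params, dose, t)  # (n, 10)
    full = np.zeros((model.N_STATES, t.size))
    full[6:16] = pools.T
    conc = model.observed_concentrations(full, params, "exogenous")
    rows = []
    for organ in organs:
        for j, tj in enumerate(t):
            rows.append({"organ": organ, "population": "exogenous",
                         "protocol": "bolus", "time_h": tj,
                         "value": conc[organ][j], "unit": "cells_per_ml",
                         "cv": noise.cv, "dose": dose, "omega": assay.omega})
    df = pd.DataFrame(rows)
    df["value"] *= _lognormal_factors(len(df), noise)
    if assay.unit == "counts_per_gram":
        df["value"] *= df["organ"].map(lambda o: _per_gram_factor(o, params))
        df["unit"] = "counts_per_gram"
    df["value"] *= assay.omega
    return validate_observations(df)


def make_thymectomy_dataset(params: ParameterSet, noise: NoiseSpec,
                            timepoints=(50, 250, 500, 750, 1000, 1300, 1650, 2000),
                            organ: str = "spleen") -> pd.DataFrame:
    """Noisy endogenous decay series after ablating thymic output at t=0.

    Starts from the unperturbed steady state; the decay toward the lower
    proliferation-sustained equilibrium identifies Vmax_pro.
    """
    t = np.asarray(sorted(timepoints), dtype=float)
    traj = thymectomy_scenario(params, horizon=float(t[-1]))
    conc = traj.concentrations("endogenous")[organ]
    median = np.interp(t, traj.times, conc)
    values = median * _lognormal_factors(t.size, noise)
    return validate_observations(pd.DataFrame({
        "organ": organ, "population": "endogenous", "protocol": "thymectomy",
        "time_h": t, "value": values, "unit": "cells_per_ml",
        "cv": noise.cv, "dose": np.nan, "omega": 1.0,
    }))
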