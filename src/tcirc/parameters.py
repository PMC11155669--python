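"""Model parameters and mouse physiology.

The parameterization follows the published mouse calibration of the
T cell recirculation model: first-order inter-compartment migration rate
constants (1/h), CCR7+ fractions gating lymph-node entry through high
endothelial venules, elimination constants (blood apoptosis, lung
degradation of infused cells), delay-compartment exchange constants for
infused cells in spleen/liver/LNs, thymic output, and a Michaelis-Menten
homeostatic proliferation term in the spleen.

One rate constant of the published set, ``mu15ex`` (infused-cell migration
from blood to the generalized LN compartment), has no published value; the
packaged default sets it equal to ``mu13ex`` (0.064 1/h), a choice
calibrated against the published CCR7-fraction scan (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "Physiology",
    "ParameterSet",
    "ParameterError",
    "default_parameters",
    "load_parameters",
    "write_parameters",
    "parameter_hash",
    "MU15EX_DEFAULT",
]

#: Default for the rate constant with no published value (1/h); equal to
#: mu13ex by calibration against the published CCR7-fraction AUC scan.
MU15EX_DEFAULT = 0.064


class ParameterError(ValueError):
    """Invalid, unknown or out-of-range parameter value."""


@dataclass(frozen=True)
class Physiology:
    """Mouse organ volumes (ml) and masses (g).

    ``V_regln`` (regional lymph node compartment volume) has no published
    value and defaults to ``V_ln``.
    """

    V_blood: float = 2.15
    V_lung: float = 0.204
    V_spleen: float = 0.127
    V_liver: float = 1.93
    V_ln: float = 0.113
    V_regln: float = 0.113
    mass_lung: float = 0.130
    mass_spleen: float = 0.106
    mass_liver: float = 1.013

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ParameterError(f"physiology field {f.name!r} must be a positive number, got {v!r}")


# organ-key order used throughout the package
ORGANS = ("blood", "lung", "spleen", "liver", "ln", "regln")

_RATE_FIELDS = (
    "mu12", "mu13", "mu14", "mu15", "mu16",
    "mu21", "mu25", "mu31", "mu41", "mu45", "mu51", "mu65",
    "mu12ex", "mu13ex", "mu15ex", "mu16ex",
    "k_apo", "k_deg",
    "kdel3", "kdel4", "kdel5", "kdel6",
    "koff3", "koff4", "koff5", "koff6",
)
_FRACTION_FIELDS = ("f_ccr7", "f_ccr7_ex")

# delay-exit constants tied by default to the matching organ-to-blood rates
_KOFF_TIES = {"koff3": "mu31", "koff4": "mu41", "koff5": "mu51", "koff6": "mu65"}


@dataclass(frozen=True)
class ParameterSet:
    """Complete parameter set of the recirculation model.

    Units: rate constants 1/h, influx and proliferation cells/h, pool
    half-saturation cells, fractions dimensionless in [0, 1].
    """

    # endogenous migration, blood -> organ
    mu12: float = 2.66    # blood -> lungs
    mu13: float = 0.92    # blood -> spleen (not CCR7-gated)
    mu14: float = 1.05    # blood -> liver
    mu15: float = 2.4     # blood -> generalized LNs (CCR7-gated)
    mu16: float = 0.048   # blood -> regional LNs (CCR7-gated)
    # organ -> blood / afferent lymphatics (shared by both populations)
    mu21: float = 2.31    # lungs -> blood
    mu25: float = 0.51    # lungs -> generalized LNs
    mu31: float = 0.17    # spleen -> blood
    mu41: float = 0.63    # liver -> blood
    mu45: float = 0.54    # liver -> generalized LNs
    mu51: float = 0.20    # generalized LNs -> blood (thoracic duct)
    mu65: float = 0.077   # regional LNs -> generalized LNs
    # infused-cell specific blood -> organ rates
    mu12ex: float = 3.99
    mu13ex: float = 0.064
    mu15ex: float = MU15EX_DEFAULT  # no published value; see module docstring
    mu16ex: float = 0.000086
    # elimination
    k_apo: float = 0.004  # apoptosis in blood (both populations)
    k_deg: float = 0.84   # degradation of infused cells in lungs
    # delay-compartment exchange for infused cells
    kdel3: float = 3.55   # spleen, into delay pool
    kdel4: float = 72.06  # liver, into delay pool
    kdel5: float = 3.55   # generalized LNs (tied to kdel3 in the published fit)
    kdel6: float = 3.55   # regional LNs (tied to kdel3)
    koff3: float = 0.17   # spleen delay pool exit (= mu31)
    koff4: float = 0.63   # liver delay pool exit (= mu41)
    koff5: float = 0.20   # generalized LN delay pool exit (= mu51)
    koff6: float = 0.077  # regional LN delay pool exit (= mu65)
    # sources and homeostasis
    V_inf_thymus: float = 3.13e3   # thymic output, cells/h
    Vmax_pro: float = 12281.0      # maximal homeostatic proliferation, cells/h
    EC50_pro: float = 1.0e6        # spleen pool size at half-maximal proliferation, cells
    # CCR7+ fractions
    f_ccr7: float = 0.75
    f_ccr7_ex: float = 0.75
    physiology: Physiology = field(default_factory=Physiology)

    # -- validation ---------------------------------------------------------
    def validate(self) -> "ParameterSet":
        for name in _RATE_FIELDS + ("V_inf_thymus", "Vmax_pro"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v >= 0):
                raise ParameterError(f"{name} must be a nonnegative number, got {v!r}")
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v!r}")
        if not self.EC50_pro > 0:
            raise ParameterError(f"EC50_pro must be > 0, got {self.EC50_pro!r}")
        self.physiology.validate()
        return self

    # -- flat-dict interface (mirrors the YAML file) ------------------------
    def as_flat_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self) if f.name != "physiology"}
        d.update({f.name: getattr(self.physiology, f.name) for f in dataclasses.fields(Physiology)})
        return d

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given (flat) keys replaced."""
        phys_names = {f.name for f in dataclasses.fields(Physiology)}
        phys = {k: v for k, v in overrides.items() if k in phys_names}
        rest = {k: v for k, v in overrides.items() if k not in phys_names}
        own = {f.name for f in dataclasses.fields(self)}
        unknown = set(rest) - own
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        new_phys = dataclasses.replace(self.physiology, **phys) if phys else self.physiology
        return dataclasses.replace(self, physiology=new_phys, **rest).validate()

    @classmethod
    def from_flat_dict(cls, d: dict[str, float], *, tie_koff: bool = True) -> "ParameterSet":
        """Build a set from a flat mapping, filling gaps with defaults.

        When ``tie_koff`` is true, any delay-exit constant not given
        explicitly is tied to the matching organ-exit rate if that rate was
        overridden (the published convention koff3=mu31, koff4=mu41,
        koff5=mu51, koff6=mu65).
        """
        base = cls()
        d = dict(d)
        if tie_koff:
            for koff, mu in _KOFF_TIES.items():
                if koff not in d and mu in d:
                    d[koff] = d[mu]
        if "V_regln" not in d and "V_ln" in d:
            d["V_regln"] = d["V_ln"]
        return base.replace(**d)


def default_parameters() -> ParameterSet:
    """The packaged default (published mouse calibration) parameter set."""
    return ParameterSet().validate()


_DATA_FILE = Path(__file__).parent / "data" / "default_parameters.yaml"


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a parameter file (flat YAML mapping of symbol -> value).

    Unknown keys are rejected; missing keys are filled from the packaged
    defaults. An absent ``mu15ex`` triggers an explicit warning naming the
    default used, because that constant has no published value.
    """
    if path is None:
        path = _DATA_FILE
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"parameter file {path} must contain a flat key: value mapping")
    for k, v in raw.items():
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ParameterError(f"parameter {k!r} has non-numeric value {v!r}")
    if "mu15ex" not in raw:
        warnings.warn(
            f"mu15ex not specified in {path}; using the package default "
            f"{MU15EX_DEFAULT} 1/h (no published value exists for this constant)",
            stacklevel=2,
        )
    return ParameterSet.from_flat_dict(raw)


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as a flat YAML mapping (round-trips with load)."""
    Path(path).write_text(yaml.safe_dump(params.as_flat_dict(), sort_keys=True))


def parameter_hash(params: ParameterSet) -> str:
    """Stable sha256 of the flat parameter mapping (for run manifests)."""
    canon = yaml.safe_dump(params.as_flat_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
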