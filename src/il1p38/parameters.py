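"""Rate constants, expression levels and their provenance.

The package ships a committed default :class:`ParameterSet` (provenance
``calibrated``) produced by the calibration path in
:mod:`il1p38.calibration`; a user-supplied parameter file loaded with
:func:`load_parameters` takes precedence over it.

Canonical units are nM and seconds.  Parameter files may declare other
recognized units (min, h, uM, pM ...) and are converted on load; a
degradation constant ``beta_*`` may alternatively be given as a half-life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "PARAMETER_UNITS",
    "REQUIRED_PARAMETERS",
    "ParameterSet",
    "load_parameters",
    "default_parameters",
    "sample_perturbations",
]

MKP1_HALF_LIFE_S = 40.0 * 60.0  # 40 min

#: canonical unit of every model parameter
PARAMETER_UNITS = {
    # receptor module
    "kon_il1_receptor": "1/(nM*s)",
    "kcat_irak": "1/s",
    "km_irak": "nM",
    "kon_pirak_traf6": "1/(nM*s)",
    "kon_tab2_membrane": "1/(nM*s)",
    "kdeg_irak": "1/s",
    # TAK1 module
    "kcat_tak1": "1/s",
    "km_tak1": "nM",
    "k_tab1_tak1": "1/(nM*s)",
    "kdephos_ptak1": "1/s",
    "beta_ptak1": "1/s",
    "beta_tab2_traf6": "1/s",
    # turnover (production alpha, decay beta)
    "alpha_tab2": "nM/s",
    "beta_tab2": "1/s",
    "alpha_traf6": "nM/s",
    "beta_traf6": "1/s",
    "alpha_tak1": "nM/s",
    "beta_tak1": "1/s",
    "alpha_tab1": "nM/s",
    "beta_tab1": "1/s",
    # TAB1 positive-feedback induction
    "vmax_tab1_induction": "nM/s",
    "k_tab1_induction": "nM",
    # MKK / p38 module
    "kcat_mkk": "1/s",
    "km_mkk": "nM",
    "kdephos_pmkk": "1/s",
    "kcat_p38": "1/s",
    "km_p38": "nM",
    # MKP1 negative feedback
    "kcat_mkp1": "1/s",
    "km_mkp1": "nM",
    "alpha_mkp1": "nM/s",
    "beta_mkp1": "1/s",
    "vmax_mkp1_induction": "nM/s",
    "k_mkp1_induction": "nM",
    # TAB1-p38 membrane branch
    "kon_tab1_p38": "1/(nM*s)",
    "koff_tab1_p38": "1/s",
    "kauto_p38": "1/s",
    "kdephos_pp38cyt": "1/s",
    # wild-type expression levels (pre-stimulation)
    "level_il1r": "nM",
    "level_irak": "nM",
    "level_traf6": "nM",
    "level_tab2": "nM",
    "level_tak1": "nM",
    "level_tab1": "nM",
    "level_mkk": "nM",
    "level_p38": "nM",
    "level_mkp1": "nM",
}

REQUIRED_PARAMETERS = tuple(PARAMETER_UNITS)

PROVENANCE_TAGS = ("s1_text", "calibrated", "user", "perturbed")

#: multiplicative factor to the canonical unit, keyed by declared unit string
_UNIT_FACTORS = {
    "1/s": ("1/s", 1.0),
    "1/min": ("1/s", 1.0 / 60.0),
    "1/h": ("1/s", 1.0 / 3600.0),
    "nM/s": ("nM/s", 1.0),
    "nM/min": ("nM/s", 1.0 / 60.0),
    "nM/h": ("nM/s", 1.0 / 3600.0),
    "uM/s": ("nM/s", 1e3),
    "1/(nM*s)": ("1/(nM*s)", 1.0),
    "1/(nM*min)": ("1/(nM*s)", 1.0 / 60.0),
    "1/(uM*s)": ("1/(nM*s)", 1e-3),
    "nM": ("nM", 1.0),
    "uM": ("nM", 1e3),
    "pM": ("nM", 1e-3),
    "s": ("s", 1.0),
    "min": ("s", 60.0),
    "h": ("s", 3600.0),
}


def _convert(name: str, value: float, unit: str | None) -> float:
    canonical = PARAMETER_UNITS.get(name)
    if unit is None:
        return float(value)
    if unit not in _UNIT_FACTORS:
        raise ConfigurationError(f"parameter {name!r}: unrecognized unit {unit!r}")
    target, factor = _UNIT_FACTORS[unit]
    if canonical is not None and target != canonical:
        raise ConfigurationError(
            f"parameter {name!r}: unit {unit!r} is a {target}, expected "
            f"{canonical}"
        )
    return float(value) * factor


@dataclass
class ParameterSet:
    """Named rate constants and expression levels with units and provenance."""

    values: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = {k: float(v) for k, v in self.values.items()}
        for name, v in self.values.items():
            if not (v >= 0.0):
                raise InvalidArgumentError(f"parameter {name}={v} must be >= 0")
            self.units.setdefault(name, PARAMETER_UNITS.get(name, ""))
            self.provenance.setdefault(name, "user")

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ConfigurationError(f"missing parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def get(self, name: str, default: float | None = None):
        return self.values.get(name, default)

    def missing(self, required=REQUIRED_PARAMETERS) -> list[str]:
        return [n for n in required if n not in self.values]

    def with_values(self, provenance: str = "user", **updates: float) -> "ParameterSet":
        values = dict(self.values)
        prov = dict(self.provenance)
        for k, v in updates.items():
            values[k] = float(v)
            prov[k] = provenance
        return ParameterSet(values, dict(self.units), prov)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self.values == other.values

    # -- file round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "format": "il1p38-parameters-v1",
            "parameters": {
                name: {
                    "value": self.values[name],
                    "unit": self.units.get(name, ""),
                    "provenance": self.provenance.get(name, "user"),
                }
                for name in self.values
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, default_provenance: str = "user") -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "parameters" not in data:
            raise ConfigurationError(f"{path}: not a parameter file (no 'parameters')")
        values, units, prov = {}, {}, {}
        for name, entry in data["parameters"].items():
            if isinstance(entry, (int, float)):
                entry = {"value": entry}
            unit = entry.get("unit") or None
            if "half_life" in entry:
                if not str(name).startswith("beta_"):
                    raise ConfigurationError(
                        f"parameter {name!r}: half_life only applies to beta_* constants"
                    )
                t_half = _convert(name + "_half_life", float(entry["half_life"]),
                                  unit or "s")
                values[name] = math.log(2.0) / t_half
            elif "value" in entry:
                values[name] = _convert(name, float(entry["value"]), unit)
            else:
                raise ConfigurationError(f"parameter {name!r}: no value given")
            units[name] = PARAMETER_UNITS.get(name, unit or "")
            prov[name] = entry.get("provenance", default_provenance)
        return cls(values, units, prov)


def load_parameters(path) -> ParameterSet:
    """Load a parameter file, convert units, and validate completeness."""
    ps = ParameterSet.from_yaml(path)
    missing = ps.missing()
    if missing:
        raise ConfigurationError(
            f"parameter file {path} is missing constants: {', '.join(missing)}"
        )
    return ps


def default_parameters() -> ParameterSet:
    """The committed calibrated parameter set the package runs with
    out-of-the-box (provenance ``calibrated``)."""
    ref = resources.files("il1p38").joinpath("data/default_params.yaml")
    with resources.as_file(ref) as path:
        ps = ParameterSet.from_yaml(path, default_provenance="calibrated")
    missing = ps.missing()
    if missing:  # pragma: no cover - packaging defect
        raise ConfigurationError(f"default parameter file incomplete: {missing}")
    return ps


def sample_perturbations(base: ParameterSet, fold: float = 2.0, n: int = 10,
                         seed: int = 0) -> list[ParameterSet]:
    """Seeded ensemble of parameter sets for robustness scans.

    Every rate constant (all parameters except the ``level_*`` expression
    levels) is independently multiplied by a factor log-uniform in
    [1/fold, fold].  Reproducible: the same seed gives the same ensemble.
    """
    if not (fold > 1.0):
        raise InvalidArgumentError(f"fold must be > 1, got {fold}")
    if not (n > 0):
        raise InvalidArgumentError(f"n must be > 0, got {n}")
    rng = np.random.default_rng(seed)
    keys = [k for k in base.values if not k.startswith("level_")]
    out = []
    for _ in range(int(n)):
        factors = np.exp(rng.uniform(-math.log(fold), math.log(fold), len(keys)))
        updates = {k: base[k] * f for k, f in zip(keys, factors)}
        out.append(base.with_values(provenance="perturbed", **updates))
    return out
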