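"""Scenario runner for the in-silico experiments: dose scans, expression-level
scans, basal-activity panels and deletion panels.

Every scenario follows the same protocol: apply knockouts, apply expression
overrides, re-equilibrate the IL1 = 0 system to its basal fixed point,
add the IL-1 dose, integrate, and extract response features for each
observable relative to that scenario's own basal state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .features import ResponseFeatures, extract_features
from .model import OBSERVABLES, apply_knockout, set_expression_level
from .network import ModelSpec
from .simulate import SolverSettings, Trajectory, default_grid, find_basal_state, integrate

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "PanelResult",
    "run_scenario",
    "run_dose_scan",
    "run_level_scan",
    "run_basal_panel",
    "run_deletion_panel",
    "DELETION_PANEL",
]

#: the deletion panel of the knockout experiments (IL-1 at the reference dose)
DELETION_PANEL = (
    ("wild_type", ()),
    ("dTAB1", ("TAB1",)),
    ("dTAB2", ("TAB2",)),
    ("dMKP1", ("MKP1",)),
    ("dTAB1_dTAB2", ("TAB1", "TAB2")),
    ("dTAB1_dMKP1", ("TAB1", "MKP1")),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """One in-silico experiment: dose, expression overrides, knockouts."""

    label: str
    il1_dose: float = 0.0
    expression_overrides: dict = field(default_factory=dict)
    knockouts: tuple[str, ...] = ()
    horizon: float = 2e5  # s
    observables: tuple[str, ...] = OBSERVABLES

    def __post_init__(self):
        if self.il1_dose < 0:
            raise ConfigurationError(f"{self.label}: IL-1 dose must be >= 0")
        for prot, level in self.expression_overrides.items():
            if level < 0:
                raise ConfigurationError(
                    f"{self.label}: level of {prot} must be >= 0")
        clash = set(self.knockouts) & set(self.expression_overrides)
        if clash:
            raise ConfigurationError(
                f"{self.label}: {sorted(clash)} appear both as knockout and "
                "expression override")


@dataclass
class ScenarioResult:
    label: str
    trajectory: Trajectory
    features: dict[str, ResponseFeatures]
    basal: dict[str, float]  # per-observable basal value of this scenario
    basal_state: np.ndarray


@dataclass
class PanelResult:
    """Results of a family of scenarios, keyed by label."""

    results: dict[str, ScenarioResult]

    def __getitem__(self, label: str) -> ScenarioResult:
        return self.results[label]

    def __iter__(self):
        return iter(self.results.values())

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.results)

    def features_frame(self) -> pd.DataFrame:
        rows = []
        for res in self:
            for sp, f in res.features.items():
                rows.append(
                    {
                        "scenario": res.label,
                        "species": sp,
                        "peak_time_s": f.peak_time,
                        "peak_nM": f.peak_value,
                        "basal_nM": f.basal_value,
                        "time_to_basal_s": f.time_to_basal,
                        "terminal_nM": f.terminal_value,
                        "class": f.response_class,
                        "flags": ";".join(f.flags),
                    }
                )
        return pd.DataFrame(rows)


def run_scenario(base: ModelSpec, cfg: ScenarioConfig,
                 settings: SolverSettings | None = None) -> ScenarioResult:
    """Apply a scenario's perturbations, re-equilibrate, stimulate, integrate."""
    settings = settings or SolverSettings()
    settings = replace(settings, horizon=cfg.horizon)
    spec = base
    for prot in cfg.knockouts:
        spec = apply_knockout(spec, prot)
    for prot, level in cfg.expression_overrides.items():
        spec = set_expression_level(spec, prot, level, settings)
    basal_state = find_basal_state(spec.with_initial(IL1=0.0), settings)
    stim = spec.with_initial_state(basal_state).with_initial(IL1=float(cfg.il1_dose))
    traj = integrate(stim, settings, default_grid(cfg.horizon))
    names = stim.species_names
    basal = {sp: float(basal_state[names.index(sp)]) for sp in cfg.observables}
    feats = {sp: extract_features(traj, sp, basal[sp]) for sp in cfg.observables}
    return ScenarioResult(cfg.label, traj, feats, basal, basal_state)


def _panel(base, configs, settings) -> PanelResult:
    results = {}
    for cfg in configs:
        if cfg.label in results:
            raise ConfigurationError(f"duplicate scenario label {cfg.label!r}")
        results[cfg.label] = run_scenario(base, cfg, settings)
    return PanelResult(results)


def run_dose_scan(base: ModelSpec, doses, settings: SolverSettings | None = None,
                  horizon: float = 2e5) -> PanelResult:
    """One wild-type scenario per IL-1 dose."""
    doses = list(doses)
    if not doses:
        raise ConfigurationError("dose scan needs at least one dose")
    cfgs = [ScenarioConfig(label=f"dose_{d:g}", il1_dose=d, horizon=horizon)
            for d in doses]
    return _panel(base, cfgs, settings)


def run_level_scan(base: ModelSpec, protein: str, levels, dose: float,
                   settings: SolverSettings | None = None,
                   horizon: float = 2e5) -> PanelResult:
    """One scenario per expression level of ``protein``, all at ``dose``."""
    levels = list(levels)
    if not levels:
        raise ConfigurationError("level scan needs at least one level")
    cfgs = [
        ScenarioConfig(label=f"{protein}_{lvl:g}", il1_dose=dose,
                       expression_overrides={protein: lvl}, horizon=horizon)
        for lvl in levels
    ]
    return _panel(base, cfgs, settings)


def run_basal_panel(base: ModelSpec, protein: str, levels,
                    settings: SolverSettings | None = None,
                    horizon: float = 2e4) -> PanelResult:
    """Basal activity (IL-1 = 0) of the observables versus expression level."""
    levels = list(levels)
    if not levels:
        raise ConfigurationError("basal panel needs at least one level")
    cfgs = [
        ScenarioConfig(label=f"{protein}_{lvl:g}", il1_dose=0.0,
                       expression_overrides={protein: lvl}, horizon=horizon)
        for lvl in levels
    ]
    return _panel(base, cfgs, settings)


def run_deletion_panel(base: ModelSpec, settings: SolverSettings | None = None,
                       dose: float = 100.0, horizon: float = 2e5) -> PanelResult:
    """Wild type plus the single and double deletions of TAB1/TAB2/MKP1."""
    cfgs = [
        ScenarioConfig(label=label, il1_dose=dose, knockouts=kos, horizon=horizon)
        for label, kos in DELETION_PANEL
    ]
    return _panel(base, cfgs, settings)
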