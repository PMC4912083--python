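"""Publication-style figure panels for the in-silico experiments.

Each ``figure_*`` function recomputes its panel from scratch and returns a
matplotlib Figure laid out like the corresponding results figure: dose
scans of the nuclear and cytosolic responses, pMKK dynamics, the TAB1/TAB2,
TAB1/MKP1 and TAB2/MKP1 level scans, the basal-activity panels and the
deletion panel.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .experiments import (
    PanelResult,
    run_basal_panel,
    run_deletion_panel,
    run_dose_scan,
    run_level_scan,
)
from .network import ModelSpec
from .simulate import SolverSettings

__all__ = [
    "figure_dose_response",
    "figure_pmkk_dynamics",
    "figure_level_scan",
    "figure_basal_activity",
    "figure_deletion_panel",
    "FIGURE_BUILDERS",
]

ACUTE_WINDOW = 1500.0  # s, window showing the acute phase
FULL_WINDOW = 2e4  # s, window showing attainment of the steady state


def _plot_panel(ax, panel: PanelResult, species: str, tmax: float, title: str):
    for res in panel:
        m = res.trajectory.times <= tmax
        ax.plot(res.trajectory.times[m], res.trajectory[species][m], label=res.label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"{species} (nM)")
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=6)


def figure_dose_response(base: ModelSpec, settings: SolverSettings | None = None,
                         doses=(100.0, 1.0, 0.01, 0.0)) -> plt.Figure:
    """Nuclear and cytosolic pp38 under varied IL-1: acute phase and
    attainment of the steady state (four panels)."""
    panel = run_dose_scan(base, doses, settings)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    _plot_panel(axes[0, 0], panel, "pp38_nuc", ACUTE_WINDOW, "A  nuclear pp38, acute phase")
    _plot_panel(axes[0, 1], panel, "pp38_nuc", FULL_WINDOW, "B  nuclear pp38, to steady state")
    _plot_panel(axes[1, 0], panel, "pp38_cyt", ACUTE_WINDOW * 4, "C  cytosolic pp38, transient")
    _plot_panel(axes[1, 1], panel, "pp38_cyt", FULL_WINDOW, "D  cytosolic pp38, to steady state")
    fig.tight_layout()
    return fig


def figure_pmkk_dynamics(base: ModelSpec, settings: SolverSettings | None = None,
                         doses=(100.0, 1.0, 0.01, 0.0)) -> plt.Figure:
    """pMKK activation/deactivation and the mirrored inactive MKK (six panels)."""
    panel = run_dose_scan(base, doses, settings)
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    _plot_panel(axes[0, 0], panel, "pMKK", 600.0, "A  pMKK activation")
    _plot_panel(axes[0, 1], panel, "pMKK", 6000.0, "B  pMKK deactivation")
    _plot_panel(axes[0, 2], panel, "pMKK", FULL_WINDOW, "C  pMKK to steady state")
    _plot_panel(axes[1, 0], panel, "MKK", 600.0, "D  MKK, activation phase")
    _plot_panel(axes[1, 1], panel, "MKK", 6000.0, "E  MKK, deactivation phase")
    _plot_panel(axes[1, 2], panel, "MKK", FULL_WINDOW, "F  MKK to steady state")
    fig.tight_layout()
    return fig


def figure_level_scan(base: ModelSpec, protein_a: str, protein_b: str,
                      settings: SolverSettings | None = None,
                      folds=(0.5, 1.0, 2.0), dose: float = 100.0,
                      wildtype=None) -> plt.Figure:
    """Effect of varying two proteins around wild type on the three
    observables (five panels: nuclear acute/steady, cytosolic
    transient/steady, pMKK)."""
    from .model import WILDTYPE_LEVELS

    wildtype = wildtype or WILDTYPE_LEVELS
    panels = {}
    for prot in (protein_a, protein_b):
        levels = [f * wildtype[prot] for f in folds]
        panels[prot] = run_level_scan(base, prot, levels, dose, settings)
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    layout = [
        ("pp38_nuc", ACUTE_WINDOW, "nuclear pp38, acute phase", axes[0, 0]),
        ("pp38_nuc", FULL_WINDOW, "nuclear pp38, steady state", axes[0, 1]),
        ("pp38_cyt", ACUTE_WINDOW * 4, "cytosolic pp38, transient", axes[0, 2]),
        ("pp38_cyt", FULL_WINDOW, "cytosolic pp38, steady state", axes[1, 0]),
        ("pMKK", 6000.0, "pMKK dynamics", axes[1, 1]),
    ]
    for letter, (sp, tmax, title, ax) in zip("ABCDE", layout):
        for prot, panel in panels.items():
            for res in panel:
                m = res.trajectory.times <= tmax
                ax.plot(res.trajectory.times[m], res.trajectory[sp][m],
                        label=res.label)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(f"{sp} (nM)")
        ax.set_title(f"{letter}  {title}", fontsize=9)
        ax.legend(fontsize=6)
    axes[1, 2].axis("off")
    fig.tight_layout()
    return fig


def figure_basal_activity(base: ModelSpec, settings: SolverSettings | None = None,
                          folds=(0.5, 1.0, 2.0, 4.0)) -> plt.Figure:
    """Basal levels of the observables versus TAB1, TAB2 and MKP1 expression
    (no IL-1; six panels)."""
    from .model import WILDTYPE_LEVELS

    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    pairs = (("TAB1", "TAB2"), ("MKP1",))
    for row, prots in enumerate(pairs):
        for col, sp in enumerate(("pp38_nuc", "pp38_cyt", "pMKK")):
            ax = axes[row, col]
            for prot in prots:
                levels = [f * WILDTYPE_LEVELS[prot] for f in folds]
                panel = run_basal_panel(base, prot, levels, settings)
                vals = [res.basal[sp] for res in panel]
                ax.plot(folds, vals, "o-", label=prot)
            ax.set_xscale("log")
            ax.set_xlabel("fold of wild-type level")
            ax.set_ylabel(f"basal {sp} (nM)")
            ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def figure_deletion_panel(base: ModelSpec, settings: SolverSettings | None = None,
                          dose: float = 100.0) -> plt.Figure:
    """Wild type and TAB1/TAB2/MKP1 deletions at the reference dose
    (nuclear acute/steady, cytosolic, pMKK; four panels)."""
    panel = run_deletion_panel(base, settings, dose=dose)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    _plot_panel(axes[0, 0], panel, "pp38_nuc", ACUTE_WINDOW, "A  nuclear pp38, acute phase")
    _plot_panel(axes[0, 1], panel, "pp38_nuc", FULL_WINDOW, "B  nuclear pp38, to steady state")
    _plot_panel(axes[1, 0], panel, "pp38_cyt", FULL_WINDOW, "C  cytosolic pp38")
    _plot_panel(axes[1, 1], panel, "pMKK", 6000.0, "D  pMKK")
    fig.tight_layout()
    return fig


FIGURE_BUILDERS = {
    "dose_response": figure_dose_response,
    "pmkk_dynamics": figure_pmkk_dynamics,
    "tab1_tab2_scan": lambda base, settings=None: figure_level_scan(base, "TAB1", "TAB2", settings),
    "tab1_mkp1_scan": lambda base, settings=None: figure_level_scan(base, "TAB1", "MKP1", settings),
    "tab2_mkp1_scan": lambda base, settings=None: figure_level_scan(base, "TAB2", "MKP1", settings),
    "basal_activity": figure_basal_activity,
    "deletion_panel": figure_deletion_panel,
}
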