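"""The IL-1 -> p38alpha signaling network as an executable ModelSpec.

Pathway encoded (well-established arm): IL-1 binds its receptor pool
(IL-1RI + IL-1RAcP + MyD88 lumped into one step); the ligand-receptor
complex phosphorylates IRAK; pIRAK binds TRAF6 and then TAB2 at the
membrane, where IRAK is ubiquitinated and degraded, releasing a cytosolic
TAB2-TRAF6 complex that activates TAK1; pTAK1 phosphorylates MKK3/6, which
phosphorylates p38; phosphorylation-coupled nuclear import makes this pool
``pp38_nuc``.  MKP1 dephosphorylates nuclear pp38 and is itself induced by
it (negative feedback).  Independently, TAB1 binds TAK1 (activating it) and
binds p38 directly, driving p38 autophosphorylation into a
cytosolic/membrane pool ``pp38_cyt`` that never enters the nucleus; pTAK1
induces TAB1 post-transcriptionally (the hypothesized positive feedback).

IRAK is degraded but not resynthesized during stimulation, which is what
makes the IL-1 response transient.  TAB2, TRAF6, TAK1 and TAB1 undergo
alpha/beta turnover; MKP1 decays with a 40 min half-life.  All
dephosphorylations except MKP1's are first order (phosphatases in excess).
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ConfigurationError, ConvergenceError, InvalidArgumentError
from .network import (
    FIRST_ORDER_DECAY,
    MASS_ACTION,
    MICHAELIS_MENTEN,
    SATURATING_INDUCTION,
    ZERO_ORDER_PRODUCTION,
    ModelSpec,
    RateLaw,
    Reaction,
    Species,
)
from .parameters import REQUIRED_PARAMETERS, ParameterSet
from .simulate import SolverSettings, find_basal_state

__all__ = [
    "SPECIES_COMPARTMENTS",
    "ACTIVE_SPECIES",
    "OBSERVABLES",
    "WILDTYPE_LEVELS",
    "build_default_model",
    "apply_knockout",
    "set_expression_level",
    "stimulate",
    "stimulate_from_basal",
]

#: species registry: name -> compartment label
SPECIES_COMPARTMENTS = {
    "IL1": "membrane",
    "IL1R": "membrane",
    "IL1R_complex": "membrane",
    "IRAK": "cytosol",
    "pIRAK": "cytosol",
    "TRAF6": "cytosol",
    "pIRAK_TRAF6": "cytosol",
    "TAB2": "cytosol",
    "IRAK_TRAF6_TAB2": "membrane",
    "TAB2_TRAF6": "cytosol",
    "TAK1": "cytosol",
    "pTAK1": "cytosol",
    "TAB1": "cytosol",
    "TAB1_p38": "cytosol",
    "pp38_cyt": "cytosol",
    "MKK": "cytosol",
    "pMKK": "cytosol",
    "p38": "cytosol",
    "pp38_nuc": "nucleus",
    "MKP1": "nucleus",
}

#: phosphorylated/active species and complexes; all start at zero
ACTIVE_SPECIES = (
    "IL1R_complex",
    "pIRAK",
    "pIRAK_TRAF6",
    "IRAK_TRAF6_TAB2",
    "TAB2_TRAF6",
    "pTAK1",
    "TAB1_p38",
    "pp38_cyt",
    "pMKK",
    "pp38_nuc",
)

#: the three readouts the in-silico experiments track
OBSERVABLES = ("pp38_nuc", "pp38_cyt", "pMKK")

#: wild-type pre-stimulation levels (nM)
WILDTYPE_LEVELS = {"TAB1": 10.0, "TAB2": 100.0, "MKP1": 100.0}

IL1_REFERENCE_DOSE = 100.0  # nM

#: proteins with an alpha/beta turnover pair: name -> (level param, alpha, beta)
_TURNOVER = {
    "TAB2": ("level_tab2", "alpha_tab2", "beta_tab2"),
    "TRAF6": ("level_traf6", "alpha_traf6", "beta_traf6"),
    "TAK1": ("level_tak1", "alpha_tak1", "beta_tak1"),
    "TAB1": ("level_tab1", "alpha_tab1", "beta_tab1"),
    "MKP1": ("level_mkp1", "alpha_mkp1", "beta_mkp1"),
}

_LEVEL_PARAMS = {
    "IL1R": "level_il1r",
    "IRAK": "level_irak",
    "TRAF6": "level_traf6",
    "TAB2": "level_tab2",
    "TAK1": "level_tak1",
    "TAB1": "level_tab1",
    "MKK": "level_mkk",
    "p38": "level_p38",
    "MKP1": "level_mkp1",
}


def build_default_model(params: ParameterSet) -> ModelSpec:
    """Encode the full IL-1/p38 network from ``params``.

    Raises :class:`ConfigurationError` naming any missing rate constant.
    All active species start at zero; basal activity emerges from relaxing
    the unstimulated system (see :func:`stimulate`).
    """
    missing = params.missing(REQUIRED_PARAMETERS)
    if missing:
        raise ConfigurationError(
            "parameter set is missing rate constants: " + ", ".join(missing)
        )

    def init(name: str) -> float:
        if name == "IL1" or name in ACTIVE_SPECIES:
            return 0.0
        return params[_LEVEL_PARAMS[name]]

    species = [
        Species(name, comp, init(name)) for name, comp in SPECIES_COMPARTMENTS.items()
    ]

    ma = lambda k: RateLaw(MASS_ACTION, {"k": params[k]})
    mm = lambda kcat, km: RateLaw(MICHAELIS_MENTEN,
                                  {"kcat": params[kcat], "Km": params[km]})
    prod = lambda a: RateLaw(ZERO_ORDER_PRODUCTION, {"alpha": params[a]})
    decay = lambda b: RateLaw(FIRST_ORDER_DECAY, {"beta": params[b]})
    induce = lambda v, k: RateLaw(SATURATING_INDUCTION,
                                  {"Vmax": params[v], "K": params[k]})

    reactions = [
        # (1) ligand-receptor assembly (MyD88/IL-1RAcP lumped into the pool)
        Reaction("il1_receptor_binding", [("IL1", 1), ("IL1R", 1)],
                 [("IL1R_complex", 1)], ma("kon_il1_receptor")),
        # (2) receptor-complex-catalysed IRAK phosphorylation
        Reaction("irak_phosphorylation", [("IRAK", 1)], [("pIRAK", 1)],
                 mm("kcat_irak", "km_irak"), modifiers=["IL1R_complex"]),
        # (3) pIRAK-TRAF6 binding, then TAB2 joins at the membrane
        Reaction("pirak_traf6_binding", [("pIRAK", 1), ("TRAF6", 1)],
                 [("pIRAK_TRAF6", 1)], ma("kon_pirak_traf6")),
        Reaction("membrane_complex_assembly", [("pIRAK_TRAF6", 1), ("TAB2", 1)],
                 [("IRAK_TRAF6_TAB2", 1)], ma("kon_tab2_membrane")),
        # (4) IRAK ubiquitination/degradation releases cytosolic TAB2-TRAF6
        Reaction("irak_degradation_release", [("IRAK_TRAF6_TAB2", 1)],
                 [("TAB2_TRAF6", 1)], ma("kdeg_irak")),
        # (5) TAB2-TRAF6-dependent TAK1 activation (IL-1 arm)
        Reaction("tak1_activation_by_tab2_traf6", [("TAK1", 1)], [("pTAK1", 1)],
                 mm("kcat_tak1", "km_tak1"), modifiers=["TAB2_TRAF6"]),
        # IL-1-coupled degradation of the TAB2-TRAF6 complex (removes both)
        Reaction("tab2_traf6_degradation", [("TAB2_TRAF6", 1)], [],
                 decay("beta_tab2_traf6")),
        # (6) TAB1-dependent TAK1 activation: backward arm of the positive loop
        Reaction("tak1_activation_by_tab1", [("TAK1", 1)], [("pTAK1", 1)],
                 ma("k_tab1_tak1"), modifiers=["TAB1"]),
        Reaction("ptak1_dephosphorylation", [("pTAK1", 1)], [("TAK1", 1)],
                 ma("kdephos_ptak1")),
        Reaction("ptak1_degradation", [("pTAK1", 1)], [], decay("beta_ptak1")),
        # (7) pTAK1-induced TAB1 production: forward arm of the positive loop
        Reaction("tab1_production_induced", [], [("TAB1", 1)],
                 induce("vmax_tab1_induction", "k_tab1_induction"),
                 modifiers=["pTAK1"]),
        # (8) MKK3/6 activation by pTAK1; excess-phosphatase reversal
        Reaction("mkk_phosphorylation", [("MKK", 1)], [("pMKK", 1)],
                 mm("kcat_mkk", "km_mkk"), modifiers=["pTAK1"]),
        Reaction("pmkk_dephosphorylation", [("pMKK", 1)], [("MKK", 1)],
                 ma("kdephos_pmkk")),
        # (9) p38 phosphorylation by pMKK; the product is born nuclear
        Reaction("p38_phosphorylation_nuclear", [("p38", 1)], [("pp38_nuc", 1)],
                 mm("kcat_p38", "km_p38"), modifiers=["pMKK"]),
        # (10) MKP1-catalysed dephosphorylation of nuclear pp38
        Reaction("pp38_dephosphorylation_by_mkp1", [("pp38_nuc", 1)], [("p38", 1)],
                 mm("kcat_mkp1", "km_mkp1"), modifiers=["MKP1"]),
        # (11) MKP1 turnover: basal + pp38_nuc-induced production, 40 min half-life
        Reaction("mkp1_production_basal", [], [("MKP1", 1)], prod("alpha_mkp1")),
        Reaction("mkp1_production_induced", [], [("MKP1", 1)],
                 induce("vmax_mkp1_induction", "k_mkp1_induction"),
                 modifiers=["pp38_nuc"]),
        Reaction("mkp1_decay", [("MKP1", 1)], [], decay("beta_mkp1")),
        # (12) TAB1-p38 binding and autophosphorylation -> cytosolic pp38,
        #      which never enters the nucleus; first-order return (excess
        #      phosphatase) lets the membrane response relax to basal
        Reaction("tab1_p38_binding", [("TAB1", 1), ("p38", 1)],
                 [("TAB1_p38", 1)], ma("kon_tab1_p38")),
        Reaction("tab1_p38_dissociation", [("TAB1_p38", 1)],
                 [("TAB1", 1), ("p38", 1)], ma("koff_tab1_p38")),
        Reaction("p38_autophosphorylation", [("TAB1_p38", 1)], [("pp38_cyt", 1)],
                 ma("kauto_p38")),
        Reaction("pp38_cyt_dephosphorylation", [("pp38_cyt", 1)], [("TAB1_p38", 1)],
                 ma("kdephos_pp38cyt")),
        # (13) alpha/beta turnover of TAB2, TRAF6, TAK1, TAB1 (free forms;
        #      complexed protein is protected from basal turnover)
        Reaction("tab2_production_basal", [], [("TAB2", 1)], prod("alpha_tab2")),
        Reaction("tab2_decay", [("TAB2", 1)], [], decay("beta_tab2")),
        Reaction("traf6_production_basal", [], [("TRAF6", 1)], prod("alpha_traf6")),
        Reaction("traf6_decay", [("TRAF6", 1)], [], decay("beta_traf6")),
        Reaction("tak1_production_basal", [], [("TAK1", 1)], prod("alpha_tak1")),
        Reaction("tak1_decay", [("TAK1", 1)], [], decay("beta_tak1")),
        Reaction("tab1_production_basal", [], [("TAB1", 1)], prod("alpha_tab1")),
        Reaction("tab1_decay", [("TAB1", 1)], [], decay("beta_tab1")),
        # (14) IRAK has no production reaction: degradation only.
    ]

    conserved = [
        frozenset({"MKK", "pMKK"}),
        frozenset({"p38", "pp38_nuc", "TAB1_p38", "pp38_cyt"}),
    ]
    spec = ModelSpec(species, reactions, conserved)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# perturbation protocol


def _production_reactions(spec: ModelSpec, protein: str) -> list[str]:
    """Names of zero-order/induced production reactions making ``protein``."""
    out = []
    for r in spec.reactions:
        if r.rate_law.kind in (ZERO_ORDER_PRODUCTION, SATURATING_INDUCTION):
            if any(sp == protein for sp, _ in r.products):
                out.append(r.name)
    return out


def apply_knockout(spec: ModelSpec, protein: str) -> ModelSpec:
    """Abolish ``protein``: zero its pre-stimulation level and every
    production rate, including feedback-induced production.

    Intended for pre-stimulation specs (complexes empty); all other
    reactions are left intact.
    """
    if protein not in spec.species_names:
        raise ConfigurationError(f"cannot knock out unknown protein {protein!r}")
    new = spec.with_initial(**{protein: 0.0})
    for rname in _production_reactions(spec, protein):
        r = new.get_reaction(rname)
        const = "alpha" if r.rate_law.kind == ZERO_ORDER_PRODUCTION else "Vmax"
        new = new.with_rate_constant(rname, const, 0.0)
    return new


def set_expression_level(spec: ModelSpec, protein: str, level: float,
                         settings: SolverSettings | None = None,
                         rel_tol: float = 1e-8, max_iter: int = 25) -> ModelSpec:
    """Retarget a turnover protein's pre-stimulation level by rescaling its
    basal production rate alpha.

    The relaxed unstimulated free concentration of ``protein`` is driven to
    ``level`` (within ``rel_tol`` relative) by an iterative alpha update:
    feedback-induced production terms are left untouched, so for TAB1 and
    MKP1 the basal alpha absorbs the complement of the induced share.
    ``level = 0`` reproduces :func:`apply_knockout`.
    """
    if level < 0:
        raise InvalidArgumentError(f"expression level must be >= 0, got {level}")
    basal_name = f"{protein.lower()}_production_basal"
    decay_name = f"{protein.lower()}_decay"
    try:
        spec.get_reaction(basal_name)
        beta = spec.get_reaction(decay_name).rate_law["beta"]
    except Exception:
        raise ConfigurationError(
            f"protein {protein!r} has no alpha/beta turnover pair"
        ) from None
    if level == 0.0:
        return apply_knockout(spec, protein)

    settings = settings or SolverSettings()
    alpha = beta * level  # exact in the absence of induction/consumption
    new = spec
    for _ in range(max_iter):
        new = spec.with_rate_constant(basal_name, "alpha", alpha)
        new = new.with_initial(**{protein: level, "IL1": 0.0})
        basal = find_basal_state(new, settings)
        realized = basal[new.index(protein)]
        err = (realized - level) / level
        if abs(err) <= rel_tol:
            break
        alpha = max(alpha + beta * (level - realized), 0.0)
        if alpha == 0.0 and realized > level:
            # induced production alone overshoots the target level
            raise ConfigurationError(
                f"cannot reach {protein} level {level} nM: feedback induction "
                f"alone sustains {realized:.3g} nM"
            )
    else:
        raise ConvergenceError(
            f"expression-level calibration for {protein} did not converge "
            f"(last realized {realized:.6g} nM for target {level} nM)",
            residual=abs(err))
    # restore the caller's IL1 initial
    return new.with_initial(IL1=spec.get_species("IL1").initial_concentration)


def stimulate_from_basal(spec: ModelSpec, il1_dose: float,
                         settings: SolverSettings | None = None):
    """Relax the IL1 = 0 system to its basal fixed point, then add IL-1.

    Returns ``(stimulated_spec, basal_state)``: the spec's initial state is
    the basal state with the IL1 species set to ``il1_dose``.  IL-1 is
    neither produced nor degraded (sustained presence); it is only consumed
    by receptor binding.
    """
    if il1_dose < 0:
        raise InvalidArgumentError(f"IL-1 dose must be >= 0, got {il1_dose}")
    settings = settings or SolverSettings()
    basal = find_basal_state(spec.with_initial(IL1=0.0), settings)
    stim = spec.with_initial_state(basal).with_initial(IL1=float(il1_dose))
    return stim, basal


def stimulate(spec: ModelSpec, il1_dose: float,
              settings: SolverSettings | None = None) -> ModelSpec:
    """Convenience wrapper around :func:`stimulate_from_basal`."""
    stim, _ = stimulate_from_basal(spec, il1_dose, settings)
    return stim
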