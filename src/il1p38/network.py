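"""Biochemical reaction networks and assembly of their ODE right-hand sides.

A :class:`ModelSpec` is a list of :class:`Species` and :class:`Reaction`
objects plus optional conserved groups.  Reactions carry one of five rate
laws:

``mass_action``
    rate = k * prod(reactant^stoichiometry) * prod(modifiers); covers
    bimolecular binding (k in 1/(nM*s)) and first-order conversions (k in
    1/s).  Modifiers are catalysts: they multiply the rate but are not
    consumed.
``michaelis_menten``
    rate = kcat * [E] * [S] / (Km + [S]) with the enzyme E as the single
    modifier and the substrate S as the single reactant.  The enzyme is kept
    explicit (no lumped Vmax) so varying enzyme expression propagates.
``zero_order_production``
    rate = alpha (nM/s), constant synthesis.
``first_order_decay``
    rate = beta * [X] (1/s), degradation to nothing.
``saturating_induction``
    rate = Vmax * [X] / (K + [X]) with inducer X as the single modifier;
    a bounded production term used for feedback-induced synthesis.

Units are fixed at nM and seconds throughout.  Compartment labels
(membrane / cytosol / nucleus) are bookkeeping only: every species lives in
one well-mixed concentration frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import InvalidArgumentError, SpecificationError

__all__ = [
    "COMPARTMENTS",
    "MASS_ACTION",
    "MICHAELIS_MENTEN",
    "ZERO_ORDER_PRODUCTION",
    "FIRST_ORDER_DECAY",
    "SATURATING_INDUCTION",
    "Species",
    "RateLaw",
    "Reaction",
    "ModelSpec",
    "mass_action_rate",
    "michaelis_menten_rate",
    "assemble_odes",
    "check_conservation",
]

COMPARTMENTS = ("membrane", "cytosol", "nucleus")

MASS_ACTION = "mass_action"
MICHAELIS_MENTEN = "michaelis_menten"
ZERO_ORDER_PRODUCTION = "zero_order_production"
FIRST_ORDER_DECAY = "first_order_decay"
SATURATING_INDUCTION = "saturating_induction"

#: constants each rate-law kind must provide
RATE_LAW_CONSTANTS = {
    MASS_ACTION: ("k",),
    MICHAELIS_MENTEN: ("kcat", "Km"),
    ZERO_ORDER_PRODUCTION: ("alpha",),
    FIRST_ORDER_DECAY: ("beta",),
    SATURATING_INDUCTION: ("Vmax", "K"),
}


@dataclass(frozen=True)
class Species:
    """One chemical species: a name, a compartment label and an initial level (nM)."""

    name: str
    compartment_label: str = "cytosol"
    initial_concentration: float = 0.0

    def __post_init__(self):
        if not self.name or not isinstance(self.name, str):
            raise SpecificationError("species name must be a non-empty string")
        if self.compartment_label not in COMPARTMENTS:
            raise SpecificationError(
                f"unknown compartment {self.compartment_label!r} for species "
                f"{self.name!r}; expected one of {COMPARTMENTS}"
            )
        if not (self.initial_concentration >= 0.0):
            raise InvalidArgumentError(
                f"initial concentration of {self.name!r} must be >= 0, got "
                f"{self.initial_concentration}"
            )


@dataclass(frozen=True)
class RateLaw:
    """A rate-law kind plus its named constants (see module docstring for units)."""

    kind: str
    constants: Mapping[str, float]

    def __post_init__(self):
        if self.kind not in RATE_LAW_CONSTANTS:
            raise SpecificationError(f"unknown rate-law kind {self.kind!r}")
        object.__setattr__(self, "constants", dict(self.constants))
        required = RATE_LAW_CONSTANTS[self.kind]
        missing = [c for c in required if c not in self.constants]
        if missing:
            raise SpecificationError(
                f"rate law {self.kind!r} missing constants {missing}"
            )
        for name, value in self.constants.items():
            if not (float(value) >= 0.0):
                raise InvalidArgumentError(
                    f"rate constant {name}={value} must be >= 0"
                )
        if self.kind == MICHAELIS_MENTEN and not (self.constants["Km"] > 0.0):
            raise InvalidArgumentError("Michaelis constant Km must be > 0")
        if self.kind == SATURATING_INDUCTION and not (self.constants["K"] > 0.0):
            raise InvalidArgumentError("induction constant K must be > 0")

    def __getitem__(self, name: str) -> float:
        return float(self.constants[name])

    def with_constant(self, name: str, value: float) -> "RateLaw":
        c = dict(self.constants)
        c[name] = float(value)
        return RateLaw(self.kind, c)


def _norm_stoich(pairs) -> tuple[tuple[str, int], ...]:
    out = []
    for sp, st in pairs:
        st = int(st)
        if st <= 0:
            raise SpecificationError(f"stoichiometry for {sp!r} must be a positive integer")
        out.append((str(sp), st))
    return tuple(out)


@dataclass(frozen=True)
class Reaction:
    """A reaction: reactants/products with stoichiometry, catalytic modifiers, rate law.

    Modifiers appear in the rate but are neither consumed nor produced.
    """

    name: str
    reactants: Sequence[tuple[str, int]]
    products: Sequence[tuple[str, int]]
    rate_law: RateLaw
    modifiers: Sequence[str] = ()

    def __post_init__(self):
        object.__setattr__(self, "reactants", _norm_stoich(self.reactants))
        object.__setattr__(self, "products", _norm_stoich(self.products))
        object.__setattr__(self, "modifiers", tuple(str(m) for m in self.modifiers))
        kind = self.rate_law.kind
        if kind == MICHAELIS_MENTEN:
            if len(self.reactants) != 1 or self.reactants[0][1] != 1:
                raise SpecificationError(
                    f"{self.name}: a Michaelis-Menten reaction needs exactly one "
                    "substrate with stoichiometry 1"
                )
            if len(self.modifiers) != 1:
                raise SpecificationError(
                    f"{self.name}: a Michaelis-Menten reaction needs exactly one "
                    "enzyme modifier"
                )
        elif kind == ZERO_ORDER_PRODUCTION:
            if self.reactants or self.modifiers:
                raise SpecificationError(
                    f"{self.name}: zero-order production takes no reactants/modifiers"
                )
            if not self.products:
                raise SpecificationError(f"{self.name}: production needs a product")
        elif kind == FIRST_ORDER_DECAY:
            if len(self.reactants) != 1 or self.reactants[0][1] != 1 or self.products:
                raise SpecificationError(
                    f"{self.name}: first-order decay is one species -> nothing"
                )
        elif kind == SATURATING_INDUCTION:
            if self.reactants or len(self.modifiers) != 1 or not self.products:
                raise SpecificationError(
                    f"{self.name}: saturating induction is nothing -> product with "
                    "exactly one inducer modifier"
                )
        elif kind == MASS_ACTION:
            if not self.reactants:
                raise SpecificationError(
                    f"{self.name}: a mass-action reaction needs at least one reactant"
                )

    def species_referenced(self) -> set[str]:
        return (
            {s for s, _ in self.reactants}
            | {s for s, _ in self.products}
            | set(self.modifiers)
        )


@dataclass
class ModelSpec:
    """Executable description of a reaction network.

    ``conserved_groups`` lists sets of species names whose summed concentration
    is expected to stay constant (e.g. a kinase and its phospho-form when the
    protein is not turned over); :meth:`validate` checks each group is
    structurally conserved by every reaction.
    """

    species: list[Species]
    reactions: list[Reaction]
    conserved_groups: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self):
        self.species = list(self.species)
        self.reactions = list(self.reactions)
        self.conserved_groups = [frozenset(g) for g in self.conserved_groups]

    # -- lookup helpers -----------------------------------------------------

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise SpecificationError(f"unknown species {name!r}") from None

    def get_species(self, name: str) -> Species:
        return self.species[self.index(name)]

    def get_reaction(self, name: str) -> Reaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise SpecificationError(f"unknown reaction {name!r}")

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], float)

    # -- functional updates -------------------------------------------------

    def copy(self) -> "ModelSpec":
        return ModelSpec(list(self.species), list(self.reactions),
                         list(self.conserved_groups))

    def with_initial(self, **levels: float) -> "ModelSpec":
        """New spec with the named species' initial concentrations replaced."""
        new = self.copy()
        for name, value in levels.items():
            i = new.index(name)
            new.species[i] = replace(new.species[i], initial_concentration=float(value))
        return new

    def with_initial_state(self, state: np.ndarray) -> "ModelSpec":
        state = np.asarray(state, float)
        if state.shape != (len(self.species),):
            raise InvalidArgumentError(
                f"state has shape {state.shape}, expected ({len(self.species)},)"
            )
        new = self.copy()
        for i, s in enumerate(new.species):
            new.species[i] = replace(s, initial_concentration=max(float(state[i]), 0.0))
        return new

    def with_rate_constant(self, reaction: str, constant: str, value: float) -> "ModelSpec":
        new = self.copy()
        for i, r in enumerate(new.reactions):
            if r.name == reaction:
                new.reactions[i] = replace(r, rate_law=r.rate_law.with_constant(constant, value))
                return new
        raise SpecificationError(f"unknown reaction {reaction!r}")

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        names = self.species_names
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SpecificationError(f"duplicate species names: {dup}")
        known = set(names)
        rnames = [r.name for r in self.reactions]
        if len(set(rnames)) != len(rnames):
            dup = sorted({n for n in rnames if rnames.count(n) > 1})
            raise SpecificationError(f"duplicate reaction names: {dup}")
        for r in self.reactions:
            unknown = r.species_referenced() - known
            if unknown:
                raise SpecificationError(
                    f"reaction {r.name!r} references unknown species {sorted(unknown)}"
                )
        for group in self.conserved_groups:
            unknown = set(group) - known
            if unknown:
                raise SpecificationError(
                    f"conserved group references unknown species {sorted(unknown)}"
                )
            for r in self.reactions:
                net = sum(st for sp, st in r.products if sp in group) - sum(
                    st for sp, st in r.reactants if sp in group
                )
                if net != 0:
                    raise SpecificationError(
                        f"conserved group {sorted(group)} is changed by reaction "
                        f"{r.name!r} (net {net:+d})"
                    )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": [
                {
                    "name": s.name,
                    "compartment": s.compartment_label,
                    "initial_nM": s.initial_concentration,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "name": r.name,
                    "reactants": {sp: st for sp, st in r.reactants},
                    "products": {sp: st for sp, st in r.products},
                    "modifiers": list(r.modifiers),
                    "rate_law": {"kind": r.rate_law.kind,
                                 **{k: float(v) for k, v in r.rate_law.constants.items()}},
                }
                for r in self.reactions
            ],
            "conserved_groups": [sorted(g) for g in self.conserved_groups],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelSpec":
        species = [
            Species(d["name"], d.get("compartment", "cytosol"),
                    float(d.get("initial_nM", 0.0)))
            for d in data["species"]
        ]
        reactions = []
        for d in data["reactions"]:
            law = dict(d["rate_law"])
            kind = law.pop("kind")
            reactions.append(
                Reaction(
                    name=d["name"],
                    reactants=list(d.get("reactants", {}).items()),
                    products=list(d.get("products", {}).items()),
                    modifiers=d.get("modifiers", []),
                    rate_law=RateLaw(kind, law),
                )
            )
        groups = [frozenset(g) for g in data.get("conserved_groups", [])]
        spec = cls(species, reactions, groups)
        spec.validate()
        return spec

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# rate-law evaluation


def mass_action_rate(k: float, reactant_concentrations: Iterable[float],
                     stoichiometries: Iterable[int] | None = None) -> float:
    """Law-of-mass-action rate k * prod(c_i ** s_i) in nM/s.

    ``stoichiometries`` defaults to 1 for every reactant.
    """
    if not (k >= 0.0):
        raise InvalidArgumentError(f"rate constant must be >= 0, got {k}")
    conc = [float(c) for c in reactant_concentrations]
    if any(c < 0.0 for c in conc):
        raise InvalidArgumentError("concentrations must be >= 0")
    if stoichiometries is None:
        stoich = [1] * len(conc)
    else:
        stoich = [int(s) for s in stoichiometries]
        if len(stoich) != len(conc):
            raise InvalidArgumentError("stoichiometries must match concentrations")
        if any(s <= 0 for s in stoich):
            raise InvalidArgumentError("stoichiometries must be positive")
    rate = float(k)
    for c, s in zip(conc, stoich):
        rate *= c ** s
    return rate


def michaelis_menten_rate(k_cat: float, Km: float, substrate: float,
                          enzyme: float) -> float:
    """Michaelis-Menten rate k_cat * E * S / (Km + S) in nM/s."""
    if not (Km > 0.0):
        raise InvalidArgumentError(f"Km must be > 0, got {Km}")
    if not (k_cat >= 0.0):
        raise InvalidArgumentError(f"k_cat must be >= 0, got {k_cat}")
    if substrate < 0.0 or enzyme < 0.0:
        raise InvalidArgumentError("substrate and enzyme must be >= 0")
    return float(k_cat) * float(enzyme) * float(substrate) / (float(Km) + float(substrate))


def saturating_induction_rate(Vmax: float, K: float, inducer: float) -> float:
    """Bounded induced-production rate Vmax * X / (K + X) in nM/s."""
    if not (K > 0.0):
        raise InvalidArgumentError(f"K must be > 0, got {K}")
    if not (Vmax >= 0.0) or inducer < 0.0:
        raise InvalidArgumentError("Vmax and inducer must be >= 0")
    return float(Vmax) * float(inducer) / (float(K) + float(inducer))


# ---------------------------------------------------------------------------
# ODE assembly


def assemble_odes(spec: ModelSpec):
    """Compile ``spec`` into a vectorized derivative function f(t, x) -> dx/dt.

    For each species, d/dt is the stoichiometry-signed sum of the rates of the
    reactions touching it; modifiers are not consumed.  The state is clipped
    at zero inside the evaluation so tiny negative excursions from the
    integrator cannot feed back into the dynamics.
    """
    spec.validate()
    idx = {name: i for i, name in enumerate(spec.species_names)}
    n_sp, n_rx = len(spec.species), len(spec.reactions)

    stoich = np.zeros((n_sp, n_rx))
    base = np.zeros(n_rx)  # k / beta / alpha prefactor per reaction
    fac_rx: list[int] = []  # multiplicative concentration factors (mass action)
    fac_sp: list[int] = []
    mm_rx, mm_sub, mm_enz, mm_kcat, mm_km = [], [], [], [], []
    ind_rx, ind_mod, ind_vmax, ind_k = [], [], [], []

    for j, r in enumerate(spec.reactions):
        for sp, st in r.reactants:
            stoich[idx[sp], j] -= st
        for sp, st in r.products:
            stoich[idx[sp], j] += st
        law = r.rate_law
        if law.kind in (MASS_ACTION, FIRST_ORDER_DECAY):
            base[j] = law["k"] if law.kind == MASS_ACTION else law["beta"]
            for sp, st in r.reactants:
                fac_rx.extend([j] * st)
                fac_sp.extend([idx[sp]] * st)
            for m in r.modifiers:
                fac_rx.append(j)
                fac_sp.append(idx[m])
        elif law.kind == ZERO_ORDER_PRODUCTION:
            base[j] = law["alpha"]
        elif law.kind == MICHAELIS_MENTEN:
            mm_rx.append(j)
            mm_sub.append(idx[r.reactants[0][0]])
            mm_enz.append(idx[r.modifiers[0]])
            mm_kcat.append(law["kcat"])
            mm_km.append(law["Km"])
        elif law.kind == SATURATING_INDUCTION:
            ind_rx.append(j)
            ind_mod.append(idx[r.modifiers[0]])
            ind_vmax.append(law["Vmax"])
            ind_k.append(law["K"])

    fac_rx_a = np.asarray(fac_rx, int)
    fac_sp_a = np.asarray(fac_sp, int)
    mm_rx_a = np.asarray(mm_rx, int)
    mm_sub_a = np.asarray(mm_sub, int)
    mm_enz_a = np.asarray(mm_enz, int)
    mm_kcat_a = np.asarray(mm_kcat, float)
    mm_km_a = np.asarray(mm_km, float)
    ind_rx_a = np.asarray(ind_rx, int)
    ind_mod_a = np.asarray(ind_mod, int)
    ind_vmax_a = np.asarray(ind_vmax, float)
    ind_k_a = np.asarray(ind_k, float)

    def rhs(t, x):
        xc = np.maximum(x, 0.0)
        rates = base.copy()
        if fac_rx_a.size:
            np.multiply.at(rates, fac_rx_a, xc[fac_sp_a])
        if mm_rx_a.size:
            s = xc[mm_sub_a]
            rates[mm_rx_a] = mm_kcat_a * xc[mm_enz_a] * s / (mm_km_a + s)
        if ind_rx_a.size:
            m = xc[ind_mod_a]
            rates[ind_rx_a] = ind_vmax_a * m / (ind_k_a + m)
        return stoich @ rates

    return rhs


def check_conservation(spec: ModelSpec, trajectory, tol: float = 1e-6) -> dict:
    """Verify each declared conserved group along ``trajectory``.

    Returns ``{group_key: {"passed": bool, "max_rel_dev": float}}`` where the
    deviation is max over time of |group sum - initial sum| / initial sum.
    """
    spec.validate()
    results = {}
    for group in spec.conserved_groups:
        missing = set(group) - set(trajectory.species_order)
        if missing:
            raise SpecificationError(
                f"trajectory lacks species {sorted(missing)} of conserved group"
            )
        cols = [trajectory.species_order.index(s) for s in sorted(group)]
        total = trajectory.states[:, cols].sum(axis=1)
        ref = total[0]
        if ref <= 0.0:
            # group starts empty; require it to stay empty in absolute terms
            dev = float(np.max(np.abs(total)))
            passed = dev <= tol
        else:
            dev = float(np.max(np.abs(total - ref)) / ref)
            passed = dev <= tol
        results["+".join(sorted(group))] = {"passed": bool(passed), "max_rel_dev": dev}
    return results
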