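"""Rate laws, ODE assembly against a brute-force oracle, conservation checks
and ModelSpec validation/serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from il1p38 import (
    InvalidArgumentError,
    ModelSpec,
    RateLaw,
    Reaction,
    SolverSettings,
    Species,
    SpecificationError,
    assemble_odes,
    check_conservation,
    integrate,
    mass_action_rate,
    michaelis_menten_rate,
)
from il1p38.network import (
    FIRST_ORDER_DECAY,
    MASS_ACTION,
    MICHAELIS_MENTEN,
    SATURATING_INDUCTION,
    ZERO_ORDER_PRODUCTION,
)


# ---------------------------------------------------------------------------
# elementary rate laws


@pytest.mark.parametrize(
    "k,conc,stoich,expected",
    [
        (0.0, [3.0, 7.0], None, 0.0),
        (2.0, [3.0, 4.0], None, 24.0),
        (1.0, [5.0], [2], 25.0),
    ],
)
def test_mass_action_rate_product_law(k, conc, stoich, expected):
    assert mass_action_rate(k, conc, stoich) == pytest.approx(expected)


def test_mass_action_rate_rejects_negative_inputs():
    with pytest.raises(InvalidArgumentError):
        mass_action_rate(-1.0, [1.0])
    with pytest.raises(InvalidArgumentError):
        mass_action_rate(1.0, [-1.0])


def test_michaelis_menten_limits():
    # no substrate -> no flux
    assert michaelis_menten_rate(3.0, 10.0, 0.0, 5.0) == 0.0
    # half saturation at S = Km
    assert michaelis_menten_rate(3.0, 10.0, 10.0, 5.0) == pytest.approx(3.0 * 5.0 / 2)
    # saturation: S >> Km approaches kcat * E
    v = michaelis_menten_rate(3.0, 10.0, 1e7, 5.0)
    assert v == pytest.approx(15.0, rel=1e-4)
    with pytest.raises(InvalidArgumentError):
        michaelis_menten_rate(3.0, 0.0, 1.0, 1.0)


conc = st.floats(0.0, 1e4, allow_nan=False, allow_infinity=False)


@hyp_settings(derandomize=True, max_examples=50)
@given(kcat=st.floats(0.0, 100.0), km=st.floats(1e-3, 1e4), s=conc, e=conc)
def test_michaelis_menten_is_bounded_and_monotone(kcat, km, s, e):
    v = michaelis_menten_rate(kcat, km, s, e)
    assert 0.0 <= v <= kcat * e + 1e-12
    assert michaelis_menten_rate(kcat, km, 2 * s, e) >= v  # monotone in substrate


@hyp_settings(derandomize=True, max_examples=50)
@given(k=st.floats(0.0, 10.0), a=conc, b=conc, lam=st.floats(0.0, 10.0))
def test_mass_action_is_multilinear(k, a, b, lam):
    base = mass_action_rate(k, [a, b])
    assert mass_action_rate(k, [lam * a, b]) == pytest.approx(lam * base, rel=1e-9,
                                                              abs=1e-9)
    assert mass_action_rate(lam * k, [a, b]) == pytest.approx(lam * base, rel=1e-9,
                                                              abs=1e-9)


# ---------------------------------------------------------------------------
# ODE assembly


def turnover_spec(alpha=0.02, beta=1e-3, x0=0.0):
    return ModelSpec(
        [Species("X", "cytosol", x0)],
        [
            Reaction("x_production_basal", [], [("X", 1)],
                     RateLaw(ZERO_ORDER_PRODUCTION, {"alpha": alpha})),
            Reaction("x_decay", [("X", 1)], [],
                     RateLaw(FIRST_ORDER_DECAY, {"beta": beta})),
        ],
    )


def test_turnover_fixed_point_is_alpha_over_beta():
    spec = turnover_spec(alpha=0.02, beta=1e-3)
    rhs = assemble_odes(spec)
    assert rhs(0.0, np.array([0.02 / 1e-3])) == pytest.approx(0.0, abs=1e-15)


def test_empty_reaction_list_gives_zero_derivative():
    spec = ModelSpec([Species("A"), Species("B", "nucleus", 3.0)], [])
    rhs = assemble_odes(spec)
    assert np.all(rhs(0.0, np.array([1.0, 2.0])) == 0.0)


def test_interconversion_conserves_total():
    spec = ModelSpec(
        [Species("MKK", "cytosol", 80.0), Species("pMKK", "cytosol", 0.0),
         Species("E", "cytosol", 5.0)],
        [
            Reaction("fwd", [("MKK", 1)], [("pMKK", 1)],
                     RateLaw(MICHAELIS_MENTEN, {"kcat": 1.0, "Km": 10.0}),
                     modifiers=["E"]),
            Reaction("rev", [("pMKK", 1)], [("MKK", 1)],
                     RateLaw(MASS_ACTION, {"k": 0.3})),
        ],
        [frozenset({"MKK", "pMKK"})],
    )
    rhs = assemble_odes(spec)
    rng = np.random.default_rng(7)
    for _ in range(20):
        x = rng.uniform(0, 100, 3)
        d = rhs(0.0, x)
        assert d[0] + d[1] == pytest.approx(0.0, abs=1e-12)


def _random_spec(rng, n_species=5, n_reactions=7):
    names = [f"S{i}" for i in range(n_species)]
    species = [Species(n, "cytosol", float(rng.uniform(0, 50))) for n in names]
    reactions = []
    for j in range(n_reactions):
        kind = rng.choice([MASS_ACTION, MICHAELIS_MENTEN, ZERO_ORDER_PRODUCTION,
                           FIRST_ORDER_DECAY, SATURATING_INDUCTION])
        if kind == MASS_ACTION:
            r = list(rng.choice(names, size=rng.integers(1, 3), replace=False))
            p = list(rng.choice(names, size=rng.integers(1, 3), replace=False))
            mods = list(rng.choice(names, size=rng.integers(0, 2), replace=False))
            rx = Reaction(f"r{j}", [(s, int(rng.integers(1, 3))) for s in r],
                          [(s, 1) for s in p],
                          RateLaw(kind, {"k": float(rng.uniform(0, 0.1))}), mods)
        elif kind == MICHAELIS_MENTEN:
            s, e, p = rng.choice(names, size=3, replace=False)
            rx = Reaction(f"r{j}", [(s, 1)], [(p, 1)],
                          RateLaw(kind, {"kcat": float(rng.uniform(0, 1)),
                                         "Km": float(rng.uniform(1, 100))}), [e])
        elif kind == ZERO_ORDER_PRODUCTION:
            rx = Reaction(f"r{j}", [], [(str(rng.choice(names)), 1)],
                          RateLaw(kind, {"alpha": float(rng.uniform(0, 0.1))}))
        elif kind == FIRST_ORDER_DECAY:
            rx = Reaction(f"r{j}", [(str(rng.choice(names)), 1)], [],
                          RateLaw(kind, {"beta": float(rng.uniform(0, 0.01))}))
        else:
            m, p = rng.choice(names, size=2, replace=False)
            rx = Reaction(f"r{j}", [], [(p, 1)],
                          RateLaw(kind, {"Vmax": float(rng.uniform(0, 0.1)),
                                         "K": float(rng.uniform(1, 50))}), [m])
        reactions.append(rx)
    return ModelSpec(species, reactions)


def _oracle_rhs(spec, x):
    """Independent term-by-term re-summation of reaction contributions."""
    idx = {s.name: i for i, s in enumerate(spec.species)}
    d = [0.0] * len(spec.species)
    for r in spec.reactions:
        law = r.rate_law
        if law.kind == MASS_ACTION:
            rate = law["k"]
            for sp, st in r.reactants:
                rate *= x[idx[sp]] ** st
            for m in r.modifiers:
                rate *= x[idx[m]]
        elif law.kind == FIRST_ORDER_DECAY:
            rate = law["beta"] * x[idx[r.reactants[0][0]]]
        elif law.kind == ZERO_ORDER_PRODUCTION:
            rate = law["alpha"]
        elif law.kind == MICHAELIS_MENTEN:
            s = x[idx[r.reactants[0][0]]]
            rate = law["kcat"] * x[idx[r.modifiers[0]]] * s / (law["Km"] + s)
        else:
            m = x[idx[r.modifiers[0]]]
            rate = law["Vmax"] * m / (law["K"] + m)
        for sp, st in r.reactants:
            d[idx[sp]] -= st * rate
        for sp, st in r.products:
            d[idx[sp]] += st * rate
    return np.array(d)


@pytest.mark.parametrize("trial", range(12))
def test_assembled_rhs_matches_bruteforce_oracle(trial):
    """Vectorized ODE assembly agrees with naive per-reaction summation on
    randomly generated small networks."""
    rng = np.random.default_rng(1000 + trial)
    spec = _random_spec(rng, n_species=int(rng.integers(3, 7)),
                        n_reactions=int(rng.integers(2, 9)))
    rhs = assemble_odes(spec)
    for _ in range(5):
        x = rng.uniform(0, 80, len(spec.species))
        np.testing.assert_allclose(rhs(0.0, x), _oracle_rhs(spec, x),
                                   rtol=1e-12, atol=1e-12)


def test_nonnegativity_of_random_network_trajectories():
    rng = np.random.default_rng(42)
    settings = SolverSettings(horizon=5e3)
    for trial in range(3):
        spec = _random_spec(rng)
        traj = integrate(spec, settings, np.linspace(0, 5e3, 200))
        assert traj.states.min() >= -settings.absolute_tolerance


# ---------------------------------------------------------------------------
# validation and serialization


def test_unknown_species_reference_is_rejected():
    spec = ModelSpec([Species("A")],
                     [Reaction("r", [("A", 1)], [("GHOST", 1)],
                               RateLaw(MASS_ACTION, {"k": 1.0}))])
    with pytest.raises(SpecificationError, match="GHOST"):
        spec.validate()


def test_duplicate_species_names_rejected():
    spec = ModelSpec([Species("A"), Species("A")], [])
    with pytest.raises(SpecificationError, match="duplicate"):
        spec.validate()


def test_inconsistent_conserved_group_rejected():
    spec = ModelSpec(
        [Species("A", "cytosol", 1.0), Species("B")],
        [Reaction("r", [("A", 1)], [], RateLaw(FIRST_ORDER_DECAY, {"beta": 0.1}))],
        [frozenset({"A", "B"})],
    )
    with pytest.raises(SpecificationError, match="conserved"):
        spec.validate()


def test_rate_law_constant_validation():
    with pytest.raises(InvalidArgumentError):
        RateLaw(MICHAELIS_MENTEN, {"kcat": 1.0, "Km": 0.0})
    with pytest.raises(SpecificationError):
        RateLaw(MASS_ACTION, {})
    with pytest.raises(SpecificationError):
        RateLaw("hill", {"n": 2})


def test_model_yaml_round_trip(base_spec, tmp_path):
    path = tmp_path / "net.yaml"
    base_spec.to_yaml(path)
    back = ModelSpec.from_yaml(path)
    assert back.to_dict() == base_spec.to_dict()


def test_committed_network_file_matches_default_model(base_spec):
    from importlib import resources

    ref = resources.files("il1p38").joinpath("data/il1_p38_network.yaml")
    with resources.as_file(ref) as path:
        shipped = ModelSpec.from_yaml(path)
    assert shipped.to_dict() == base_spec.to_dict()


def test_check_conservation_constant_trajectory():
    spec = ModelSpec([Species("X", "cytosol", 5.0)], [], [frozenset({"X"})])
    traj = integrate(spec, SolverSettings(horizon=100.0), np.linspace(0, 100, 11))
    result = check_conservation(spec, traj, tol=1e-12)
    assert result["X"]["passed"]


def test_check_conservation_missing_species_errors(base_spec, wt_run):
    bad = base_spec.copy()
    bad.conserved_groups = [frozenset({"MKK", "NOT_A_SPECIES"})]
    with pytest.raises(SpecificationError):
        check_conservation(bad, wt_run)
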