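"""Integrator contracts: closed forms, determinism, tolerance stability,
steady-state location."""

import math

import numpy as np
import pytest

from il1p38 import (
    InvalidArgumentError,
    ModelSpec,
    RateLaw,
    Reaction,
    SolverSettings,
    Species,
    default_grid,
    find_basal_state,
    integrate,
    is_steady,
)
from il1p38.network import FIRST_ORDER_DECAY, ZERO_ORDER_PRODUCTION

BETA_40MIN = math.log(2.0) / 2400.0


def decay_spec(x0=100.0, beta=BETA_40MIN):
    return ModelSpec(
        [Species("X", "nucleus", x0)],
        [Reaction("x_decay", [("X", 1)], [], RateLaw(FIRST_ORDER_DECAY, {"beta": beta}))],
    )


def turnover_spec(alpha, beta, x0=0.0):
    return ModelSpec(
        [Species("X", "cytosol", x0)],
        [
            Reaction("x_production_basal", [], [("X", 1)],
                     RateLaw(ZERO_ORDER_PRODUCTION, {"alpha": alpha})),
            Reaction("x_decay", [("X", 1)], [],
                     RateLaw(FIRST_ORDER_DECAY, {"beta": beta})),
        ],
    )


def test_pure_decay_halves_in_one_half_life():
    traj = integrate(decay_spec(), SolverSettings(horizon=4800.0),
                     np.array([0.0, 2400.0, 4800.0]))
    assert traj["X"][1] == pytest.approx(50.0, rel=1e-4)
    assert traj["X"][2] == pytest.approx(25.0, rel=1e-4)


def test_zero_reaction_spec_stays_at_initial_state():
    spec = ModelSpec([Species("A", "cytosol", 1.5), Species("B", "membrane", 0.0)], [])
    traj = integrate(spec, SolverSettings(horizon=1e4), np.linspace(0, 1e4, 50))
    assert np.all(traj["A"] == 1.5)
    assert np.all(traj["B"] == 0.0)


def test_turnover_matches_closed_form_rise():
    alpha, beta = 0.05, 2e-3
    grid = np.linspace(0, 5000, 101)
    traj = integrate(turnover_spec(alpha, beta), SolverSettings(horizon=5000.0), grid)
    expected = alpha / beta * (1.0 - np.exp(-beta * grid))
    np.testing.assert_allclose(traj["X"][1:], expected[1:], rtol=1e-6)


def test_turnover_relaxation_from_above_matches_closed_form():
    alpha, beta, x0 = 0.05, 2e-3, 80.0
    grid = np.linspace(0, 5000, 101)
    traj = integrate(turnover_spec(alpha, beta, x0), SolverSettings(horizon=5000.0), grid)
    expected = alpha / beta + (x0 - alpha / beta) * np.exp(-beta * grid)
    np.testing.assert_allclose(traj["X"], expected, rtol=1e-6)


def test_integration_is_bitwise_deterministic(base_spec, settings, wt_basal, wt_run):
    stim = base_spec.with_initial_state(wt_basal).with_initial(IL1=100.0)
    again = integrate(stim, settings, default_grid(2e5))
    assert np.array_equal(again.states, wt_run.states)
    assert np.array_equal(again.times, wt_run.times)


def test_tolerance_halving_changes_nothing_beyond_1e4(base_spec, wt_basal, settings, wt_run):
    stim = base_spec.with_initial_state(wt_basal).with_initial(IL1=100.0)
    tight = SolverSettings(relative_tolerance=settings.relative_tolerance / 2,
                           absolute_tolerance=settings.absolute_tolerance / 2)
    other = integrate(stim, tight, default_grid(2e5))
    dev = np.abs(other.states - wt_run.states) / np.maximum(np.abs(wt_run.states), 1e-6)
    assert dev.max() < 1e-4


def test_output_grid_validation():
    spec = decay_spec()
    with pytest.raises(InvalidArgumentError):
        integrate(spec, SolverSettings(horizon=10.0), np.array([1.0, 2.0]))  # no t=0
    with pytest.raises(InvalidArgumentError):
        integrate(spec, SolverSettings(horizon=10.0), np.array([0.0, 5.0, 5.0]))
    with pytest.raises(InvalidArgumentError):
        integrate(spec, SolverSettings(horizon=10.0), np.array([0.0, 20.0]))


def test_find_basal_state_turnover_network_reaches_alpha_over_beta():
    state = find_basal_state(turnover_spec(0.05, 2e-3), SolverSettings(horizon=2e4))
    assert state[0] == pytest.approx(25.0, rel=1e-9)


def test_is_steady_at_and_off_the_fixed_point(base_spec, wt_basal):
    basal_spec = base_spec.with_initial(IL1=0.0)
    assert is_steady(basal_spec, wt_basal, tol=1e-8)
    perturbed = wt_basal.copy()
    perturbed[base_spec.index("pp38_nuc")] += 10.0
    assert not is_steady(basal_spec, perturbed, tol=1e-8)


def test_all_zero_state_is_not_steady_with_production(base_spec):
    zero = np.zeros(len(base_spec.species))
    assert not is_steady(base_spec, zero, tol=1e-8)


def test_is_steady_rejects_dimension_mismatch(base_spec):
    with pytest.raises(InvalidArgumentError):
        is_steady(base_spec, np.zeros(3))


def test_solver_settings_validation():
    with pytest.raises(InvalidArgumentError):
        SolverSettings(relative_tolerance=0.0)
    with pytest.raises(InvalidArgumentError):
        SolverSettings(horizon=-1.0)
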