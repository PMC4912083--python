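"""The IL-1/p38 network itself: structure, basal state, perturbation
protocol, conservation and the transience of the IL-1 response."""

import numpy as np
import pytest

from il1p38 import (
    ConfigurationError,
    InvalidArgumentError,
    SolverSettings,
    apply_knockout,
    build_default_model,
    check_conservation,
    default_grid,
    find_basal_state,
    integrate,
    set_expression_level,
    stimulate,
)
from il1p38.model import ACTIVE_SPECIES, OBSERVABLES
from il1p38.parameters import ParameterSet


def test_all_active_species_start_at_zero(base_spec):
    for name in ACTIVE_SPECIES:
        assert base_spec.get_species(name).initial_concentration == 0.0
    assert base_spec.get_species("IL1").initial_concentration == 0.0


def test_missing_rate_constant_is_named(params):
    values = dict(params.values)
    values.pop("kcat_mkp1")
    with pytest.raises(ConfigurationError, match="kcat_mkp1"):
        build_default_model(ParameterSet(values))


def test_basal_state_is_stationary_and_nonnegative(base_spec, wt_basal):
    from il1p38.simulate import rhs_norm

    assert rhs_norm(base_spec.with_initial(IL1=0.0), wt_basal) < 1e-9
    assert np.all(wt_basal >= 0.0)


def test_unstimulated_irak_is_not_degraded(base_spec, settings, wt_basal, species_index):
    # without IL-1 there is no receptor complex, hence no IRAK turnover path
    assert species_index(wt_basal, "IRAK") == pytest.approx(100.0, rel=1e-9)
    assert species_index(wt_basal, "IL1R_complex") == 0.0


def test_positive_feedback_generates_basal_mkk_activity(base_spec, settings,
                                                        wt_basal, species_index):
    """Zeroing the pTAK1->TAB1 induced production lowers basal pMKK."""
    no_loop = base_spec.with_rate_constant("tab1_production_induced", "Vmax", 0.0)
    basal2 = find_basal_state(no_loop.with_initial(IL1=0.0), settings)
    assert species_index(wt_basal, "pMKK") > 0.0
    assert species_index(basal2, "pMKK") < species_index(wt_basal, "pMKK")


def test_set_expression_level_hits_target_exactly(base_spec, settings, species_index):
    spec = set_expression_level(base_spec, "TAB1", 10.0, settings)
    basal = find_basal_state(spec.with_initial(IL1=0.0), settings)
    assert species_index(basal, "TAB1") == pytest.approx(10.0, rel=1e-6)
    spec = set_expression_level(base_spec, "TAB2", 250.0, settings)
    basal = find_basal_state(spec.with_initial(IL1=0.0), settings)
    assert species_index(basal, "TAB2") == pytest.approx(250.0, rel=1e-6)


def test_level_zero_reproduces_knockout(base_spec, settings):
    via_level = set_expression_level(base_spec, "MKP1", 0.0, settings)
    via_ko = apply_knockout(base_spec, "MKP1")
    assert via_level.to_dict() == via_ko.to_dict()


def test_expression_level_requires_turnover(base_spec):
    with pytest.raises(ConfigurationError):
        set_expression_level(base_spec, "MKK", 50.0)
    with pytest.raises(InvalidArgumentError):
        set_expression_level(base_spec, "TAB1", -1.0)


def test_knockout_unknown_protein_rejected(base_spec):
    with pytest.raises(ConfigurationError):
        apply_knockout(base_spec, "TAB99")


def test_knockout_zeroes_level_and_all_production(base_spec):
    ko = apply_knockout(base_spec, "TAB1")
    assert ko.get_species("TAB1").initial_concentration == 0.0
    assert ko.get_reaction("tab1_production_basal").rate_law["alpha"] == 0.0
    assert ko.get_reaction("tab1_production_induced").rate_law["Vmax"] == 0.0
    # everything else intact
    assert ko.get_reaction("tak1_activation_by_tab1").rate_law["k"] > 0.0


def test_stimulate_rejects_negative_dose(base_spec):
    with pytest.raises(InvalidArgumentError):
        stimulate(base_spec, -5.0)


def test_zero_dose_trajectories_stay_at_basal(base_spec, settings, wt_basal):
    stim = base_spec.with_initial_state(wt_basal).with_initial(IL1=0.0)
    traj = integrate(stim, settings, default_grid(2e4))
    for sp in OBSERVABLES:
        b = wt_basal[base_spec.index(sp)]
        assert np.max(np.abs(traj[sp] - b)) <= max(1e-6, 1e-6 * b)


def test_conserved_pools_hold_along_stimulated_trajectory(base_spec, wt_run):
    results = check_conservation(base_spec, wt_run, tol=1e-6)
    assert all(r["passed"] for r in results.values())
    assert set(results) == {"MKK+pMKK", "TAB1_p38+p38+pp38_cyt+pp38_nuc"}


def test_total_irak_only_decreases_under_stimulation(wt_run):
    total = (wt_run["IRAK"] + wt_run["pIRAK"] + wt_run["pIRAK_TRAF6"]
             + wt_run["IRAK_TRAF6_TAB2"])
    assert np.all(np.diff(total) <= 1e-9)
    assert total[-1] < 1e-3 * total[0]  # fully degraded by the horizon


def test_steady_state_under_sustained_il1_equals_basal(base_spec, wt_run, wt_basal):
    """IRAK depletion without resynthesis extinguishes the TAB2 arm, so the
    long-horizon stimulated state returns to the unstimulated basal state."""
    for sp in OBSERVABLES:
        b = wt_basal[base_spec.index(sp)]
        assert wt_run[sp][-1] == pytest.approx(b, rel=0.01)


def test_nonnegativity_of_stimulated_trajectory(wt_run, settings):
    assert wt_run.states.min() >= -settings.absolute_tolerance
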