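"""Scenario runner: dose scans, level scans, basal panels and the deletion
panel with its knockout phenotypes."""

import numpy as np
import pytest

from il1p38 import ConfigurationError, dose_similarity, full_width_half_max
from il1p38.experiments import (
    ScenarioConfig,
    run_basal_panel,
    run_dose_scan,
    run_level_scan,
    run_scenario,
)


def test_config_rejects_override_knockout_clash():
    with pytest.raises(ConfigurationError):
        ScenarioConfig(label="bad", il1_dose=100.0,
                       expression_overrides={"TAB1": 20.0}, knockouts=("TAB1",))
    with pytest.raises(ConfigurationError):
        ScenarioConfig(label="bad", il1_dose=-1.0)


def test_empty_dose_scan_rejected(base_spec):
    with pytest.raises(ConfigurationError):
        run_dose_scan(base_spec, [])


@pytest.fixture(scope="module")
def dose_panel(base_spec, settings):
    return run_dose_scan(base_spec, [100.0, 1.0, 0.01, 0.0], settings)


def test_wildtype_response_classes(dose_panel):
    ref = dose_panel["dose_100"]
    assert ref.features["pp38_nuc"].response_class == "pulse"
    assert ref.features["pp38_cyt"].response_class == "step"
    flat = dose_panel["dose_0"]
    assert all(f.response_class == "flat" for f in flat.features.values())


def test_dose_robustness_100_vs_1(dose_panel):
    sim = dose_similarity(dose_panel["dose_100"].trajectory,
                          dose_panel["dose_1"].trajectory, "pp38_nuc")
    assert sim >= 0.95


def test_small_dose_delays_and_lowers_nuclear_peak(dose_panel):
    ref = dose_panel["dose_100"].features["pp38_nuc"]
    tiny = dose_panel["dose_0.01"].features["pp38_nuc"]
    assert tiny.peak_time > ref.peak_time
    assert tiny.peak_value < ref.peak_value


def test_cytosolic_amplitude_insensitive_to_dose(dose_panel):
    """Lower IL-1 delays the cytosolic response but does not shrink it."""
    a100 = dose_panel["dose_100"].features["pp38_cyt"]
    a1 = dose_panel["dose_1"].features["pp38_cyt"]
    amp100 = a100.peak_value - a100.basal_value
    amp1 = a1.peak_value - a1.basal_value
    assert amp1 == pytest.approx(amp100, rel=0.05)


# --- deletion phenotypes ---------------------------------------------------


def test_deletion_panel_has_all_six_scenarios(deletion_panel):
    assert set(deletion_panel.labels) == {
        "wild_type", "dTAB1", "dTAB2", "dMKP1", "dTAB1_dTAB2", "dTAB1_dMKP1"}


def test_tab2_deletion_abolishes_every_il1_response(deletion_panel):
    res = deletion_panel["dTAB2"]
    for sp in ("pp38_nuc", "pp38_cyt", "pMKK"):
        assert np.max(np.abs(res.trajectory[sp] - res.basal[sp])) < 1e-6


def test_tab1_deletion_zeroes_cytosolic_and_terminal_nuclear(deletion_panel):
    res = deletion_panel["dTAB1"]
    assert np.max(np.abs(res.trajectory["pp38_cyt"])) <= 1e-9
    f = res.features["pp38_nuc"]
    assert f.response_class == "pulse"  # the acute phase survives
    assert abs(f.terminal_value) <= 1e-3 * f.peak_value


def test_tab1_deletion_broadens_the_nuclear_pulse(deletion_panel):
    wt = deletion_panel["wild_type"]
    ko = deletion_panel["dTAB1"]
    fwhm_wt = full_width_half_max(wt.trajectory, "pp38_nuc", wt.basal["pp38_nuc"])
    fwhm_ko = full_width_half_max(ko.trajectory, "pp38_nuc", ko.basal["pp38_nuc"])
    assert fwhm_ko > fwhm_wt


def test_mkp1_deletion_sustained_nuclear_with_unchanged_pmkk(deletion_panel):
    wt = deletion_panel["wild_type"]
    ko = deletion_panel["dMKP1"]
    nuc = ko.trajectory["pp38_nuc"]
    late = ko.trajectory.times > 600
    # constitutive activation: elevated plateau, no acute-phase decline
    assert np.min(nuc[late]) > 10 * wt.basal["pp38_nuc"]
    assert ko.features["pp38_nuc"].response_class != "pulse"
    dev = np.max(np.abs(ko.trajectory["pMKK"] - wt.trajectory["pMKK"]))
    assert dev <= 5e-3 * np.max(wt.trajectory["pMKK"])


def test_double_tab_deletion_nullifies_nuclear_activation(deletion_panel):
    res = deletion_panel["dTAB1_dTAB2"]
    assert np.max(res.trajectory["pp38_nuc"] - res.basal["pp38_nuc"]) <= 1e-6


def test_tab1_mkp1_double_deletion_phosphorylates_all_p38(deletion_panel, params):
    """No phosphatase and no cytosolic sequestration: nuclear pp38 rises
    toward the total p38 pool (the last ~2% stays unphosphorylated because
    IRAK depletion extinguishes the kinase drive)."""
    res = deletion_panel["dTAB1_dMKP1"]
    assert res.trajectory["pp38_nuc"][-1] >= 0.95 * params["level_p38"]
    assert res.features["pp38_nuc"].response_class != "pulse"


# --- expression-level effects ----------------------------------------------


@pytest.fixture(scope="module")
def tab1_scan(base_spec, settings):
    return run_level_scan(base_spec, "TAB1", [5.0, 10.0, 20.0], 100.0, settings)


def test_tab1_level_sets_all_terminal_states_monotonically(tab1_scan):
    for sp in ("pp38_nuc", "pp38_cyt", "pMKK"):
        terms = [tab1_scan[f"TAB1_{l:g}"].features[sp].terminal_value
                 for l in (5.0, 10.0, 20.0)]
        assert terms[0] < terms[1] < terms[2]


def test_mkp1_level_inversely_sets_nuclear_peak(base_spec, settings):
    panel = run_level_scan(base_spec, "MKP1", [50.0, 100.0, 200.0], 100.0, settings)
    peaks = [panel[f"MKP1_{l:g}"].features["pp38_nuc"].peak_value
             for l in (50.0, 100.0, 200.0)]
    assert peaks[0] > peaks[1] > peaks[2]


def test_tab2_tenfold_variation_leaves_terminals_unchanged(base_spec, settings):
    panel = run_level_scan(base_spec, "TAB2", [10.0, 100.0, 1000.0], 100.0, settings)
    for sp in ("pp38_nuc", "pp38_cyt", "pMKK"):
        terms = [panel[f"TAB2_{l:g}"].features[sp].terminal_value
                 for l in (10.0, 100.0, 1000.0)]
        assert (max(terms) - min(terms)) / min(terms) <= 0.01


# --- basal panels ----------------------------------------------------------


def test_basal_panel_tab1_raises_all_basal_activities(base_spec, settings):
    panel = run_basal_panel(base_spec, "TAB1", [5.0, 10.0, 20.0], settings)
    for sp in ("pp38_nuc", "pp38_cyt", "pMKK"):
        basals = [panel[f"TAB1_{l:g}"].basal[sp] for l in (5.0, 10.0, 20.0)]
        assert basals[0] < basals[1] < basals[2]


def test_basal_panel_tab2_and_mkp1_invariances(base_spec, settings):
    tab2 = run_basal_panel(base_spec, "TAB2", [10.0, 100.0, 1000.0], settings)
    for sp in ("pp38_nuc", "pp38_cyt", "pMKK"):
        basals = [tab2[f"TAB2_{l:g}"].basal[sp] for l in (10.0, 100.0, 1000.0)]
        assert (max(basals) - min(basals)) / min(basals) <= 1e-6
    mkp1 = run_basal_panel(base_spec, "MKP1", [50.0, 100.0, 200.0], settings)
    pmkk = [mkp1[f"MKP1_{l:g}"].basal["pMKK"] for l in (50.0, 100.0, 200.0)]
    assert (max(pmkk) - min(pmkk)) / min(pmkk) <= 0.01


def test_panel_rerun_reproduces_identical_feature_tables(base_spec, settings):
    a = run_dose_scan(base_spec, [100.0], settings, horizon=2e4).features_frame()
    b = run_dose_scan(base_spec, [100.0], settings, horizon=2e4).features_frame()
    assert a.equals(b)
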