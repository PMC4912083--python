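"""Shared fixtures: the calibrated model, its basal state and the reference
stimulation run are computed once per session."""

import numpy as np
import pytest

from il1p38 import (
    SolverSettings,
    build_default_model,
    default_grid,
    default_parameters,
    find_basal_state,
    integrate,
)
from il1p38.experiments import run_deletion_panel


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def base_spec(params):
    return build_default_model(params)


@pytest.fixture(scope="session")
def settings():
    return SolverSettings()


@pytest.fixture(scope="session")
def wt_basal(base_spec, settings):
    return find_basal_state(base_spec.with_initial(IL1=0.0), settings)


@pytest.fixture(scope="session")
def wt_run(base_spec, settings, wt_basal):
    """Wild-type trajectory under 100 nM IL-1, started from the basal state."""
    stim = base_spec.with_initial_state(wt_basal).with_initial(IL1=100.0)
    return integrate(stim, settings, default_grid(2e5))


@pytest.fixture(scope="session")
def deletion_panel(base_spec, settings):
    return run_deletion_panel(base_spec, settings)


@pytest.fixture(scope="session")
def species_index(base_spec):
    names = base_spec.species_names
    return lambda state, name: float(state[names.index(name)])
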