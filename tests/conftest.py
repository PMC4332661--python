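import numpy as np
import pytest

from cortsep import (
    cohort_correlation,
    correlation_difference,
    hub_scenario,
    load_atlas,
    select_top_features,
    simulate_cohorts,
)


@pytest.fixture(scope="session")
def dk70():
    return load_atlas("dk70")


@pytest.fixture(scope="session")
def default_scenario():
    """Default planted-hub spec plus the hub pairs it should reveal."""
    return hub_scenario(seed=11)


@pytest.fixture(scope="session")
def cohort_tables(default_scenario):
    spec, _ = default_scenario
    return simulate_cohorts(spec, seed=11)


@pytest.fixture(scope="session")
def selected_features(cohort_tables):
    case, control = cohort_tables
    diff = correlation_difference(cohort_correlation(case), cohort_correlation(control))
    return select_top_features(diff, 15, case.atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
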