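import numpy as np
import pytest

from sclerogrowth.stations import load_fixture_tables
from sclerogrowth.synthetic import StationScenario, simulate_cohort


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def small_cohort():
    """One moderately sized synthetic cohort reused across tests."""
    scenario = StationScenario.linear_seasons(
        "coh",
        peak_daily_growth_um=240.0,
        first_season_days=250,
        omega=-12,
        n_ages=4,
        n_individuals=8,
        noise_cv=0.05,
        start_jitter_days=8,
        seed=11,
    )
    return simulate_cohort(scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
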