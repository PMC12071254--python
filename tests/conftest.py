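import numpy as np
import pytest
from hypothesis import settings

from emdeepsd import SimulationConfig, simulate_profiles, make_founder_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort():
    """Small labelled cohort with the standard cancer shift."""
    return simulate_profiles(
        SimulationConfig(n_cancer=50, n_control=50, effect_size=0.5, seed=7)
    )


@pytest.fixture(scope="session")
def founders():
    return make_founder_fixture(seed=3)


@pytest.fixture()
def rng():
    return np.random.RandomState(0)
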