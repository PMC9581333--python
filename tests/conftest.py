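import numpy as np
import pytest
from hypothesis import settings

from scratchkit.cohort import CohortSpec, simulate_cohort
from scratchkit.simulate import SignalParams, simulate_session

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free, confounder-free default session (seed 1)."""
    params = SignalParams(seed=1, noise_sd=0.0, confounder_spec=())
    return simulate_session(params)


@pytest.fixture(scope="session")
def default_session():
    """Default session with both confounder kinds and noise (seed 1)."""
    return simulate_session(SignalParams(seed=1))


@pytest.fixture(scope="session")
def short_session():
    """2-minute noiseless session for cheap detector tests."""
    params = SignalParams(seed=4, duration_s=120.0, n_events=4, noise_sd=0.0, confounder_spec=())
    return simulate_session(params)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortSpec(seed=7))
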