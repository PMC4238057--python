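import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cueattn as ca
from cueattn.trial_classification import classify_trials

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_session():
    """A 1,500-trial default-calibrated session with 12 heterogeneous units."""
    neurons = ca.sample_population(12, 99)
    return ca.generate_session(1500, seed=42, neurons=neurons)


@pytest.fixture(scope="session")
def classified_trials(small_session):
    return classify_trials(small_session.trials)


@pytest.fixture(scope="session")
def behavior_session():
    """A larger, spike-free session for behavioral convergence checks."""
    return ca.generate_session(24000, seed=7)


@pytest.fixture(scope="session")
def behavior_trials(behavior_session):
    return classify_trials(behavior_session.trials)
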