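import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gvstrack.simulate import SimConfig, simulate_cohort
from gvstrack.trajectory import TrialTimeline


@pytest.fixture(scope="session")
def small_cohort():
    """Two participants, full crossover design, fixed seed."""
    return simulate_cohort(SimConfig(n_participants=2, seed=12345))


@pytest.fixture(scope="session")
def timeline():
    return TrialTimeline()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
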