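import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fixwalk as fw

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def pop100():
    return fw.Population(N=100)


@pytest.fixture
def pop1500():
    return fw.Population(N=1500)


@pytest.fixture
def improvement_dist():
    """The working point of the accumulation analysis: alpha=30, N=1500."""
    return fw.ImprovementDistribution(alpha=30.0, N=1500)
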