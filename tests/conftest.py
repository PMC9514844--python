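import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_voxel_cfg():
    """Small synthetic voxel cohort config, quick enough for unit tests."""
    from tractvelocity.synthetic import SyntheticConfig

    return SyntheticConfig(seed=7, n_participants=12)
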