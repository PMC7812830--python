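import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neocent import SimulationConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def config() -> SimulationConfig:
    """Default simulation conditions: 78% single-allele loss over a 100-kb,
    10-bin domain at 500 reads/bin/allele."""
    return SimulationConfig(seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
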