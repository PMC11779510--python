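import numpy as np
import pytest

from aristop import RunConfig, simulate_session
from aristop.pipeline import reduced_scale_config


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    """Reduced-scale study: 1 kHz sampling, 72 trials, dip + coupling on."""
    return reduced_scale_config(dip_depth=0.5, coupled_increase_gain=1.2)


@pytest.fixture(scope="session")
def small_session(small_config):
    return simulate_session("sub-01", small_config, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
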