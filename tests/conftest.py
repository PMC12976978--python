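import numpy as np
import pytest

from evquant import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small, fast synthetic lane used across tests."""
    return SyntheticConfig(
        fov_size=15000.0,
        n_fov=2,
        mean_evs_per_fov=25.0,
        seed=7,
    )
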