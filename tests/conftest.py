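import numpy as np
import pytest

from emocsp import SimConfig, make_ground_truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """6-channel configuration for fast spatial-filter tests."""
    return SimConfig(n_channels=6, seed=3, pink_scale=0.1, white_scale=0.05)


@pytest.fixture(scope="session")
def small_gt(small_cfg):
    return make_ground_truth(small_cfg, seed=3)
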