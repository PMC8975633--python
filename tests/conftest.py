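import numpy as np
import pytest

from petcycle.imaging import ImageSlice, PairedSample
from petcycle.networks import DiscriminatorConfig, GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_gen_cfg():
    """Smallest architecture of the same family, for fast training tests."""
    return GeneratorConfig(base_channels=4, n_res_blocks=1, cbam_reduction=2,
                           cbam_spatial_kernel=3)


@pytest.fixture
def tiny_disc_cfg():
    return DiscriminatorConfig(channel_ladder=(4, 8, 16, 32))


@pytest.fixture
def small_norm_pairs(rng):
    """Eight aligned 32x32 pairs already normalized to [-1, 1]."""
    pairs = []
    for _ in range(8):
        hq = np.tanh(rng.normal(size=(32, 32)))
        lq = np.clip(hq + 0.1 * rng.normal(size=(32, 32)), -1, 1)
        pairs.append(PairedSample(lq=ImageSlice(lq), hq=ImageSlice(hq)))
    return pairs
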