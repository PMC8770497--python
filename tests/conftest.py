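import numpy as np
import pytest

from mafcdn.image_core import GrayImage, MaskImage
from mafcdn.network import ArchitectureConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.integers(0, 256, size=(12, 17)), scale="8bit")


@pytest.fixture
def micro_arch():
    """Smallest architecture that still exercises every layer type."""
    return ArchitectureConfig(
        variant_name="micro",
        first_conv_channels=4,
        growth_rate=3,
        down_block_layers=(2,),
        bottleneck_layers=2,
        up_block_layers=(2,),
        dropout_p=0.0,
    )


@pytest.fixture
def tiny_arch():
    return ArchitectureConfig(
        variant_name="tiny",
        first_conv_channels=16,
        growth_rate=8,
        down_block_layers=(2, 2),
        bottleneck_layers=2,
        up_block_layers=(2, 2),
    )


def random_mask(rng, shape, p=0.2):
    return MaskImage((rng.random(shape) < p).astype(np.uint8))
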