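import numpy as np
import pytest

from rgbpheno import RgbImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def uniform_image(rgb, h=4, w=4):
    """Small image of one constant color."""
    px = np.tile(np.asarray(rgb, np.uint8), (h, w, 1))
    return RgbImage(px)


@pytest.fixture
def make_uniform():
    return uniform_image
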