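import numpy as np
import pytest

from qrseg import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gray_image(rng, shape=(16, 16), levels=256) -> GrayImage:
    return GrayImage(pixels=rng.integers(0, levels, size=shape), levels=levels)
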