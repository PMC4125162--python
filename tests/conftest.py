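import numpy as np
import pytest

from heightscape.segmentation import LandscapeWindow


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_window(rng, shape=(12, 12), n_classes=3, cell=30.0, nodata_frac=0.0):
    """A random height window whose classes under thresholds (5, 10) span
    {0..n_classes}."""
    heights = rng.choice([0.0, 3.0, 7.0, 12.0][: n_classes + 1], size=shape)
    valid = rng.random(shape) >= nodata_frac
    return LandscapeWindow(heights, valid, cell)


@pytest.fixture
def small_window(rng):
    return random_window(rng)
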