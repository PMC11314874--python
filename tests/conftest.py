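import numpy as np
import pytest

from lipimage import GreyScale, ToneImage

M8 = GreyScale(256.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240731)


@pytest.fixture
def random_tone_image(rng):
    """Non-constant single-channel tone image on the ordinary scale [0, M[."""
    return ToneImage(rng.uniform(30.0, 220.0, size=(24, 32)), M8)


@pytest.fixture
def random_colour_image(rng):
    return ToneImage(rng.uniform(40.0, 200.0, size=(16, 16, 3)), M8)


def tone(values, scale=M8):
    """Shorthand: wrap a nested list/array as a ToneImage."""
    return ToneImage(np.atleast_2d(np.asarray(values, dtype=float)), scale)
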