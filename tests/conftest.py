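import numpy as np
import pytest

from acetosuperpose import AnnotatedImage, Rect, SyntheticParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Generator parameters at 1/8 linear scale for fast unit tests."""
    return SyntheticParams(image_width=188, image_height=125, n_A1=6, n_P1B=8, seed=7)


def random_annotated(rng, width=32, height=24, label="A1"):
    """A random annotated image with an interior ROI, for geometry tests."""
    pixels = rng.integers(0, 256, size=(height, width, 3), dtype=np.uint8)
    roi = Rect(x=width // 4, y=height // 4, width=width // 3, height=height // 3)
    return AnnotatedImage(pixels=pixels, roi=roi, label=label)
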