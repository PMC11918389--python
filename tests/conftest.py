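import numpy as np
import pytest

from agriflow.raster_land import BandStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """A 6×6 scene: vegetation block (high NIR/low red) in the top-left,
    saline block (high green/low SWIR) bottom-right, bare soil elsewhere."""
    shape = (6, 6)
    green = np.full(shape, 0.12)
    red = np.full(shape, 0.15)
    nir = np.full(shape, 0.22)
    swir = np.full(shape, 0.20)
    nir[:3, :3], red[:3, :3] = 0.55, 0.06
    green[4:, 4:], swir[4:, 4:] = 0.35, 0.12
    jitter = rng.normal(0, 1e-3, shape)
    return BandStack(green=green + jitter, red=red + jitter,
                     nir=nir + jitter, swir=swir + jitter, pixel_size=30.0)
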