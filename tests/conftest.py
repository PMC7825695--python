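import numpy as np
import pytest

from radsig.image import ImageVolume, ROIMask
from radsig.synthetic import PhantomEffect, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small, fast phantom with a mild label effect (label = 1)."""
    spec = PhantomSpec(
        shape=(32, 32, 16),
        gland_radii=(12.0, 10.0, 11.0),
        effect=PhantomEffect(mean_shift=30.0),
        seed=42,
    )
    vol, gland, peri = generate_phantom(spec, label=1)
    return spec, vol, gland, peri


@pytest.fixture()
def cube_volume():
    """An 8x8x8 seeded random volume with a central cubic ROI."""
    rng = np.random.default_rng(7)
    vox = rng.normal(100.0, 20.0, size=(8, 8, 8))
    vol = ImageVolume(vox, (1.0, 1.0, 1.0))
    m = np.zeros((8, 8, 8), dtype=np.uint8)
    m[2:6, 2:6, 2:6] = 1
    return vol, ROIMask(m, (1.0, 1.0, 1.0))
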