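import numpy as np
import pytest

from tdcai.core import CTPSeries
from tdcai.phantom import default_ctp_scene, rasterize_scene


@pytest.fixture(scope="session")
def clean_scene():
    return default_ctp_scene(noise_sigma=0.0, seed=3)


@pytest.fixture(scope="session")
def clean_phantom(clean_scene):
    """Noise-free CTP phantom: (series, labels, centerlines)."""
    return rasterize_scene(clean_scene)


@pytest.fixture(scope="session")
def noisy_phantom():
    """CTP phantom with 5 HU Gaussian noise."""
    scene = default_ctp_scene(noise_sigma=5.0, seed=3)
    return rasterize_scene(scene)


@pytest.fixture()
def straight_tube_series():
    """Minimal series with one straight tube of constant value along z."""
    shape = (40, 21, 21)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    mask = ((yy - 10) ** 2 + (xx - 10) ** 2) <= 6**2
    mask[:4] = False
    mask[-4:] = False
    values = np.where(mask, 300.0, 0.0).astype(np.float32)
    return values, mask
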