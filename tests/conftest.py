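import numpy as np
import pytest
from scipy import ndimage

from peakpattern.geometry import VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return VolumeGrid.full((16, 16, 16))


def smooth_field(rng, shape=(16, 16, 16), sigma=1.2, scale=2.0):
    """Standardized smoothed Gaussian field, handy for peak tests."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.mean()) / f.std() * scale


def stationary_residuals(rng, fwhm, n_volumes=40, core=32):
    """Stationary smoothed-noise residual series, cropped from a padded
    lattice so the core is free of smoothing edge effects."""
    sigma = fwhm / np.sqrt(8 * np.log(2))
    pad = int(4 * sigma) + 2
    big = core + 2 * pad
    noise = rng.standard_normal((n_volumes, big, big, big)).astype(np.float32)
    out = np.empty((n_volumes, core, core, core))
    for i, v in enumerate(noise):
        sm = ndimage.gaussian_filter(v, sigma, mode="reflect")
        out[i] = sm[pad:pad + core, pad:pad + core, pad:pad + core]
    return out
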