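"""Shared fixtures: small phantoms and registration test images."""

import numpy as np
import pytest
from scipy import ndimage

from ratfc import phantom
from ratfc.io_core import Volume4D


@pytest.fixture(scope="session")
def smooth_blob():
    """Smooth asymmetric 32^3 test image for rigid-registration tests.

    An anisotropic Gaussian 'brain' plus three broad off-centre bumps:
    smooth enough that trilinear resampling is nearly exact, asymmetric
    enough that all six rigid parameters are identifiable.
    """
    n = 32
    g = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    c = (n - 1) / 2
    img = 100 * np.exp(-(((g[0] - c) / (0.30 * n)) ** 2
                         + ((g[1] - c) / (0.22 * n)) ** 2
                         + ((g[2] - c) / (0.27 * n)) ** 2))
    for dx, dy, dz, amp, s in [(0.12, 0.05, -0.1, 40, 0.12),
                               (-0.15, 0.1, 0.05, -30, 0.10),
                               (0.02, -0.18, 0.08, 25, 0.09)]:
        img += amp * np.exp(-(((g[0] - c - dx * n) ** 2 + (g[1] - c - dy * n) ** 2
                               + (g[2] - c - dz * n) ** 2) / (2 * (s * n) ** 2)))
    return ndimage.gaussian_filter(img, 2.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Default-condition phantom scan with its ground truth (no motion)."""
    spec = phantom.PhantomSpec(nt=200, seed=42)
    return phantom.make_phantom(spec)


@pytest.fixture(scope="session")
def quiet_phantom():
    """Artefact-free phantom: networks + anatomy + noise only."""
    spec = phantom.PhantomSpec(nt=200, seed=43, artefacts=[])
    return phantom.make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def tiny_volume(rng, shape=(8, 8, 4, 10), tr_s=1.0):
    return Volume4D(data=rng.standard_normal(shape) + 10,
                    voxel_size_mm=(0.5, 0.5, 1.0), tr_s=tr_s)


@pytest.fixture()
def tiny_vol(rng):
    return tiny_volume(rng)
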