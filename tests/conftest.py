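import numpy as np
import pytest

from lfspim.io import Volume3D
from lfspim.synth import CameraNoiseModel, make_bead_phantom


@pytest.fixture(scope="session")
def default_noise():
    return CameraNoiseModel(offset=100.0, read_noise=2.0, gain=1.0)


@pytest.fixture(scope="session")
def bead_phantom_100(default_noise):
    """100 well-separated beads with constant FWHM, realistic camera noise."""
    vol, truth = make_bead_phantom(
        (48, 320, 320),
        100,
        (1.5, 1.5, 3.0),
        peak_counts=10000,
        background_counts=200,
        noise=default_noise,
        seed=11,
        voxel_size_um=(1.0, 0.75, 0.75),
        placement="jittered_grid",
    )
    return vol, truth


@pytest.fixture
def two_peak_volume():
    """Two hand-placed blobs 3 voxels apart, brighter one first."""
    data = np.full((15, 15, 15), 100.0)
    zz, yy, xx = np.mgrid[0:15, 0:15, 0:15]
    for (c, amp) in (((7, 7, 6), 1000.0), ((7, 7, 9), 800.0)):
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        data += amp * np.exp(-d2 / (2 * 1.0**2))
    return Volume3D(data, (1.0, 1.0, 1.0))
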