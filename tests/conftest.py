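import warnings

import numpy as np
import pytest

import pcmkit as pk

# the late-frame "no PCM component contains a centriole position" warning is
# expected once a channel is essentially exhausted
warnings.filterwarnings("ignore", message="no PCM component contains")


@pytest.fixture(scope="session")
def control_preset():
    return pk.make_preset("control")


@pytest.fixture(scope="session")
def noiseless_movie(control_preset):
    """One noiseless control movie (seed 3) with ground truth."""
    return pk.generate_movie(control_preset, 3, noise=False)


@pytest.fixture(scope="session")
def noisy_movie(control_preset):
    """One noisy control movie (seed 1) with ground truth."""
    return pk.generate_movie(control_preset, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def truth_positions(truth):
    return [[tuple(p) for p in frame] for frame in truth.centriole_positions_um]


@pytest.fixture(scope="session")
def small_sphere_grid():
    """A tiny calibrated grid with a hard-edged sphere on uniform background.

    Background exactly 100, sphere voxels exactly 1100 (radius 1.0 um at the
    grid center); used for exact background-subtraction and segmentation
    checks.
    """
    cal = pk.PhysicalCalibration(dx_um=0.15, dz_um=0.5)
    nz, ny, nx = 12, 40, 40
    z = (np.arange(nz) * cal.dz_um)[:, None, None]
    y = (np.arange(ny) * cal.dx_um)[None, :, None]
    x = (np.arange(nx) * cal.dx_um)[None, None, :]
    center = (3.0, 3.0, 3.0)
    d = np.sqrt((z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2)
    sphere = d <= 1.0
    data = np.full((nz, ny, nx), 100.0)
    data[sphere] = 1100.0
    grid = pk.VoxelGrid(data[None, None], cal, ("ch0",))
    return grid, sphere, center
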