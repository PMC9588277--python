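import numpy as np
import pytest

import petiq as pq


@pytest.fixture(scope="session")
def nema_default():
    """Default-geometry noiseless NEMA phantom (partial-volume rasterized)."""
    vol, truth = pq.generate_nema_phantom(pq.PhantomTruth())
    return vol, truth


@pytest.fixture(scope="session")
def exact_pose(nema_default):
    vol, _ = nema_default
    return pq.PhantomPose(0.0, 0.0, vol.n_slices // 2, 0.0)


@pytest.fixture(scope="session")
def nema_roiset(nema_default, exact_pose):
    vol, _ = nema_default
    return pq.place_nema_rois(vol, exact_pose)


@pytest.fixture(scope="session")
def blurred_nema(nema_default, exact_pose):
    """Default phantom through an 8-mm system PSF (noiseless)."""
    vol, truth = nema_default
    return pq.apply_system_blur(vol, 8.0), truth


@pytest.fixture(scope="session")
def noisy_nema(blurred_nema, nema_roiset):
    """Blurred phantom plus moderately correlated noise, fixed seed."""
    vol, truth = blurred_nema
    preset = pq.ConditionPreset("test", 8.0, 0.08, 6.0)
    return pq.add_noise(vol, preset, seed=7), truth


def on_grid_point_source(psf_fwhm_mm, matrix_size=513, pixel_spacing=1.59,
                         amplitude=1000.0):
    """Blurred point source whose impulse sits exactly on a voxel center."""
    vol = pq.generate_point_sources([(0.0, 0.0)], amplitude=amplitude,
                                    matrix_size=matrix_size,
                                    pixel_spacing=pixel_spacing)
    assert np.count_nonzero(vol.voxels) == 1
    return pq.apply_system_blur(vol, psf_fwhm_mm)
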