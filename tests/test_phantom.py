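"""Synthetic phantom generator: geometry truth, splats, blur, noise model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petiq as pq
from petiq.errors import GeometryError
from petiq.phantom import validate_preset_family

from conftest import on_grid_point_source


class TestNemaPhantom:
    def test_concentrations_match_truth(self, nema_default):
        vol, truth = nema_default
        assert vol.voxels.max() == pytest.approx(truth.h_true)
        body = vol.voxels[vol.voxels > 0]
        values, counts = np.unique(body, return_counts=True)
        assert values[np.argmax(counts)] == pytest.approx(truth.b_true)
        assert truth.h_true / truth.b_true == pytest.approx(8.0)

    def test_degenerate_contrast_rejected(self):
        with pytest.raises(GeometryError, match="H_true > B_true"):
            pq.PhantomTruth(h_true=40.0, b_true=40.0)

    def test_total_activity_closed_form(self, nema_default):
        vol, truth = nema_default
        geo = pq.NemaGeometry()
        length = vol.n_slices * vol.slice_spacing
        v_lung = np.pi * (geo.lung_insert_diameter / 2) ** 2 * length
        v_spheres = sum(4 / 3 * np.pi * (d / 2) ** 3 for d in geo.sphere_diameters)
        expected = (truth.b_true * (geo.body_cross_section_area() * length
                                    - v_lung - v_spheres)
                    + truth.h_true * v_spheres)
        measured = vol.voxels.sum() * vol.pixel_spacing**2 * vol.slice_spacing
        assert measured == pytest.approx(expected, rel=1e-3)

    def test_sphere_outside_body_is_geometry_error(self):
        geo = pq.NemaGeometry(sphere_diameters=(10, 13, 17, 22, 28, 37),
                              ring_radius=140.0)
        with pytest.raises(GeometryError, match="outside the phantom body"):
            pq.generate_nema_phantom(pq.PhantomTruth(), geometry=geo)

    def test_too_small_fov_rejected(self):
        with pytest.raises(GeometryError, match="accommodate"):
            pq.generate_nema_phantom(pq.PhantomTruth(), matrix_size=64,
                                     pixel_spacing=4.0)


class TestPointSources:
    def test_on_center_single_voxel(self):
        vol = pq.generate_point_sources([(0.0, 0.0)], amplitude=100.0,
                                        matrix_size=513)
        nz = np.flatnonzero(vol.voxels)
        assert nz.size == 1
        assert vol.voxels.ravel()[nz[0]] == pytest.approx(100.0)

    def test_corner_splats_four_equal_quarters(self):
        p = 1.59
        vol = pq.generate_point_sources([(p / 2, p / 2)], amplitude=100.0,
                                        matrix_size=513, pixel_spacing=p)
        nz = vol.voxels[vol.voxels > 0]
        assert nz.size == 4
        np.testing.assert_allclose(nz, 25.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(y=st.floats(-30, 30), x=st.floats(-30, 30),
           n=st.integers(1, 3))
    def test_total_deposit_equals_sources_times_amplitude(self, y, x, n):
        positions = [(y + 40 * k, x) for k in range(n)]
        vol = pq.generate_point_sources(positions, amplitude=37.0,
                                        matrix_size=128, pixel_spacing=2.0)
        assert vol.voxels.sum() == pytest.approx(n * 37.0)

    def test_outside_fov_rejected(self):
        with pytest.raises(GeometryError, match="outside"):
            pq.generate_point_sources([(0.0, 600.0)], matrix_size=128,
                                      pixel_spacing=2.0)


class TestSystemBlur:
    def test_zero_fwhm_is_identity(self, nema_default):
        vol, _ = nema_default
        out = pq.apply_system_blur(vol, 0.0)
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_signal_conserved(self):
        vol = on_grid_point_source(8.55)
        assert vol.voxels.sum() == pytest.approx(1000.0, rel=1e-3)

    def test_gaussian_semigroup(self):
        src = pq.generate_point_sources([(0.0, 0.0)], matrix_size=257,
                                        pixel_spacing=1.59)
        a, b = 5.0, 7.0
        twice = pq.apply_system_blur(pq.apply_system_blur(src, a), b)
        once = pq.apply_system_blur(src, np.hypot(a, b))
        np.testing.assert_allclose(twice.voxels, once.voxels,
                                   atol=1e-3 * once.voxels.max())

    def test_blurred_impulse_fwhm_recovered(self):
        vol = on_grid_point_source(8.55)
        pm = pq.profile_fwhm(vol, (0.0, 0.0), "radial")
        assert pm.fwhm == pytest.approx(8.55, abs=vol.pixel_spacing / 4)


class TestNoise:
    def test_zero_amplitude_identity(self, blurred_nema):
        vol, _ = blurred_nema
        out = pq.add_noise(vol, pq.ConditionPreset("z", 8.0, 0.0, 6.0), seed=1)
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_seed_determinism(self, blurred_nema):
        vol, _ = blurred_nema
        preset = pq.ConditionPreset("n", 8.0, 0.1, 5.0)
        a = pq.add_noise(vol, preset, seed=3)
        b = pq.add_noise(vol, preset, seed=3)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        c = pq.add_noise(vol, preset, seed=4)
        assert not np.array_equal(a.voxels, c.voxels)

    @pytest.mark.parametrize("corr_fwhm", [0.0, 8.0])
    def test_sd_matches_amplitude_times_mean(self, corr_fwhm):
        bg = 7.0
        vol = pq.Volume(np.full((5, 128, 128), bg), 4.07, 5.0)
        out = pq.add_noise(vol, pq.ConditionPreset("n", 0, 0.05, corr_fwhm),
                           seed=3)
        sd = (out.voxels - bg).std()
        assert sd == pytest.approx(0.05 * bg, rel=0.03)

    def test_noise_only_where_signal(self, nema_default):
        vol, _ = nema_default
        out = pq.add_noise(vol, pq.ConditionPreset("n", 0, 0.1, 0.0), seed=1)
        assert np.all(out.voxels[vol.voxels == 0] == 0)


class TestConditionPresets:
    def test_default_family_satisfies_trend_constraints(self):
        validate_preset_family(pq.DEFAULT_PRESETS)
        rm = [p.psf_fwhm for p in pq.DEFAULT_PRESETS.values() if "RM" in p.label]
        no_rm = [p.psf_fwhm for p in pq.DEFAULT_PRESETS.values()
                 if "RM" not in p.label]
        assert max(rm) < min(no_rm)

    def test_violating_family_rejected(self):
        bad = dict(pq.DEFAULT_PRESETS)
        bad["RM"] = pq.ConditionPreset("RM", 9.9, 0.08, 8.5)
        with pytest.raises(GeometryError):
            validate_preset_family(bad)

    def test_uncorrected_condition_is_noisiest(self, nema_default, exact_pose):
        """NC total noise (NPS AUC) >= every corrected preset, matched seeds."""
        vol, truth = nema_default
        rois = pq.place_nema_rois(vol, exact_pose)
        for seed in range(3):
            aucs = {}
            for label, preset in pq.DEFAULT_PRESETS.items():
                v = pq.apply_system_blur(vol, preset.psf_fwhm)
                v = pq.add_noise(v, preset, seed)
                aucs[label] = pq.volume_nps(v, rois, truth.b_true).auc
            for label in ("RM", "TOF", "RM+TOF"):
                assert aucs["NC"] >= aucs[label]


class TestFullPipelineRecovery:
    def test_fine_grid_blur_recovers_largest_sphere(self):
        """A 2-pixel PSF on a 1-mm grid: RC(37 mm) >= 0.95 and RC monotone
        nondecreasing with sphere diameter."""
        vol, truth = pq.generate_nema_phantom(
            pq.PhantomTruth(), matrix_size=340, pixel_spacing=1.0,
            slice_spacing=2.0, n_slices=41)
        volb = pq.apply_system_blur(vol, 2.0 * vol.pixel_spacing)
        pose = pq.PhantomPose(0.0, 0.0, vol.n_slices // 2, 0.0)
        rois = pq.place_nema_rois(volb, pose)
        rc = pq.recovery_coefficients(volb, rois, truth.h_true, truth.b_true)
        values = rc.table.RC.to_numpy()
        assert values[-1] >= 0.95
        assert np.all(np.diff(values) >= 0)
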