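"""Recovery coefficients and CNR against analytic and constructed oracles."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

import petiq as pq
from petiq.errors import AnalysisError
from petiq.roi import CircularROI, ROISet, SquareROI
from petiq.volume import SliceAddress

FWHM_TO_SIGMA = 1.0 / 2.354820045


def sphere_gaussian_oracle(vol, geometry, psf_fwhm):
    """Continuum oracle for the blurred-sphere ROI mean: slice-thickness
    chord profile x in-plane voxel aperture x Gaussian PSF on a 0.1-mm grid,
    sampled at the implementation's ROI voxel centers."""
    T, p = vol.slice_spacing, vol.pixel_spacing
    sigma = psf_fwhm * FWHM_TO_SIGMA
    fine, half = 0.1, 40.0
    c = np.arange(-half, half + 1e-9, fine)
    xx, yy = np.meshgrid(c, c)
    kern = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    kern /= kern.sum()
    nb = int(round(p / fine))
    box = np.ones((nb, nb)) / nb**2
    out = {}
    for (cx, cy), d in zip(geometry.sphere_centers_xy(),
                           geometry.sphere_diameters):
        r = d / 2
        h = np.sqrt(np.clip(r * r - (xx**2 + yy**2), 0, None))
        chord = np.minimum(h, T / 2) * 2 / T
        conv = fftconvolve(fftconvolve(chord, box, mode="same"), kern,
                           mode="same")
        samples = []
        for yv in vol.y_coords()[np.abs(vol.y_coords() - cy) <= r + p]:
            for xv in vol.x_coords()[np.abs(vol.x_coords() - cx) <= r + p]:
                if (yv - cy) ** 2 + (xv - cx) ** 2 < r * r:
                    samples.append(conv[int(round((yv - cy + half) / fine)),
                                        int(round((xv - cx + half) / fine))])
        out[d] = float(np.mean(samples))
    return out


class TestRecoveryCoefficients:
    def test_ideal_phantom_recovers_unity(self):
        """Binary-rasterized, noiseless, unblurred phantom: RC = 1 exactly."""
        vol, truth = pq.generate_nema_phantom(pq.PhantomTruth(), supersample=1)
        pose = pq.PhantomPose(0.0, 0.0, vol.n_slices // 2, 0.0)
        rois = pq.place_nema_rois(vol, pose)
        rc = pq.recovery_coefficients(vol, rois, truth.h_true, truth.b_true)
        np.testing.assert_allclose(rc.table.RC.to_numpy(), 1.0, atol=0.01)

    def test_flat_volume_gives_zero(self, nema_default, nema_roiset):
        base, _ = nema_default
        vol = pq.Volume(np.full_like(base.voxels, 9.0), base.pixel_spacing,
                        base.slice_spacing, base.origin)
        rc = pq.recovery_coefficients(vol, nema_roiset, 40.0, 5.0)
        np.testing.assert_allclose(rc.table.RC.to_numpy(), 0.0, atol=1e-12)

    def test_zero_denominator_is_explicit_error(self, nema_default,
                                                nema_roiset):
        vol, _ = nema_default
        with pytest.raises(AnalysisError, match="denominator"):
            pq.recovery_coefficients(vol, nema_roiset, 5.0, 5.0)

    def test_blurred_rc_matches_convolution_oracle(self):
        """10-mm PSF on a 2-mm grid: every RC within 2% of the fine-grid
        sphere (x) Gaussian oracle."""
        vol, truth = pq.generate_nema_phantom(
            pq.PhantomTruth(), matrix_size=400, pixel_spacing=2.035)
        volb = pq.apply_system_blur(vol, 10.0)
        pose = pq.PhantomPose(0.0, 0.0, vol.n_slices // 2, 0.0)
        rois = pq.place_nema_rois(volb, pose)
        rc = pq.recovery_coefficients(volb, rois, truth.h_true, truth.b_true)
        oracle = sphere_gaussian_oracle(vol, pq.NemaGeometry(), 10.0)
        for d, expected in oracle.items():
            assert rc.rc(d) == pytest.approx(expected, rel=0.02)

    def test_affine_intensity_invariance(self, blurred_nema, nema_roiset):
        vol, truth = blurred_nema
        rc = pq.recovery_coefficients(vol, nema_roiset, truth.h_true,
                                      truth.b_true)
        scaled = pq.Volume(3.0 * vol.voxels, vol.pixel_spacing,
                           vol.slice_spacing, vol.origin)
        rc2 = pq.recovery_coefficients(scaled, nema_roiset, 3 * truth.h_true,
                                       3 * truth.b_true)
        np.testing.assert_allclose(rc.table.RC, rc2.table.RC, rtol=1e-12)

    def test_ensemble_rc_monotone_in_diameter(self, blurred_nema, nema_roiset):
        """Mean RC over 20 noise seeds increases with sphere size under blur."""
        vol, truth = blurred_nema
        preset = pq.ConditionPreset("n", 8.0, 0.08, 6.0)
        rcs = []
        for seed in range(20):
            nv = pq.add_noise(vol, preset, seed)
            rcs.append(pq.recovery_coefficients(
                nv, nema_roiset, truth.h_true, truth.b_true).table.RC.to_numpy())
        mean_rc = np.mean(rcs, axis=0)
        assert np.all(np.diff(mean_rc) > 0)


def _hand_built_roiset(vol, hot_center, bg_center, sd_center):
    """One hot ROI + 12 coincident background locations, with the 37-mm SD
    reference ROI placed at a *different* center so the size-matched mean and
    the 37-mm SD are distinguishable by construction."""
    mid = vol.n_slices // 2
    addr = SliceAddress(mid, 0.0)
    hot = [CircularROI(hot_center[0], hot_center[1], addr, 10.0,
                       "hot_sphere", 10.0)]
    background = {
        10.0: [CircularROI(bg_center[0], bg_center[1], addr, 10.0,
                           "background", 10.0, j) for j in range(12)],
        37.0: [CircularROI(sd_center[0], sd_center[1], addr, 37.0,
                           "background", 37.0, j) for j in range(12)],
    }
    nps = [SquareROI(bg_center[0], bg_center[1], addr, 9, j)
           for _ in range(5) for j in range(12)]
    return ROISet(hot, background, nps, addr)


class TestCNR:
    def test_collapses_to_single_roi_formula(self):
        """Identical background ROIs with SD s, hot mean h: CNR = (h - b)/s,
        and the SD comes from the 37-mm class, not the size-matched ROI."""
        origin = (-5.0, -99.5 * 4.07, -99.5 * 4.07)
        voxels = np.full((3, 200, 200), 5.0)
        vol = pq.Volume(voxels.copy(), 4.07, 5.0, origin=origin)
        ys, xs = np.meshgrid(vol.y_coords(), vol.x_coords(), indexing="ij")
        # 37-mm SD region (painted larger than the ROI): +/-2 checker, mean 5
        sd_mask = (ys - 80.0) ** 2 + (xs - 80.0) ** 2 < 21.0**2
        checker = np.indices((200, 200)).sum(axis=0) % 2
        plane = voxels[1].copy()
        plane[sd_mask] = 5.0 + 2.0 * np.where(checker[sd_mask] == 1, 1, -1)
        # hot region painted larger than the 10-mm hot ROI
        hot_mask = (ys + 80.0) ** 2 + (xs + 80.0) ** 2 < 9.0**2
        plane[hot_mask] = 21.0
        voxels[1] = plane
        vol = pq.Volume(voxels, 4.07, 5.0, origin=origin)

        rois = _hand_built_roiset(vol, (-80.0, -80.0), (0.0, 120.0),
                                  (80.0, 80.0))
        res = pq.contrast_to_noise(vol, rois)
        sigma37 = pq.roi_statistics(vol, rois.background_rois[37.0][0])[1]
        assert sigma37 > 0
        # size-matched (10 mm) background is constant: SD 0 there; the fact
        # that CNR is finite proves the 37-mm SD is the one used
        assert pq.roi_statistics(vol, rois.background_rois[10.0][0])[1] == 0
        expected = (21.0 - 5.0) / sigma37
        assert res.cnr(10.0) == pytest.approx(expected, rel=1e-12)

    def test_equal_means_give_zero(self):
        origin = (-5.0, -99.5 * 4.07, -99.5 * 4.07)
        voxels = np.full((3, 200, 200), 5.0)
        vol0 = pq.Volume(voxels.copy(), 4.07, 5.0, origin=origin)
        ys, xs = np.meshgrid(vol0.y_coords(), vol0.x_coords(), indexing="ij")
        checker = np.indices((200, 200)).sum(axis=0) % 2
        sd_mask = (ys - 80.0) ** 2 + (xs - 80.0) ** 2 < 21.0**2
        voxels[1][sd_mask] += 2.0 * np.where(checker[sd_mask] == 1, 1, -1)
        vol = pq.Volume(voxels, 4.07, 5.0, origin=origin)
        rois = _hand_built_roiset(vol, (-80.0, -80.0), (0.0, 120.0),
                                  (80.0, 80.0))
        res = pq.contrast_to_noise(vol, rois)
        assert abs(res.cnr(10.0)) < 1e-10

    def test_zero_sd_names_offending_roi(self, nema_default, nema_roiset):
        vol, _ = nema_default
        with pytest.raises(AnalysisError, match=r"ROI \d+ \(37 mm\)"):
            pq.contrast_to_noise(vol, nema_roiset)

    def test_linearity_in_contrast_at_fixed_noise(self, nema_roiset):
        """Doubling H_true - B_true with the identical noise field doubles
        CNR to within 2.5%."""
        rng = np.random.default_rng(5)
        vol1, _ = pq.generate_nema_phantom(pq.PhantomTruth(h_true=40.0,
                                                           b_true=5.0))
        vol2, _ = pq.generate_nema_phantom(pq.PhantomTruth(h_true=75.0,
                                                           b_true=5.0))
        b1 = pq.apply_system_blur(vol1, 8.0)
        b2 = pq.apply_system_blur(vol2, 8.0)
        noise = rng.normal(0, 0.4, b1.voxels.shape)
        n1 = pq.Volume(b1.voxels + noise, b1.pixel_spacing, b1.slice_spacing,
                       b1.origin)
        n2 = pq.Volume(b2.voxels + noise, b2.pixel_spacing, b2.slice_spacing,
                       b2.origin)
        c1 = pq.contrast_to_noise(n1, nema_roiset)
        c2 = pq.contrast_to_noise(n2, nema_roiset)
        ratios = (c2.table.CNR / c1.table.CNR).to_numpy()
        np.testing.assert_allclose(ratios, 2.0, atol=0.05)
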