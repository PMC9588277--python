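"""Point-source spatial resolution: line-profile FWHM and the MTF.

FWHM follows the NU-2 convention: the peak is located by a parabolic fit
through the maximum sample and its two neighbours, and each half-maximum
crossing is found by linear interpolation between the bracketing samples;
the image itself is never interpolated — profiles are the raw voxel row and
column through the peak.

The MTF is the magnitude spectrum of a 50 x 50 mm ROI around the point
source, normalized by the ROI integral so MTF(0) = 1.  The reported 1-D MTF
is the average of the 2-D MTF along the two zero-frequency lines in s_x and
s_y (with the +f and -f halves averaged).  Magnitude rather than real part
is used so sub-pixel source offsets (pure phase) do not bias the curve.  The
normalized ROI is zero-padded before the transform (interpolating the
spectrum, exactly as the NPS patches are padded) so that the MTF = 0.1
crossing — the limiting resolution — can be read off by linear interpolation
with negligible grid bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError
from .volume import Volume

__all__ = [
    "ProfileMeasurement",
    "MTFResult",
    "fwhm_of_profile",
    "profile_fwhm",
    "mtf_from_point_source",
    "limiting_resolution",
]


@dataclass
class ProfileMeasurement:
    direction: str            # "radial" | "tangential"
    samples: np.ndarray
    spacing: float            # mm
    peak_position: float      # sub-pixel, mm from profile start
    fwhm: float               # mm


@dataclass
class MTFResult:
    freqs: np.ndarray         # mm^-1, from 0 to Nyquist
    mtf: np.ndarray           # dimensionless, mtf[0] == 1
    limiting_resolution: float  # mm^-1 at MTF = 0.1 (nan if not computed)
    roi_size_mm: float


def _parabolic_vertex(y_m1: float, y_0: float, y_p1: float) -> tuple[float, float]:
    """(offset in samples, value) of the parabola through three points."""
    denom = y_m1 - 2 * y_0 + y_p1
    if denom >= 0:
        return 0.0, y_0
    dx = 0.5 * (y_m1 - y_p1) / denom
    val = y_0 - 0.25 * (y_m1 - y_p1) * dx
    return dx, val


def _half_crossing(samples: np.ndarray, half: float, peak_idx: int,
                   direction: int) -> float:
    """Sample position (fractional index) of the half-max crossing walking
    from the peak in ``direction`` (+1 right / -1 left)."""
    i = peak_idx
    while True:
        j = i + direction
        if j < 0 or j >= len(samples):
            raise AnalysisError("no half-maximum crossing inside the profile")
        if samples[j] <= half:
            # linear interpolation between samples i (above) and j (below)
            frac = (samples[i] - half) / (samples[i] - samples[j])
            return i + direction * frac
        i = j


def fwhm_of_profile(samples: np.ndarray, spacing: float,
                    direction: str = "radial") -> ProfileMeasurement:
    """FWHM of a 1-D profile (mm)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 3:
        raise AnalysisError("profile too short")
    peak_idx = int(np.argmax(samples))
    if peak_idx in (0, samples.size - 1):
        raise AnalysisError("profile peak at the edge; extend the profile")
    doff, peak_val = _parabolic_vertex(samples[peak_idx - 1], samples[peak_idx],
                                       samples[peak_idx + 1])
    half = peak_val / 2.0
    left = _half_crossing(samples, half, peak_idx, -1)
    right = _half_crossing(samples, half, peak_idx, +1)
    return ProfileMeasurement(
        direction=direction,
        samples=samples,
        spacing=spacing,
        peak_position=(peak_idx + doff) * spacing,
        fwhm=(right - left) * spacing,
    )


def profile_fwhm(volume: Volume, source_center: tuple[float, float],
                 direction: str = "radial",
                 slice_index: int | None = None) -> ProfileMeasurement:
    """FWHM of the line profile through a point source.

    ``source_center`` is (y, x) in mm.  For a source on (or near) the scanner
    axis the radial profile is the image row (x direction) and the tangential
    profile the column (y direction); for an off-axis source the grid axis
    closest to the radial unit vector is used — profiles always run along
    voxel rows/columns, never through interpolated samples.
    """
    if direction not in ("radial", "tangential"):
        raise AnalysisError(f"unknown direction {direction!r}")
    sy, sx = source_center
    k = slice_index if slice_index is not None else volume.n_slices // 2
    iy = int(round((sy - volume.origin[1]) / volume.pixel_spacing))
    ix = int(round((sx - volume.origin[2]) / volume.pixel_spacing))
    # refine to the actual peak voxel in a small neighbourhood
    ny, nx = volume.voxels.shape[1:]
    y0, y1 = max(iy - 3, 0), min(iy + 4, ny)
    x0, x1 = max(ix - 3, 0), min(ix + 4, nx)
    sub = volume.voxels[k, y0:y1, x0:x1]
    dy, dx = np.unravel_index(np.argmax(sub), sub.shape)
    iy, ix = y0 + int(dy), x0 + int(dx)

    # radial axis = grid axis nearest the center->source direction (x if on axis)
    if abs(sy) > abs(sx):
        radial_is_x = False
    else:
        radial_is_x = True
    along_x = radial_is_x if direction == "radial" else not radial_is_x
    samples = volume.voxels[k, iy, :] if along_x else volume.voxels[k, :, ix]
    return fwhm_of_profile(samples, volume.pixel_spacing, direction)


def mtf_from_point_source(
    volume: Volume,
    source_center: tuple[float, float],
    roi_size_mm: float = 50.0,
    pad_to: int = 1024,
    slice_index: int | None = None,
    subtract_tails: bool = False,
    threshold: float = 0.1,
) -> MTFResult:
    """MTF of the point-spread function sampled around ``source_center``.

    ``subtract_tails`` (default off — sources are in air) removes the mean of
    the ROI border ring before normalization, for noisy inputs.
    """
    sy, sx = source_center
    k = slice_index if slice_index is not None else volume.n_slices // 2
    p = volume.pixel_spacing
    half_px = int(round(roi_size_mm / 2.0 / p))
    iy = int(round((sy - volume.origin[1]) / p))
    ix = int(round((sx - volume.origin[2]) / p))
    ny, nx = volume.voxels.shape[1:]
    if (iy - half_px < 0 or ix - half_px < 0
            or iy + half_px >= ny or ix + half_px >= nx):
        raise AnalysisError(f"{roi_size_mm} mm ROI does not fit in the image")
    roi = volume.voxels[k, iy - half_px: iy + half_px + 1,
                        ix - half_px: ix + half_px + 1].copy()
    if subtract_tails:
        border = np.concatenate([roi[0, :], roi[-1, :], roi[1:-1, 0], roi[1:-1, -1]])
        roi -= border.mean()
    total = roi.sum()
    if total <= 0:
        raise AnalysisError("ROI integral is not positive; cannot normalize PSF")
    roi /= total

    n = roi.shape[0]
    pad = max(pad_to, n)
    padded = np.zeros((pad, pad))
    padded[:n, :n] = roi
    ft = np.abs(np.fft.fft2(padded))
    n_pos = pad // 2
    # average of the two zero-frequency lines, +f and -f halves folded
    line_x = 0.5 * (ft[0, 1:n_pos + 1] + ft[0, -1:-n_pos - 1:-1])
    line_y = 0.5 * (ft[1:n_pos + 1, 0] + ft[-1:-n_pos - 1:-1, 0])
    mtf = np.concatenate([[ft[0, 0]], 0.5 * (line_x + line_y)])
    mtf = mtf / mtf[0]
    freqs = np.arange(n_pos + 1) / (pad * p)

    result = MTFResult(freqs, mtf, float("nan"), roi_size_mm)
    try:
        result.limiting_resolution = limiting_resolution(result, threshold)
    except AnalysisError:
        pass
    return result


def limiting_resolution(mtfresult: MTFResult, threshold: float = 0.1) -> float:
    """Frequency (mm^-1) of the first downward crossing of ``threshold``,
    linearly interpolated between the bracketing frequency samples."""
    mtf, freqs = mtfresult.mtf, mtfresult.freqs
    if threshold >= mtf[0]:
        return 0.0
    below = np.flatnonzero(mtf < threshold)
    if below.size == 0:
        raise AnalysisError(
            f"MTF never falls below {threshold}: min {mtf.min():.4f} at "
            f"max frequency {freqs[-1]:.4f} mm^-1"
        )
    j = int(below[0])
    f0, f1 = freqs[j - 1], freqs[j]
    m0, m1 = mtf[j - 1], mtf[j]
    return float(f0 + (m0 - threshold) / (m0 - m1) * (f1 - f0))
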