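"""Digital phantoms with known ground truth.

This module is the no-scanner test bed for the whole metric pipeline.  It
emulates the two acquisitions the analysis expects:

* a NEMA IQ body phantom — six hot spheres on a ring at a known
  sphere-to-background activity ratio, a cold lung insert, uniform warm
  background — rasterized as a piecewise-constant activity map with
  partial-volume handling by subpixel supersampling;
* point sources in air, deposited as subpixel bilinear impulses.

Imaging physics is reduced to two controllable stages: an in-plane Gaussian
system PSF (:func:`apply_system_blur`) and additive, optionally spatially
correlated Gaussian noise whose local standard deviation is proportional to
the noiseless signal (:func:`add_noise`).  Reconstruction conditions
(NC / RM / TOF / RM+TOF) are represented purely as presets of PSF width,
noise amplitude and noise correlation length; nothing downstream ever
branches on what a condition label "means".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GeometryError, VolumeError
from .geometry import NemaGeometry
from .volume import Volume

__all__ = [
    "PhantomTruth",
    "ConditionPreset",
    "DEFAULT_PRESETS",
    "generate_nema_phantom",
    "generate_point_sources",
    "apply_system_blur",
    "add_noise",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside every synthetic NEMA volume."""

    h_true: float = 40.0            # hot-sphere activity concentration, kBq/ml
    b_true: float = 5.0             # background concentration, kBq/ml
    sphere_diameters: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    lung_insert_diameter: float = 50.0
    psf_fwhm: float = 0.0           # mm; blur the volume has been through
    noise_model: dict | None = None
    seed: int = 0
    sphere_centers: tuple[tuple[float, float, float], ...] = ()  # (z, y, x) mm

    def __post_init__(self) -> None:
        if not (self.h_true > self.b_true >= 0):
            raise GeometryError(
                f"need H_true > B_true >= 0, got H={self.h_true}, B={self.b_true}"
            )
        if list(self.sphere_diameters) != sorted(self.sphere_diameters):
            raise GeometryError("sphere diameters must be sorted ascending")


@dataclass(frozen=True)
class ConditionPreset:
    """Noise/PSF proxy for one reconstruction condition.

    ``psf_fwhm`` is the effective in-plane system PSF (mm); ``noise_amplitude``
    is the noise SD as a fraction of the local mean; ``noise_correlation_fwhm``
    is the FWHM (mm) of the Gaussian that shapes the white noise field into
    correlated reconstruction-like texture (variance preserved).
    """

    label: str
    psf_fwhm: float
    noise_amplitude: float
    noise_correlation_fwhm: float


# Defaults reproduce the qualitative condition ordering of resolution-modeled
# and time-of-flight reconstructions: RM narrows the PSF and pushes noise
# power toward low frequencies (longer correlation); TOF lowers the noise
# amplitude; the uncorrected condition is the noisiest overall.  PSF widths
# are typical published point-source FWHMs for a clinical TOF/PSF scanner
# with an 8-mm post-filter.  Amplitudes are trend-calibrated, not fitted to
# any measured noise table.
DEFAULT_PRESETS: dict[str, ConditionPreset] = {
    "NC": ConditionPreset("NC", psf_fwhm=9.36, noise_amplitude=0.100,
                          noise_correlation_fwhm=6.0),
    "TOF": ConditionPreset("TOF", psf_fwhm=9.31, noise_amplitude=0.080,
                           noise_correlation_fwhm=6.0),
    "RM": ConditionPreset("RM", psf_fwhm=8.52, noise_amplitude=0.082,
                          noise_correlation_fwhm=8.5),
    "RM+TOF": ConditionPreset("RM+TOF", psf_fwhm=8.55, noise_amplitude=0.075,
                              noise_correlation_fwhm=7.5),
}


def validate_preset_family(presets: dict[str, ConditionPreset]) -> None:
    """Check the qualitative cross-condition constraints of a preset family:
    RM-labeled PSFs strictly narrower than non-RM ones; TOF presets quieter
    than NC at matched correlation length."""
    rm = [p.psf_fwhm for p in presets.values() if "RM" in p.label]
    no_rm = [p.psf_fwhm for p in presets.values() if "RM" not in p.label]
    if rm and no_rm and max(rm) >= min(no_rm):
        raise GeometryError("RM presets must have strictly narrower PSF")
    nc = presets.get("NC")
    if nc is not None:
        for p in presets.values():
            if "TOF" in p.label and p.noise_correlation_fwhm == nc.noise_correlation_fwhm:
                if not p.noise_amplitude < nc.noise_amplitude:
                    raise GeometryError(
                        f"TOF preset {p.label} must be quieter than NC"
                    )


# ---------------------------------------------------------------------------
# NEMA phantom rasterization
# ---------------------------------------------------------------------------

def _centered_coords(n: int, spacing: float) -> np.ndarray:
    """Physical coordinates of voxel centers with the grid center at 0."""
    return (np.arange(n) - (n - 1) / 2.0) * spacing


def _plane_coverage(shape_fn, nx: int, ny: int, pixel_spacing: float,
                    center: tuple[float, float], rotation_deg: float,
                    supersample: int) -> np.ndarray:
    """Per-pixel area fraction covered by a 2-D shape given in the phantom
    frame, using midpoint supersampling (``supersample`` points per axis)."""
    s = supersample
    sub = (np.arange(s) + 0.5) / s - 0.5
    xs = (_centered_coords(nx, pixel_spacing)[:, None] + (sub * pixel_spacing)[None, :]).ravel()
    ys = (_centered_coords(ny, pixel_spacing)[:, None] + (sub * pixel_spacing)[None, :]).ravel()
    gx, gy = np.meshgrid(xs, ys)
    # image frame -> phantom frame
    cy, cx = center
    th = np.deg2rad(rotation_deg)
    px = (gx - cx) * np.cos(th) + (gy - cy) * np.sin(th)
    py = -(gx - cx) * np.sin(th) + (gy - cy) * np.cos(th)
    mask = shape_fn(px, py).astype(np.float64)
    mask = mask.reshape(ny, s, nx, s)
    return mask.mean(axis=(1, 3))


def generate_nema_phantom(
    truth: PhantomTruth,
    matrix_size: int = 200,
    pixel_spacing: float = 4.07,
    slice_spacing: float = 5.0,
    n_slices: int = 25,
    geometry: NemaGeometry | None = None,
    center_mm: tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
    supersample: int = 4,
) -> tuple[Volume, PhantomTruth]:
    """Rasterize a noiseless NEMA IQ phantom activity map.

    The body and lung insert are cylinders spanning the whole axial extent;
    the sphere centers sit on the central slice plane.  ``center_mm`` =
    (y, x) offset and ``rotation_deg`` give the phantom pose in the image.
    ``supersample`` points per axis bound the partial-volume rasterization
    error (1 disables partial-volume handling: pure center-in-region
    labeling).  Returns the volume and the truth record with sphere centers
    filled in.
    """
    geometry = geometry or NemaGeometry(
        sphere_diameters=tuple(truth.sphere_diameters),
        lung_insert_diameter=truth.lung_insert_diameter,
    )
    nx = ny = matrix_size
    fov = matrix_size * pixel_spacing
    if fov < 300.0:
        raise GeometryError(
            f"field of view {fov:.0f} mm cannot accommodate the phantom body"
        )

    # sphere centers in the image frame
    th = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    centers_xy = geometry.sphere_centers_xy() @ rot.T
    centers_xy += np.array([center_mm[1], center_mm[0]])  # (x, y)
    z_ref = 0.0  # sphere plane = physical z 0 (central slice of the grid)

    # every sphere must lie fully inside the body (checked in phantom frame)
    for (cx, cy), d in zip(geometry.sphere_centers_xy(), geometry.sphere_diameters):
        ang = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        ex = cx + (d / 2) * np.cos(ang)
        ey = cy + (d / 2) * np.sin(ang)
        if not np.all(NemaGeometry.body_contains(ex, ey)):
            raise GeometryError(
                f"sphere of diameter {d} mm extends outside the phantom body"
            )

    body = _plane_coverage(NemaGeometry.body_contains, nx, ny, pixel_spacing,
                           center_mm, rotation_deg, supersample)
    lung_r = geometry.lung_insert_diameter / 2.0
    lung = _plane_coverage(lambda x, y: x * x + y * y <= lung_r * lung_r,
                           nx, ny, pixel_spacing, center_mm, rotation_deg,
                           supersample)

    plane = truth.b_true * (body - lung)
    voxels = np.repeat(plane[None, :, :], n_slices, axis=0)

    # spheres: 3-D partial volume within bounding boxes only
    xc = _centered_coords(nx, pixel_spacing)
    yc = _centered_coords(ny, pixel_spacing)
    zc = _centered_coords(n_slices, slice_spacing)
    s = supersample
    sub = (np.arange(s) + 0.5) / s - 0.5
    sphere_centers = []
    for (cx, cy), d in zip(centers_xy, geometry.sphere_diameters):
        r = d / 2.0
        sphere_centers.append((z_ref, cy, cx))
        ix = np.flatnonzero(np.abs(xc - cx) <= r + pixel_spacing)
        iy = np.flatnonzero(np.abs(yc - cy) <= r + pixel_spacing)
        iz = np.flatnonzero(np.abs(zc - z_ref) <= r + slice_spacing)
        if len(ix) == 0 or len(iy) == 0 or len(iz) == 0:
            raise GeometryError(f"sphere of diameter {d} mm falls outside the grid")
        fx = (xc[ix][:, None] + (sub * pixel_spacing)[None, :]).ravel() - cx
        fy = (yc[iy][:, None] + (sub * pixel_spacing)[None, :]).ravel() - cy
        fz = (zc[iz][:, None] + (sub * slice_spacing)[None, :]).ravel() - z_ref
        d2 = (fz[:, None, None] ** 2 + fy[None, :, None] ** 2
              + fx[None, None, :] ** 2)
        cov = (d2 <= r * r).reshape(len(iz), s, len(iy), s, len(ix), s)
        cov = cov.mean(axis=(1, 3, 5))
        voxels[np.ix_(iz, iy, ix)] += (truth.h_true - truth.b_true) * cov

    origin = (float(zc[0]), float(yc[0]), float(xc[0]))
    vol = Volume(voxels, pixel_spacing, slice_spacing, origin,
                 frame_of_reference="synthetic-nema")
    out_truth = replace(truth, sphere_centers=tuple(sphere_centers))
    return vol, out_truth


# ---------------------------------------------------------------------------
# Point sources
# ---------------------------------------------------------------------------

def generate_point_sources(
    positions: list[tuple[float, float]],
    amplitude: float = 1000.0,
    matrix_size: int = 512,
    pixel_spacing: float = 1.59,
    n_slices: int = 1,
    slice_spacing: float = 3.0,
) -> Volume:
    """Deposit point sources in air on a single-slice (by default) grid.

    ``positions`` are in-plane (y, x) mm relative to the image center; each
    source is splatted bilinearly onto the four surrounding voxel centers so
    the total deposited signal per source equals ``amplitude`` for arbitrary
    subpixel positions.
    """
    voxels = np.zeros((n_slices, matrix_size, matrix_size))
    mid = n_slices // 2
    half = (matrix_size - 1) / 2.0
    for (py, px) in positions:
        fy = py / pixel_spacing + half
        fx = px / pixel_spacing + half
        iy, ix = int(np.floor(fy)), int(np.floor(fx))
        wy, wx = fy - iy, fx - ix
        if not (0 <= iy < matrix_size - 1 and 0 <= ix < matrix_size - 1):
            raise GeometryError(f"source at (y={py}, x={px}) mm outside field of view")
        voxels[mid, iy, ix] += amplitude * (1 - wy) * (1 - wx)
        voxels[mid, iy, ix + 1] += amplitude * (1 - wy) * wx
        voxels[mid, iy + 1, ix] += amplitude * wy * (1 - wx)
        voxels[mid, iy + 1, ix + 1] += amplitude * wy * wx
    origin = (-(n_slices - 1) / 2.0 * slice_spacing,
              -half * pixel_spacing, -half * pixel_spacing)
    return Volume(voxels, pixel_spacing, slice_spacing, origin,
                  frame_of_reference="synthetic-point-sources")


# ---------------------------------------------------------------------------
# Imaging model
# ---------------------------------------------------------------------------

def apply_system_blur(volume: Volume, psf_fwhm_mm: float) -> Volume:
    """Convolve each slice with an isotropic in-plane Gaussian PSF.

    Signal is conserved up to boundary truncation; FWHM 0 is the identity.
    """
    if psf_fwhm_mm < 0:
        raise VolumeError("psf_fwhm must be >= 0")
    if psf_fwhm_mm == 0:
        return Volume(volume.voxels.copy(), volume.pixel_spacing,
                      volume.slice_spacing, volume.origin,
                      volume.frame_of_reference)
    sigma = psf_fwhm_mm * FWHM_TO_SIGMA / volume.pixel_spacing
    blurred = gaussian_filter(volume.voxels, sigma=(0, sigma, sigma),
                              mode="constant", truncate=6.0)
    return Volume(blurred, volume.pixel_spacing, volume.slice_spacing,
                  volume.origin, volume.frame_of_reference)


def _smoothing_kernel_energy(sigma_px: float) -> float:
    """sqrt(sum of squared weights) of the discrete 2-D Gaussian smoother."""
    n = 2 * int(np.ceil(6 * sigma_px) + 1) + 1
    imp = np.zeros((n, n))
    imp[n // 2, n // 2] = 1.0
    k = gaussian_filter(imp, sigma_px, mode="constant", truncate=6.0)
    return float(np.sqrt((k * k).sum()))


def add_noise(volume: Volume, preset: ConditionPreset, seed: int) -> Volume:
    """Add zero-mean Gaussian noise with SD = amplitude x local (noiseless)
    mean, optionally low-pass shaped in-plane.

    The white field is smoothed with a Gaussian of FWHM
    ``preset.noise_correlation_fwhm`` and rescaled so its variance is
    preserved — only the noise *texture* changes, never its magnitude.
    Amplitude 0 returns the input unchanged; results are reproducible per
    seed.
    """
    if preset.noise_amplitude < 0:
        raise VolumeError("noise amplitude must be >= 0")
    if preset.noise_amplitude == 0:
        return Volume(volume.voxels.copy(), volume.pixel_spacing,
                      volume.slice_spacing, volume.origin,
                      volume.frame_of_reference)
    rng = np.random.default_rng(seed)
    field_ = rng.standard_normal(volume.voxels.shape)
    if preset.noise_correlation_fwhm > 0:
        sigma = preset.noise_correlation_fwhm * FWHM_TO_SIGMA / volume.pixel_spacing
        field_ = gaussian_filter(field_, sigma=(0, sigma, sigma),
                                 mode="constant", truncate=6.0)
        field_ /= _smoothing_kernel_energy(sigma)
    noisy = volume.voxels * (1.0 + preset.noise_amplitude * field_)
    return Volume(noisy, volume.pixel_spacing, volume.slice_spacing,
                  volume.origin, volume.frame_of_reference)
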