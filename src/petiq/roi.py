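"""Placement of NEMA image-quality ROIs and basic ROI statistics.

An :class:`ROISet` carries the full NU-2 measurement layout on a volume:

* one circular ROI per hot sphere, matched in physical diameter and centered
  on the sphere;
* twelve background locations on the central slice, each carrying one
  concentric circular ROI per sphere size class (the 37-mm ROI plus the five
  smaller sizes it contains);
* sixty 9x9-pixel square ROIs for the noise-power spectrum: the twelve
  background locations replicated on the five NEMA slices (sphere-center
  plane and +/-10, +/-20 mm).

The voxel-in-ROI rule is deliberately simple and reproducible: a voxel
belongs to a circular ROI iff its *center* is strictly inside the circle; no
fractional weighting.  Square ROIs are snapped to the nearest voxel center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.feature import match_template

from .errors import AnalysisError, GeometryError
from .geometry import NemaGeometry
from .volume import SliceAddress, Volume, slice_at_offset

__all__ = [
    "CircularROI",
    "SquareROI",
    "ROISet",
    "PhantomPose",
    "locate_phantom",
    "place_nema_rois",
    "roi_statistics",
    "extract_patch",
]

NPS_SLICE_OFFSETS_MM = (-20.0, -10.0, 0.0, 10.0, 20.0)


@dataclass(frozen=True)
class PhantomPose:
    """Phantom pose in the image: in-plane center (mm), reference slice
    (sphere-center plane) and rotation about the axial axis (deg)."""

    center_y_mm: float
    center_x_mm: float
    reference_slice: int
    rotation_deg: float = 0.0
    score: float = float("nan")


@dataclass(frozen=True)
class CircularROI:
    center_y_mm: float
    center_x_mm: float
    slice: SliceAddress
    diameter_mm: float
    role: str  # "hot_sphere" | "background"
    size_class_mm: float
    location: int = -1  # background location index 0..11, -1 for hot ROIs

    def mask(self, volume: Volume) -> np.ndarray:
        """Boolean in-plane mask of voxel centers strictly inside the circle."""
        yy = volume.y_coords()[:, None] - self.center_y_mm
        xx = volume.x_coords()[None, :] - self.center_x_mm
        return yy * yy + xx * xx < (self.diameter_mm / 2.0) ** 2


@dataclass(frozen=True)
class SquareROI:
    center_y_mm: float
    center_x_mm: float
    slice: SliceAddress
    side_pixels: int = 9
    location: int = -1

    def __post_init__(self) -> None:
        if self.side_pixels % 2 == 0:
            raise GeometryError("square ROI side must be odd (center-symmetric)")

    def index_bounds(self, volume: Volume) -> tuple[int, int, int, int]:
        """(y0, y1, x0, x1) voxel-index bounds (half-open) after snapping the
        center to the nearest voxel center."""
        iy = int(round((self.center_y_mm - volume.origin[1]) / volume.pixel_spacing))
        ix = int(round((self.center_x_mm - volume.origin[2]) / volume.pixel_spacing))
        h = self.side_pixels // 2
        return iy - h, iy + h + 1, ix - h, ix + h + 1


@dataclass
class ROISet:
    """Complete NEMA ROI layout for one volume."""

    hot_rois: list[CircularROI]
    background_rois: dict[float, list[CircularROI]]  # size class -> 12 ROIs
    nps_rois: list[SquareROI]
    reference_slice: SliceAddress

    def validate(self) -> None:
        if len(self.nps_rois) != 60:
            raise GeometryError(f"expected 60 NPS ROIs, have {len(self.nps_rois)}")
        for size, rois in self.background_rois.items():
            if len(rois) != 12:
                raise GeometryError(
                    f"size class {size} mm has {len(rois)} background ROIs, need 12"
                )

    # -- audit serialization ---------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.hot_rois:
            rows.append(("hot_sphere", r.size_class_mm, r.location,
                         r.center_y_mm, r.center_x_mm, r.slice.slice_index,
                         r.diameter_mm))
        for size, rois in sorted(self.background_rois.items()):
            for r in rois:
                rows.append(("background", size, r.location, r.center_y_mm,
                             r.center_x_mm, r.slice.slice_index, r.diameter_mm))
        for r in self.nps_rois:
            rows.append(("nps", float(r.side_pixels), r.location,
                         r.center_y_mm, r.center_x_mm, r.slice.slice_index,
                         np.nan))
        return pd.DataFrame(rows, columns=["role", "size_class_mm", "location",
                                           "center_y_mm", "center_x_mm",
                                           "slice_index", "diameter_mm"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pose estimation
# ---------------------------------------------------------------------------

def _ring_template(geometry: NemaGeometry, pixel_spacing: float,
                   rotation_deg: float) -> np.ndarray:
    """Rasterized sphere-ring template (+1 in sphere discs, -1 in the lung
    insert) used for normalized cross-correlation."""
    extent = geometry.ring_radius + max(geometry.sphere_diameters) / 2 + 2 * pixel_spacing
    n = 2 * int(np.ceil(extent / pixel_spacing)) + 1
    c = (np.arange(n) - (n - 1) / 2.0) * pixel_spacing
    xx, yy = np.meshgrid(c, c)
    tpl = np.zeros((n, n))
    th = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    for (cx, cy), d in zip(geometry.sphere_centers_xy() @ rot.T,
                           geometry.sphere_diameters):
        tpl[(xx - cx) ** 2 + (yy - cy) ** 2 < (d / 2) ** 2] = 1.0
    tpl[xx**2 + yy**2 < (geometry.lung_insert_diameter / 2) ** 2] = -1.0
    return tpl


def _parabolic_offset(m1: float, m0: float, p1: float) -> float:
    denom = m1 - 2 * m0 + p1
    if denom >= 0:
        return 0.0
    return 0.5 * (m1 - p1) / denom


def locate_phantom(
    volume: Volume,
    geometry: NemaGeometry | None = None,
    pose: PhantomPose | None = None,
    rotation_search_deg: float = 15.0,
    rotation_step_deg: float = 0.5,
    min_score: float = 0.3,
) -> PhantomPose:
    """Estimate the phantom pose by sphere-ring template correlation.

    If ``pose`` is supplied it is returned verbatim (config wins; no search).
    Otherwise the sphere-center slice is taken as the slice with the largest
    robust contrast, and the in-plane center/rotation maximize the normalized
    cross-correlation with the ring template; ties between rotations are
    broken toward the smallest rotation magnitude.  Sub-pixel center refined
    by parabolic interpolation of the correlation peak.
    """
    if pose is not None:
        return pose
    geometry = geometry or NemaGeometry()

    # sphere-center plane = slice with the most integrated hot signal above
    # the background level (median of in-body voxels)
    contrast = []
    for s in volume.voxels:
        if not np.any(s > 0):
            contrast.append(0.0)
            continue
        bg = np.median(s[s > 0])
        excess = np.clip(s - bg, 0, None)
        contrast.append(float((excess * excess).sum()))
    ref = int(np.argmax(contrast))
    image = volume.voxels[ref]
    if image.max() - image.min() <= 0:
        raise AnalysisError("phantom not found: volume is uniform; "
                            "supply the pose manually")

    rotations = np.arange(-rotation_search_deg, rotation_search_deg + 1e-9,
                          rotation_step_deg)
    rotations = rotations[np.argsort(np.abs(rotations), kind="stable")]
    tpl_n = _ring_template(geometry, volume.pixel_spacing, 0.0).shape[0]
    # (near-)empty windows outside the phantom produce spurious normalized
    # correlations; only windows holding a substantial part of the phantom
    # signal are admissible peak locations
    wsum = uniform_filter(image, size=tpl_n, mode="constant")
    h = (tpl_n - 1) // 2
    best = (-np.inf, 0.0, 0, 0, None)  # score, rot, iy, ix, response
    for rot_deg in rotations:
        tpl = _ring_template(geometry, volume.pixel_spacing, rot_deg)
        resp = match_template(image, tpl, pad_input=False)
        resp = np.where(np.abs(resp) <= 1.0, resp, -1.0)
        content = wsum[h:h + resp.shape[0], h:h + resp.shape[1]]
        resp = np.where(content >= 0.5 * content.max(), resp, -1.0)
        iy, ix = np.unravel_index(np.argmax(resp), resp.shape)
        score = float(resp[iy, ix])
        if score > best[0] + 1e-12:
            best = (score, rot_deg, int(iy), int(ix), resp)
    score, rot_deg, iy, ix, resp = best
    if score < min_score:
        raise AnalysisError(
            f"phantom not found: best template correlation {score:.3f} < "
            f"{min_score}; supply the pose manually"
        )
    dy = dx = 0.0
    if 0 < iy < resp.shape[0] - 1:
        dy = _parabolic_offset(resp[iy - 1, ix], resp[iy, ix], resp[iy + 1, ix])
    if 0 < ix < resp.shape[1] - 1:
        dx = _parabolic_offset(resp[iy, ix - 1], resp[iy, ix], resp[iy, ix + 1])
    # valid-mode response index = window top-left; shift to template center
    half = (tpl_n - 1) / 2.0
    cy = volume.origin[1] + (iy + dy + half) * volume.pixel_spacing
    cx = volume.origin[2] + (ix + dx + half) * volume.pixel_spacing
    return PhantomPose(cy, cx, ref, rot_deg, score)


# ---------------------------------------------------------------------------
# ROI placement
# ---------------------------------------------------------------------------

def _rotate_translate(points_xy: np.ndarray, pose: PhantomPose) -> np.ndarray:
    th = np.deg2rad(pose.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    out = points_xy @ rot.T
    return out + np.array([pose.center_x_mm, pose.center_y_mm])


def _check_inside(volume: Volume, roi_name: str, cy: float, cx: float,
                  radius_mm: float) -> None:
    y0, y1 = volume.y_coords()[0], volume.y_coords()[-1]
    x0, x1 = volume.x_coords()[0], volume.x_coords()[-1]
    if (cy - radius_mm < y0 or cy + radius_mm > y1
            or cx - radius_mm < x0 or cx + radius_mm > x1):
        raise GeometryError(f"ROI {roi_name} clipped by the image edge")


def place_nema_rois(
    volume: Volume,
    pose: PhantomPose,
    geometry: NemaGeometry | None = None,
    nps_side_pixels: int = 9,
) -> ROISet:
    """Place the full NEMA ROI layout for the given phantom pose."""
    geometry = geometry or NemaGeometry()
    ref_addr = SliceAddress(pose.reference_slice, 0.0)

    sphere_xy = _rotate_translate(geometry.sphere_centers_xy(), pose)
    hot_rois = []
    for (cx, cy), d in zip(sphere_xy, geometry.sphere_diameters):
        _check_inside(volume, f"hot sphere {d} mm", cy, cx, d / 2)
        hot_rois.append(CircularROI(cy, cx, ref_addr, d, "hot_sphere", d))

    bg_xy = _rotate_translate(np.asarray(geometry.background_centers), pose)
    # background ROIs must not overlap any sphere (checked for the 37-mm class)
    max_d = max(geometry.sphere_diameters)
    for j, (bx, by) in enumerate(bg_xy):
        for (sx, sy), d in zip(sphere_xy, geometry.sphere_diameters):
            if np.hypot(bx - sx, by - sy) < (max_d + d) / 2.0:
                raise GeometryError(
                    f"background ROI {j} overlaps the {d} mm sphere"
                )

    background: dict[float, list[CircularROI]] = {}
    for d in geometry.sphere_diameters:
        rois = []
        for j, (bx, by) in enumerate(bg_xy):
            _check_inside(volume, f"background {j} ({d} mm)", by, bx, d / 2)
            rois.append(CircularROI(by, bx, ref_addr, d, "background", d, j))
        background[float(d)] = rois

    nps_rois = []
    for off in NPS_SLICE_OFFSETS_MM:
        addr = slice_at_offset(volume, pose.reference_slice, off)
        for j, (bx, by) in enumerate(bg_xy):
            half_mm = (nps_side_pixels // 2 + 0.5) * volume.pixel_spacing
            _check_inside(volume, f"NPS {j}@{off:+.0f}mm", by, bx, half_mm)
            nps_rois.append(SquareROI(by, bx, addr, nps_side_pixels, j))

    roiset = ROISet(hot_rois, background, nps_rois, ref_addr)
    roiset.validate()
    return roiset


# ---------------------------------------------------------------------------
# Statistics & patch extraction
# ---------------------------------------------------------------------------

def roi_statistics(volume: Volume, roi: CircularROI | SquareROI):
    """(mean, population SD, n_voxels) over the voxels inside ``roi``."""
    if isinstance(roi, CircularROI):
        mask = roi.mask(volume)
        if not mask.any():
            raise AnalysisError("ROI mask is empty (no voxel center inside)")
        values = volume.voxels[roi.slice.slice_index][mask]
    else:
        values = extract_patch(volume, roi).ravel()
    return float(values.mean()), float(values.std()), int(values.size)


def extract_patch(volume: Volume, roi: SquareROI) -> np.ndarray:
    """The side x side pixel block of a square ROI."""
    y0, y1, x0, x1 = roi.index_bounds(volume)
    ny, nx = volume.voxels.shape[1:]
    if y0 < 0 or x0 < 0 or y1 > ny or x1 > nx:
        raise GeometryError("square ROI outside the image")
    return volume.voxels[roi.slice.slice_index, y0:y1, x0:x1]
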