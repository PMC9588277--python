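"""Voxel volumes of activity concentration with physical geometry.

A :class:`Volume` is the single in-memory image model every metric module
works on: a 3-D grid of activity concentration (kBq/ml) ordered (slice, row,
column) = (z, y, x), with isotropic in-plane pixel spacing, a uniform axial
slice spacing, and the physical position (mm) of the *center* of voxel
(0, 0, 0).  Voxel indices are 0-based and physical coordinates always refer
to voxel centers; decay correction is never applied here — values are taken
as stored, i.e. concentrations at scan time.

I/O: DICOM PET series (via pydicom, rescale slope/intercept applied on read)
and a lossless portable container (``.npz`` voxel array + embedded JSON
metadata) used for synthetic volumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import VolumeError

__all__ = [
    "Volume",
    "SliceAddress",
    "read_dicom_series",
    "read_volume",
    "write_volume",
    "slice_at_offset",
]

PET_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.128"


@dataclass
class Volume:
    """3-D activity-concentration grid with physical spacing.

    Parameters
    ----------
    voxels
        Array of shape (n_slices, n_rows, n_cols), kBq/ml.
    pixel_spacing
        In-plane spacing, mm/pixel, identical along rows and columns.
    slice_spacing
        Axial spacing between adjacent slice centers, mm.
    origin
        Physical (z, y, x) position in mm of the center of voxel (0, 0, 0).
    frame_of_reference
        Free-text provenance tag.
    """

    voxels: np.ndarray
    pixel_spacing: float
    slice_spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_of_reference: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.validate()

    # -- geometry helpers -------------------------------------------------
    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def z_positions(self) -> np.ndarray:
        """Physical z (mm) of every slice center."""
        return self.origin[0] + np.arange(self.n_slices) * self.slice_spacing

    def y_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.voxels.shape[1]) * self.pixel_spacing

    def x_coords(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.voxels.shape[2]) * self.pixel_spacing

    def validate(self) -> None:
        if self.voxels.ndim != 3:
            raise VolumeError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if not (self.pixel_spacing > 0 and self.slice_spacing > 0):
            raise VolumeError(
                f"spacings must be positive (pixel={self.pixel_spacing}, "
                f"slice={self.slice_spacing})"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise VolumeError("voxel values must be finite (NaN/Inf present)")
        ny, nx = self.voxels.shape[1:]
        if min(ny, nx) < 64:
            raise VolumeError(
                f"in-plane dimensions must be >= 64, got {ny}x{nx} "
                "(needed for NPS zero-padding)"
            )


@dataclass(frozen=True)
class SliceAddress:
    """A slice identified both by index and by signed axial offset (mm) from a
    named reference slice.  ``residual_mm`` is the distance between the
    requested physical offset and the nearest realizable slice center."""

    slice_index: int
    axial_offset_mm: float
    residual_mm: float = 0.0


def slice_at_offset(volume: Volume, reference_index: int, offset_mm: float) -> SliceAddress:
    """Nearest slice to ``reference_index`` + ``offset_mm`` along the axis.

    Mirrors the NEMA convention of measuring on the sphere-center plane and
    planes a fixed physical distance away (e.g. +/-10 and +/-20 mm).
    """
    if not 0 <= reference_index < volume.n_slices:
        raise VolumeError(f"reference index {reference_index} outside volume")
    exact = reference_index + offset_mm / volume.slice_spacing
    idx = int(round(exact))
    if not 0 <= idx < volume.n_slices:
        raise VolumeError(
            f"offset {offset_mm} mm from slice {reference_index} falls outside "
            f"the volume (would be index {idx} of {volume.n_slices})"
        )
    actual = (idx - reference_index) * volume.slice_spacing
    return SliceAddress(idx, actual, residual_mm=offset_mm - actual)


# ---------------------------------------------------------------------------
# Portable array container
# ---------------------------------------------------------------------------

def _write_portable(volume: Volume, path: Path) -> None:
    meta = {
        "pixel_spacing": volume.pixel_spacing,
        "slice_spacing": volume.slice_spacing,
        "origin": list(volume.origin),
        "frame_of_reference": volume.frame_of_reference,
        "units": "kBq/ml",
    }
    np.savez(path, voxels=volume.voxels, meta=np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8))


def _read_portable(path: Path) -> Volume:
    with np.load(path) as data:
        voxels = data["voxels"]
        meta = json.loads(bytes(data["meta"].tobytes()).decode("utf-8"))
    return Volume(
        voxels=voxels,
        pixel_spacing=float(meta["pixel_spacing"]),
        slice_spacing=float(meta["slice_spacing"]),
        origin=tuple(meta["origin"]),
        frame_of_reference=str(meta.get("frame_of_reference", "")),
    )


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def write_volume(volume: Volume, path: str | Path, format: str = "portable-array") -> Path:
    """Write ``volume`` to ``path``.

    ``portable-array`` (default) is a lossless ``.npz`` container; ``dicom-series``
    writes one PET-image file per slice into the directory ``path``, storing the
    rescale slope/intercept so that :func:`read_dicom_series` inverts the write
    to within one rescale quantum.
    """
    volume.validate()
    path = Path(path)
    if format == "portable-array":
        if not str(path).endswith(".npz"):
            path = path.with_suffix(".npz")
        _write_portable(volume, path)
        return path
    if format != "dicom-series":
        raise VolumeError(f"unknown format {format!r}")

    path.mkdir(parents=True, exist_ok=True)
    vmin = float(volume.voxels.min())
    vmax = float(volume.voxels.max())
    slope = (vmax - vmin) / 65530.0 if vmax > vmin else 1.0
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    raw = np.round((volume.voxels - vmin) / slope).astype(np.uint16)
    for i in range(volume.n_slices):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = PET_IMAGE_STORAGE
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = PET_IMAGE_STORAGE
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "PT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = i + 1
        ds.Units = "BQML"
        ds.Rows, ds.Columns = volume.voxels.shape[1:]
        ds.PixelSpacing = [volume.pixel_spacing, volume.pixel_spacing]
        ds.SliceThickness = volume.slice_spacing
        z = volume.origin[0] + i * volume.slice_spacing
        ds.ImagePositionPatient = [volume.origin[2], volume.origin[1], z]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = slope
        ds.RescaleIntercept = vmin
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = raw[i].tobytes()
        ds.save_as(path / f"slice_{i:04d}.dcm", enforce_file_format=True)
    return path


def read_dicom_series(directory_path: str | Path) -> Volume:
    """Read one PET DICOM series from a directory into a :class:`Volume`.

    Voxel values are converted to activity concentration via the stored
    rescale slope/intercept (an explicit error is raised if those are absent:
    raw detector counts are never returned silently).  Slices are sorted by
    physical position regardless of on-disk order; a directory containing
    more than one series is rejected, naming the series found.
    """
    directory_path = Path(directory_path)
    files = sorted(p for p in directory_path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise VolumeError(f"no DICOM files in {directory_path}")
    datasets = [pydicom.dcmread(f) for f in files]

    series = sorted({str(ds.SeriesInstanceUID) for ds in datasets})
    if len(series) > 1:
        raise VolumeError(
            "directory contains multiple DICOM series: " + ", ".join(series)
        )

    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise VolumeError(
                "unscaled input: rescale slope/intercept missing from "
                f"{ds.SOPInstanceUID}; cannot convert to activity concentration"
            )

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    ps = [float(v) for v in datasets[0].PixelSpacing]
    if not math.isclose(ps[0], ps[1], rel_tol=1e-6):
        raise VolumeError(
            f"anisotropic in-plane spacing {ps} not supported; resample upstream"
        )
    for ds in datasets[1:]:
        other = [float(v) for v in ds.PixelSpacing]
        if not (math.isclose(other[0], ps[0], rel_tol=1e-6)
                and math.isclose(other[1], ps[1], rel_tol=1e-6)):
            raise VolumeError("inconsistent pixel spacing across slices")

    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise VolumeError("duplicate or non-monotone slice positions after sort")
        if not np.allclose(dz, dz[0], atol=1e-3):
            raise VolumeError("non-uniform slice spacing")
        slice_spacing = float(dz[0])
    else:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 1.0))

    planes = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        planes.append(arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept))
    first = datasets[0]
    origin = (
        float(first.ImagePositionPatient[2]),
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[0]),
    )
    return Volume(
        voxels=np.stack(planes),
        pixel_spacing=ps[0],
        slice_spacing=slice_spacing,
        origin=origin,
        frame_of_reference=str(getattr(first, "FrameOfReferenceUID", "")),
    )


def read_volume(path: str | Path) -> Volume:
    """Read either a portable-array file or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    return _read_portable(path)
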