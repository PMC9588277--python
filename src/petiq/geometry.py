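"""NEMA IQ body-phantom geometry.

The NU-2 image-quality phantom body cross-section is modeled analytically as
the standard torso shape: a 147-mm-radius half disc on top (y >= 0), a
140 x 77 mm rectangle below, and two 77-mm-radius quarter discs rounding the
bottom corners.  Six fillable spheres (inner diameters 10-37 mm) sit on a
ring of radius 57.2 mm around a 50-mm cold cylindrical lung insert; all of
these default values follow the NU-2 standard and every one is configurable.

The twelve background-ROI template positions shipped here satisfy the NU-2
placement rules for the default sphere layout: ROI edge >= 15 mm from the
phantom boundary, no overlap with any sphere or the lung insert, and no
overlap between neighbouring 37-mm ROIs.  They are expressed in the phantom
frame (mm, phantom center at the origin) and are editable per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

__all__ = ["NemaGeometry", "DEFAULT_GEOMETRY"]

_BODY_TOP_RADIUS = 147.0
_BODY_HALF_WIDTH = 70.0
_BODY_CORNER_RADIUS = 77.0

# 12 background ROI centers (x, y) mm in the phantom frame: eight on an arc of
# radius 103 mm in the upper half, four in the lower corners.
_BACKGROUND_TEMPLATE = (
    (100.7, 21.4),
    (85.1, 58.1),
    (56.7, 86.0),
    (19.8, 101.1),
    (-19.8, 101.1),
    (-56.7, 86.0),
    (-85.1, 58.1),
    (-100.7, 21.4),
    (68.0, -40.0),
    (-68.0, -40.0),
    (104.0, -24.0),
    (-104.0, -24.0),
)


@dataclass(frozen=True)
class NemaGeometry:
    """Physical layout of the NEMA IQ phantom (mm)."""

    sphere_diameters: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    sphere_angles_deg: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)
    ring_radius: float = 57.2
    lung_insert_diameter: float = 50.0
    background_centers: tuple[tuple[float, float], ...] = _BACKGROUND_TEMPLATE
    edge_margin: float = 15.0  # min distance ROI edge -> phantom boundary

    def __post_init__(self) -> None:
        if len(self.sphere_diameters) != len(self.sphere_angles_deg):
            raise GeometryError("one angle required per sphere diameter")
        if list(self.sphere_diameters) != sorted(self.sphere_diameters):
            raise GeometryError("sphere diameters must be sorted ascending")

    # -- body shape -------------------------------------------------------
    @staticmethod
    def body_contains(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask: points (x, y) in the phantom frame inside the body."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        top = (y >= 0) & (x * x + y * y <= _BODY_TOP_RADIUS**2)
        rect = (y < 0) & (np.abs(x) <= _BODY_HALF_WIDTH) & (y >= -_BODY_CORNER_RADIUS)
        corner = (y < 0) & (
            (np.abs(x) - _BODY_HALF_WIDTH) ** 2 + y * y <= _BODY_CORNER_RADIUS**2
        )
        return top | rect | corner

    @staticmethod
    def body_cross_section_area() -> float:
        """Closed-form interior cross-section area (mm^2)."""
        return (
            np.pi * _BODY_TOP_RADIUS**2 / 2.0
            + 2.0 * _BODY_HALF_WIDTH * _BODY_CORNER_RADIUS
            + np.pi * _BODY_CORNER_RADIUS**2 / 2.0
        )

    def sphere_centers_xy(self) -> np.ndarray:
        """(n_spheres, 2) array of sphere centers (x, y) in the phantom frame."""
        ang = np.deg2rad(np.asarray(self.sphere_angles_deg, dtype=float))
        return np.column_stack([self.ring_radius * np.cos(ang),
                                self.ring_radius * np.sin(ang)])


DEFAULT_GEOMETRY = NemaGeometry()
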