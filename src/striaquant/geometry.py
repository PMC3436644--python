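"""Section geometry and soma point sets.

All coordinates are micrometres (μm) in the plane of a histological
section; ``thickness_um`` is the extent along the cutting axis and
``sampling_interval`` records systematic sampling (every k-th section),
both of which the stereology module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon


class GeometryError(ValueError):
    """Raised for degenerate or invalid section geometry."""


@dataclass(frozen=True)
class SectionGeometry:
    """Spatial frame of one section: boundary polygon plus cutting metadata.

    Parameters
    ----------
    boundary
        Simple (non-self-intersecting) polygon in μm, as a shapely
        ``Polygon`` or a sequence of (x, y) vertices.
    thickness_um
        Section thickness T along the cutting axis (default 50 μm).
    sampling_interval
        Every k-th section was kept in the systematic series (default 5),
        so the period between sampled section planes is
        ``thickness_um * sampling_interval``.
    section_index
        Position of this section in the sampled series.
    """

    boundary: Polygon
    thickness_um: float = 50.0
    sampling_interval: int = 5
    section_index: int = 0

    def __post_init__(self) -> None:
        poly = self.boundary
        if not isinstance(poly, Polygon):
            poly = Polygon(poly)
            object.__setattr__(self, "boundary", poly)
        if not poly.is_valid or poly.is_empty:
            raise GeometryError("section boundary must be a simple polygon")
        if poly.area <= 0:
            raise GeometryError("section boundary has zero area")
        if self.thickness_um <= 0:
            raise GeometryError("thickness_um must be > 0")
        if self.sampling_interval < 1:
            raise GeometryError("sampling_interval must be >= 1")

    @property
    def area_um2(self) -> float:
        return float(self.boundary.area)

    @classmethod
    def rectangle(
        cls,
        width_um: float,
        height_um: float,
        *,
        thickness_um: float = 50.0,
        sampling_interval: int = 5,
        section_index: int = 0,
    ) -> "SectionGeometry":
        """Axis-aligned rectangular section with one corner at the origin."""
        return cls(
            Polygon([(0, 0), (width_um, 0), (width_um, height_um), (0, height_um)]),
            thickness_um=thickness_um,
            sampling_interval=sampling_interval,
            section_index=section_index,
        )


@dataclass(frozen=True)
class SomaPointSet:
    """Labeled soma positions charted within one section.

    ``points`` is an (n, 2) float array of (x, y) in μm. Duplicate
    coordinates are rejected: two somata cannot occupy the same point and
    a duplicate would break the Voronoi tessellation downstream.
    """

    points: np.ndarray
    group_label: str = ""
    case_label: str = ""
    section_index: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("soma coordinates must be finite")
        if len(pts) != len(np.unique(pts, axis=0)):
            raise ValueError("duplicate soma coordinates")

    def __len__(self) -> int:
        return len(self.points)

    def validate_inside(self, geometry: SectionGeometry) -> None:
        """Check that every soma lies strictly inside the section boundary."""
        if len(self.points) == 0:
            return
        inside = shapely.contains_xy(
            geometry.boundary, self.points[:, 0], self.points[:, 1]
        )
        if not np.all(inside):
            n_out = int(np.sum(~inside))
            raise ValueError(f"{n_out} soma position(s) outside the section boundary")
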