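"""Pen geometry: arena boundary, feeder zone, optional anchor positions.

All coordinates are pen-local metres. The default geometry is a 6 m x 10 m
straw-bedded group pen with a 1.5 m x 3 m feeder zone in one corner, the
layout used throughout the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box


@dataclass(frozen=True)
class PenGeometry:
    """Arena geometry for a group pen.

    Parameters
    ----------
    boundary : shapely.Polygon
        Outer pen boundary (metres). Must have positive area.
    feeder_zone : shapely.Polygon
        Zone around the automatic milk feeder; must lie inside the boundary.
    anchors : list of (x, y), optional
        Positions of the UWB anchors; informational only.
    """

    boundary: Polygon
    feeder_zone: Polygon
    anchors: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.boundary.area <= 0:
            raise ValueError("pen boundary must enclose a positive area")
        if not self.boundary.covers(self.feeder_zone):
            raise ValueError("feeder zone must lie inside the pen boundary")

    @classmethod
    def default(cls) -> "PenGeometry":
        """6 m x 10 m pen, feeder zone a 1.5 m x 3 m rectangle in a corner."""
        return cls(boundary=box(0.0, 0.0, 6.0, 10.0),
                   feeder_zone=box(0.0, 0.0, 1.5, 3.0))

    @property
    def area(self) -> float:
        return float(self.boundary.area)

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership test for the pen (vectorised)."""
        return shapely.intersects_xy(self.boundary, np.asarray(x, float),
                                     np.asarray(y, float))

    def in_feeder(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership test for the feeder zone."""
        return shapely.intersects_xy(self.feeder_zone, np.asarray(x, float),
                                     np.asarray(y, float))

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the boundary."""
        return self.boundary.bounds

    def to_dict(self) -> dict:
        return {
            "boundary": list(self.boundary.exterior.coords),
            "feeder_zone": list(self.feeder_zone.exterior.coords),
            "anchors": [list(a) for a in self.anchors],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PenGeometry":
        return cls(
            boundary=Polygon(d["boundary"]),
            feeder_zone=Polygon(d["feeder_zone"]),
            anchors=tuple(tuple(a) for a in d.get("anchors", [])),
        )
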