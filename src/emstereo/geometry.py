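"""Planar geometric primitives shared by the sampling, counting and
morphometry modules.

All coordinates are physical micrometres in a right-handed frame
(x right, y up).  Annotation readers convert pixel coordinates to μm
exactly once, so everything downstream is unit-consistent.

Point-in-polygon uses the classical even-odd ray-crossing rule (a
horizontal ray cast to +x), with the half-open edge convention: a point
exactly on a bottom/left edge is inside, on a top/right edge outside.
This makes boundary classification deterministic and tie-free, which is
what a seed grid filtered against an ROI outline needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString as _ShLineString
from shapely.geometry import Polygon as _ShPolygon

__all__ = [
    "Point2D",
    "Polygon2D",
    "Polyline2D",
    "RigidTransform2D",
    "GeometryError",
    "point_in_polygon",
    "points_in_polygon",
    "polygon_area",
    "polyline_length",
    "intersects",
    "resample_polyline",
    "point_polyline_distance",
]

#: degenerate-area floor for polygon validation, μm²
_AREA_TOL = 1e-12


class GeometryError(ValueError):
    """Raised when a geometric object violates its construction invariants."""


@dataclass(frozen=True)
class Point2D:
    """A point in physical μm coordinates."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def _as_coords(points, min_points: int, what: str) -> np.ndarray:
    a = np.asarray(points, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise GeometryError(f"{what}: expected an (n, 2) coordinate array")
    if a.shape[0] < min_points:
        raise GeometryError(f"{what}: needs at least {min_points} points, got {a.shape[0]}")
    if not np.isfinite(a).all():
        raise GeometryError(f"{what}: non-finite coordinates")
    return a


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class Polygon2D:
    """A simple (non-self-intersecting) polygon, implicitly closed.

    Validated on construction: ≥3 distinct vertices, simplicity (via GEOS
    robust predicates) and nonzero signed area.  Vertex order may be CW or
    CCW; area is unsigned.
    """

    __slots__ = ("_v", "_sh")

    def __init__(self, vertices) -> None:
        v = _as_coords(vertices, 3, "Polygon2D")
        # drop an explicit closing vertex if present
        if v.shape[0] > 3 and np.array_equal(v[0], v[-1]):
            v = v[:-1]
        if np.any(np.all(v == np.roll(v, -1, axis=0), axis=1)):
            raise GeometryError("Polygon2D: consecutive vertices must be distinct")
        if abs(_shoelace(v)) <= _AREA_TOL:
            raise GeometryError("Polygon2D: degenerate (zero signed area)")
        sh = _ShPolygon(v)
        if not sh.is_valid:
            raise GeometryError("Polygon2D: self-intersecting or otherwise invalid outline")
        v.flags.writeable = False
        self._v = v
        self._sh = sh

    @property
    def vertices(self) -> np.ndarray:
        """Vertex array of shape (n, 2), read-only, closing vertex omitted."""
        return self._v

    @property
    def area(self) -> float:
        return abs(_shoelace(self._v))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            float(self._v[:, 0].min()),
            float(self._v[:, 1].min()),
            float(self._v[:, 0].max()),
            float(self._v[:, 1].max()),
        )

    def shapely(self) -> _ShPolygon:
        return self._sh

    def contains(self, point) -> bool:
        return point_in_polygon(point, self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Polygon2D({self._v.shape[0]} vertices, area={self.area:.4g} μm²)"


class Polyline2D:
    """An open polyline (membrane trace, central line) in μm."""

    __slots__ = ("_p",)

    def __init__(self, points) -> None:
        p = _as_coords(points, 2, "Polyline2D")
        if polyline_length_of(p) <= 0.0:
            raise GeometryError("Polyline2D: total length must be positive")
        p.flags.writeable = False
        self._p = p

    @property
    def points(self) -> np.ndarray:
        return self._p

    @property
    def length(self) -> float:
        return polyline_length_of(self._p)

    def reversed(self) -> "Polyline2D":
        return Polyline2D(self._p[::-1].copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Polyline2D({self._p.shape[0]} points, length={self.length:.4g} μm)"


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation by ``angle`` (radians, CCW) followed by a translation.

    Distance preserving by construction (the linear part is a pure
    rotation, determinant +1).
    """

    angle: float = 0.0
    dx: float = 0.0
    dy: float = 0.0

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, 0.0, 0.0)

    def apply(self, coords) -> np.ndarray:
        a = np.asarray(coords, dtype=float)
        single = a.ndim == 1
        a = np.atleast_2d(a)
        c, s = math.cos(self.angle), math.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        out = a @ rot.T + np.array([self.dx, self.dy])
        return out[0] if single else out

    def inverse(self) -> "RigidTransform2D":
        c, s = math.cos(self.angle), math.sin(self.angle)
        # R^-1 · (-t)
        return RigidTransform2D(-self.angle, -(c * self.dx + s * self.dy), -(-s * self.dx + c * self.dy))


# ---------------------------------------------------------------------------
# free functions


def points_in_polygon(points, poly: Polygon2D) -> np.ndarray:
    """Vectorised even-odd ray-crossing containment test.

    Casts a horizontal ray towards +x from each point and counts edge
    crossings under the half-open convention ``(y1 > y) != (y2 > y)``;
    an odd count means inside.  Points on bottom/left edges classify as
    inside, on top/right edges as outside.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    v = poly.vertices
    x = pts[:, 0][:, None]
    y = pts[:, 1][:, None]
    x1 = v[:, 0][None, :]
    y1 = v[:, 1][None, :]
    x2 = np.roll(v[:, 0], -1)[None, :]
    y2 = np.roll(v[:, 1], -1)[None, :]
    straddles = (y1 > y) != (y2 > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_at_y = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
    crossings = straddles & (x < x_at_y)
    return (np.count_nonzero(crossings, axis=1) % 2).astype(bool)


def point_in_polygon(p, poly: Polygon2D) -> bool:
    """Ray-crossing containment for a single point (see points_in_polygon)."""
    if isinstance(p, Point2D):
        p = (p.x, p.y)
    return bool(points_in_polygon(np.asarray(p, dtype=float)[None, :], poly)[0])


def polygon_area(poly: Polygon2D) -> float:
    """Unsigned shoelace area in μm²."""
    return poly.area


def polyline_length_of(points: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


def polyline_length(line: Polyline2D) -> float:
    """Total Euclidean length in μm."""
    return line.length


def intersects(obj, segment) -> bool:
    """True iff ``segment`` crosses or touches the boundary of ``obj``.

    ``obj`` may be a Polygon2D (its boundary is tested) or a Polyline2D;
    ``segment`` is a pair of endpoints.
    """
    seg = _ShLineString(np.asarray(segment, dtype=float))
    if isinstance(obj, Polygon2D):
        return bool(obj.shapely().boundary.intersects(seg))
    if isinstance(obj, Polyline2D):
        return bool(_ShLineString(obj.points).intersects(seg))
    raise TypeError(f"unsupported geometry {type(obj).__name__}")


def resample_polyline(line: Polyline2D, n_samples: int) -> np.ndarray:
    """Resample a polyline at ``n_samples`` points equally spaced in arc length.

    Returns an (n_samples, 2) array; endpoints are preserved.
    """
    if n_samples < 2:
        raise GeometryError("resample_polyline: need at least 2 samples")
    p = line.points
    seg = np.hypot(*np.diff(p, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n_samples)
    return np.column_stack([np.interp(t, s, p[:, 0]), np.interp(t, s, p[:, 1])])


def point_polyline_distance(p, line: Polyline2D) -> float:
    """Euclidean distance from a point to the nearest point of a polyline."""
    if isinstance(p, Point2D):
        p = (p.x, p.y)
    q = np.asarray(p, dtype=float)
    a = line.points[:-1]
    b = line.points[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0.0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", q - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.hypot(*(proj - q).T)))
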