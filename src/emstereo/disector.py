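"""Physical-disector counting with an unbiased counting frame.

The unit of counting is a pair of registered serial sections: candidate
particle transects (synapse or dense-core-vesicle profiles) are
enumerated on the *reference* section and checked against the *lookup*
section.  A transect contributes to Q⁻ iff

  (a) its footprint intersects the closed counting-frame square,
  (b) it does not cross the frame's top or right border (the forbidden
      borders, in frame-local axes after rotation), and
  (c) it has no corresponding transect on the lookup section
      (i.e. the particle "ends" between the two sections).

Numerical density is then N_V = ΣQ⁻ / (n_frames · a² · h) with frame
side a and section thickness h.

The forbidden line is the frame's top border, its right border, and (by
default) the downward extension of the right border below the
bottom-right corner.  The extension closes the classical corner
loophole: a footprint that crosses the top line left of the frame and
the right line below it meets three tiles of a frame tiling but not the
diagonal one, and without the extension two tiles would both accept it.
With the extension, a plane tiling of abutting frames counts every
disjoint convex footprint exactly once — the defining property of an
unbiased counting frame, asserted exhaustively by the test suite.
``literal_borders=True`` restricts the forbidden line to the two border
segments alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Mapping

import numpy as np
import shapely
from shapely.geometry import LineString as _ShLineString
from shapely.geometry import Polygon as _ShPolygon
from shapely.geometry import box as _sh_box

from .geometry import GeometryError, Polygon2D, RigidTransform2D

__all__ = [
    "CircleFootprint",
    "ParticleTransect",
    "SectionAnnotation",
    "DisectorPair",
    "CountingFrame",
    "DisectorCount",
    "DensityEstimate",
    "FramePlacementError",
    "PARTICLE_TYPES",
    "place_frame",
    "match_transects",
    "count_frame",
    "numerical_density",
]

PARTICLE_TYPES = ("synapse", "dcv")

# classification labels for reference transects
COUNTED = "counted"
EXCLUDED_FORBIDDEN = "excluded_forbidden"
PRESENT_IN_LOOKUP = "present_in_lookup"
OUTSIDE = "outside"


class FramePlacementError(RuntimeError):
    """Raised when no admissible counting-frame placement exists."""


@dataclass(frozen=True)
class CircleFootprint:
    """Circular transect footprint (e.g. a vesicle or sphere cross-section)."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise GeometryError("CircleFootprint: radius must be positive")

    @property
    def centroid(self) -> np.ndarray:
        return np.array([self.cx, self.cy])


class ParticleTransect:
    """One particle profile on one section."""

    __slots__ = ("id", "particle_type", "footprint")

    def __init__(self, id: str, particle_type: str, footprint) -> None:
        if particle_type not in PARTICLE_TYPES:
            raise ValueError(f"unknown particle_type {particle_type!r}")
        if not isinstance(footprint, (CircleFootprint, Polygon2D)):
            raise TypeError("footprint must be a CircleFootprint or Polygon2D")
        self.id = str(id)
        self.particle_type = particle_type
        self.footprint = footprint

    @property
    def centroid(self) -> np.ndarray:
        fp = self.footprint
        if isinstance(fp, CircleFootprint):
            return fp.centroid
        return fp.vertices.mean(axis=0)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ParticleTransect({self.id!r}, {self.particle_type})"


class SectionAnnotation:
    """All annotated transects of one section plus the imaged field extent."""

    __slots__ = ("section_id", "role", "transects", "field_bounds")

    def __init__(self, section_id: str, role: str, transects, field_bounds: Polygon2D) -> None:
        if role not in ("reference", "lookup"):
            raise ValueError(f"role must be 'reference' or 'lookup', got {role!r}")
        transects = list(transects)
        ids = [t.id for t in transects]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate transect ids in section {section_id!r}")
        sh_bounds = field_bounds.shapely()
        for t in transects:
            fp = t.footprint
            if isinstance(fp, CircleFootprint):
                ok = sh_bounds.distance(shapely.points(fp.cx, fp.cy)) <= fp.radius
            else:
                ok = sh_bounds.intersects(fp.shapely())
            if not ok:
                raise ValueError(
                    f"transect {t.id!r} lies entirely outside the field bounds "
                    f"of section {section_id!r}"
                )
        self.section_id = section_id
        self.role = role
        self.transects = transects
        self.field_bounds = field_bounds


@dataclass(frozen=True)
class DisectorPair:
    """A registered reference/lookup section pair — the counting unit.

    ``alignment`` maps lookup coordinates into the reference frame;
    ``thickness`` is the section (disector) height h in μm, 0.055 by
    default for 55 nm serial thin sections.
    """

    reference: SectionAnnotation
    lookup: SectionAnnotation
    alignment: RigidTransform2D = dataclass_field(default_factory=RigidTransform2D.identity)
    thickness: float = 0.055

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError("section thickness must be positive")
        if self.reference.role != "reference" or self.lookup.role != "lookup":
            raise ValueError("section roles do not match their slots")


class CountingFrame:
    """A square counting frame with forbidden top and right borders.

    The frame is a side_a × side_a square centred at ``center`` and
    rotated CCW by ``angle``; "top" and "right" refer to the frame-local
    axes after rotation.
    """

    __slots__ = ("center", "side_a", "angle")

    def __init__(self, center, side_a: float = 5.5, angle: float = 0.0) -> None:
        if not side_a > 0:
            raise ValueError("side_a must be positive")
        self.center = np.asarray(center, dtype=float)
        self.side_a = float(side_a)
        self.angle = float(angle)

    @property
    def corners(self) -> np.ndarray:
        """Frame corners in world coordinates, CCW from bottom-left."""
        a2 = self.side_a / 2.0
        local = np.array([[-a2, -a2], [a2, -a2], [a2, a2], [-a2, a2]])
        c, s = math.cos(self.angle), math.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        return local @ rot.T + self.center

    def to_local(self, coords) -> np.ndarray:
        """Map world coordinates into frame-local axes (frame centre at origin)."""
        a = np.atleast_2d(np.asarray(coords, dtype=float)) - self.center
        c, s = math.cos(-self.angle), math.sin(-self.angle)
        rot = np.array([[c, -s], [s, c]])
        return a @ rot.T


@dataclass(frozen=True)
class DisectorCount:
    """Counting result for one frame on one disector pair."""

    frame: CountingFrame
    q_minus: Mapping[str, int]
    classifications: Mapping[str, str]  # transect id -> label

    def __post_init__(self) -> None:
        # internal consistency between labels and tallies is asserted upstream
        total = sum(self.q_minus.values())
        n_counted = sum(1 for v in self.classifications.values() if v == COUNTED)
        if total != n_counted:
            raise ValueError("q_minus inconsistent with classification labels")


@dataclass(frozen=True)
class DensityEstimate:
    """Numerical density of one particle type pooled over frames."""

    particle_type: str
    n_v: float  # per μm³
    total_q: int
    n_frames: int
    mean_q_per_frame: float


def place_frame(
    field_bounds: Polygon2D,
    side_a: float = 5.5,
    rng: np.random.Generator | int | None = None,
    angle: float | None = None,
    max_attempts: int = 10_000,
) -> CountingFrame:
    """Place a counting frame uniformly at random inside the field.

    The angle is uniform on [0, π/2) (equivalent to [0, 2π) for a square
    probe on isotropic material) unless fixed via ``angle``.  The centre
    is drawn uniformly from the bounding box shrunk by the rotated
    frame's half-extent, then rejected unless all four corners lie
    inside (or on the boundary of) the field polygon — exact for
    rectangular fields, rejection handles concave ones.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    xmin, ymin, xmax, ymax = field_bounds.bounds
    sh_bounds = field_bounds.shapely()
    for _ in range(max_attempts):
        th = float(gen.uniform(0.0, math.pi / 2.0)) if angle is None else float(angle)
        half = (side_a / 2.0) * (abs(math.cos(th)) + abs(math.sin(th)))
        lo_x, hi_x = xmin + half, xmax - half
        lo_y, hi_y = ymin + half, ymax - half
        if lo_x > hi_x + 1e-12 or lo_y > hi_y + 1e-12:
            continue
        cx = float(gen.uniform(lo_x, max(hi_x, lo_x)))
        cy = float(gen.uniform(lo_y, max(hi_y, lo_y)))
        frame = CountingFrame((cx, cy), side_a, th)
        if shapely.covers(sh_bounds, shapely.points(frame.corners)).all():
            return frame
    raise FramePlacementError(
        f"no admissible placement of a {side_a} μm frame found in "
        f"{max_attempts} attempts (field bounds {field_bounds.bounds})"
    )


def match_transects(
    pair: DisectorPair,
    tolerance: float = 0.25,
    use_ids: bool = False,
) -> dict[str, str]:
    """Correspond reference and lookup transects of the same particle.

    Greedy nearest-centroid matching of same-type transects after mapping
    lookup coordinates through the pair alignment; candidate pairs beyond
    ``tolerance`` μm are never matched.  Deterministic: candidates are
    processed in order of (distance, reference id, lookup id).  With
    ``use_ids=True``, shared annotation ids are trusted instead.

    Returns a dict mapping reference transect id → lookup transect id.
    Unmatched reference transects are the countable events.
    """
    ref = pair.reference.transects
    lk = pair.lookup.transects
    if use_ids:
        lk_by_id = {t.id: t for t in lk}
        return {
            t.id: t.id
            for t in ref
            if t.id in lk_by_id and lk_by_id[t.id].particle_type == t.particle_type
        }
    if not ref or not lk:
        return {}
    lk_centroids = pair.alignment.apply(np.array([t.centroid for t in lk]))
    candidates = []
    for i, rt in enumerate(ref):
        rc = rt.centroid
        for j, lt in enumerate(lk):
            if lt.particle_type != rt.particle_type:
                continue
            d = math.hypot(rc[0] - lk_centroids[j][0], rc[1] - lk_centroids[j][1])
            if d <= tolerance:
                candidates.append((d, rt.id, lt.id, i, j))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    matched_ref: set[int] = set()
    matched_lk: set[int] = set()
    out: dict[str, str] = {}
    for d, rid, lid, i, j in candidates:
        if i in matched_ref or j in matched_lk:
            continue
        matched_ref.add(i)
        matched_lk.add(j)
        out[rid] = lid
    return out


def _circle_frame_relation(
    frame: CountingFrame, fp: CircleFootprint, literal_borders: bool
) -> tuple[bool, bool]:
    """(intersects closed frame square, touches the forbidden line)."""
    a2 = frame.side_a / 2.0
    x, y = frame.to_local([fp.cx, fp.cy])[0]
    r = fp.radius
    # distance to the filled square
    dx = max(abs(x) - a2, 0.0)
    dy = max(abs(y) - a2, 0.0)
    hits_frame = math.hypot(dx, dy) <= r
    # top border: segment y=+a2, x in [-a2, a2]
    d_top = math.hypot(max(abs(x) - a2, 0.0), y - a2)
    if literal_borders:
        # right border segment x=+a2, y in [-a2, a2]
        d_right = math.hypot(x - a2, max(abs(y) - a2, 0.0))
    else:
        # right border plus its downward extension: ray x=+a2, y <= a2
        d_right = math.hypot(x - a2, max(y - a2, 0.0))
    return hits_frame, min(d_top, d_right) <= r


def _polygon_frame_relation(
    frame: CountingFrame, fp: Polygon2D, literal_borders: bool
) -> tuple[bool, bool]:
    a2 = frame.side_a / 2.0
    local = frame.to_local(fp.vertices)
    poly = _ShPolygon(local)
    square = _sh_box(-a2, -a2, a2, a2)
    hits_frame = square.intersects(poly)
    top = _ShLineString([(-a2, a2), (a2, a2)])
    if literal_borders:
        right = _ShLineString([(a2, -a2), (a2, a2)])
    else:
        # extension reaches far enough below to act as an infinite ray
        reach = a2 + float(np.abs(local).max()) + 1.0
        right = _ShLineString([(a2, -reach), (a2, a2)])
    return hits_frame, poly.intersects(top) or poly.intersects(right)


def count_frame(
    pair: DisectorPair,
    frame: CountingFrame,
    matches: Mapping[str, str] | None = None,
    tolerance: float = 0.25,
    bidirectional: bool = False,
    literal_borders: bool = False,
) -> DisectorCount:
    """Apply the disector counting rule to one frame.

    Every reference transect receives exactly one label: ``outside``
    (footprint does not meet the closed frame), ``excluded_forbidden``
    (touches the forbidden line), ``present_in_lookup`` (particle
    continues onto the lookup section), or ``counted``.  ``q_minus``
    tallies counted transects per particle type.

    ``literal_borders=True`` drops the forbidden-line extension and
    tests only the top and right border segments.  ``bidirectional=True``
    additionally counts lookup transects absent from the reference
    section (doubling disector efficiency); off by default, matching the
    one-directional protocol.
    """
    if matches is None:
        matches = match_transects(pair, tolerance=tolerance)
    q: dict[str, int] = {t: 0 for t in PARTICLE_TYPES}
    labels: dict[str, str] = {}
    for t in pair.reference.transects:
        labels[t.id] = _classify(frame, t, t.id in matches, literal_borders)
        if labels[t.id] == COUNTED:
            q[t.particle_type] += 1
    if bidirectional:
        matched_lookup = set(matches.values())
        for t in pair.lookup.transects:
            lbl = _classify(frame, _aligned(t, pair.alignment), t.id in matched_lookup,
                            literal_borders)
            labels[f"lookup:{t.id}"] = lbl
            if lbl == COUNTED:
                q[t.particle_type] += 1
    return DisectorCount(frame=frame, q_minus=q, classifications=labels)


def _aligned(t: ParticleTransect, transform: RigidTransform2D) -> ParticleTransect:
    fp = t.footprint
    if isinstance(fp, CircleFootprint):
        c = transform.apply([fp.cx, fp.cy])
        return ParticleTransect(t.id, t.particle_type, CircleFootprint(c[0], c[1], fp.radius))
    return ParticleTransect(t.id, t.particle_type, Polygon2D(transform.apply(fp.vertices)))


def _classify(frame: CountingFrame, t: ParticleTransect, has_match: bool,
              literal_borders: bool = False) -> str:
    fp = t.footprint
    if isinstance(fp, CircleFootprint):
        hits, forbidden = _circle_frame_relation(frame, fp, literal_borders)
    else:
        hits, forbidden = _polygon_frame_relation(frame, fp, literal_borders)
    if not hits:
        return OUTSIDE
    if forbidden:
        return EXCLUDED_FORBIDDEN
    if has_match:
        return PRESENT_IN_LOOKUP
    return COUNTED


def numerical_density(
    counts: list[DisectorCount],
    side_a: float,
    h: float,
) -> dict[str, DensityEstimate]:
    """Convert frame counts to numerical densities N_V per particle type.

    N_V = ΣQ⁻ / (n_frames · side_a² · h), in particles per μm³.  The mean
    count per frame is reported alongside (the per-animal statistic used
    for group comparison).
    """
    if not counts:
        raise ValueError("numerical_density requires at least one counted frame")
    if not (side_a > 0 and h > 0):
        raise ValueError("side_a and h must be positive")
    n = len(counts)
    probe_volume = n * side_a * side_a * h
    types = sorted({pt for c in counts for pt in c.q_minus})
    out = {}
    for pt in types:
        total = sum(int(c.q_minus.get(pt, 0)) for c in counts)
        out[pt] = DensityEstimate(
            particle_type=pt,
            n_v=total / probe_volume,
            total_q=total,
            n_frames=n,
            mean_q_per_frame=total / n,
        )
    return out
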