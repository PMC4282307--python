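"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles, without
importing any emstereo geometry, so agreement with the package is a
genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# random polygon generators


def random_star_polygon(rng: np.random.Generator, n_vertices: int = 12,
                        scale: float = 10.0) -> np.ndarray:
    """A random simple polygon, star-shaped about its centre."""
    # well-separated angles (gaps bounded away from zero) keep the star
    # polygon robustly simple
    gaps = rng.uniform(0.5, 1.5, n_vertices)
    angles = 2.0 * math.pi * np.cumsum(gaps) / gaps.sum()
    radii = rng.uniform(0.2, 1.0, n_vertices) * scale
    center = rng.uniform(2.0, 8.0, 2)
    return center + np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


def random_convex_polygon(rng: np.random.Generator, n_points: int = 10,
                          scale: float = 10.0) -> np.ndarray:
    """Convex hull of random points (CCW order)."""
    from scipy.spatial import ConvexHull

    pts = rng.uniform(0.0, scale, (n_points, 2))
    hull = ConvexHull(pts)
    return pts[hull.vertices]


# ---------------------------------------------------------------------------
# point-in-polygon winding-number oracle


def winding_number_inside(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Inside-flags via the summed-subtended-angle winding number."""
    pts = np.atleast_2d(points)
    v1 = vertices[None, :, :] - pts[:, None, :]
    v2 = np.roll(vertices, -1, axis=0)[None, :, :] - pts[:, None, :]
    cross = v1[:, :, 0] * v2[:, :, 1] - v1[:, :, 1] * v2[:, :, 0]
    dot = np.einsum("pij,pij->pi", v1, v2)
    total = np.sum(np.arctan2(cross, dot), axis=1)
    return np.abs(total) > math.pi


def convex_halfplane_inside(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """For a convex CCW polygon: inside iff left of every edge."""
    pts = np.atleast_2d(points)
    a = vertices
    b = np.roll(vertices, -1, axis=0)
    edge = b - a
    rel = pts[:, None, :] - a[None, :, :]
    cross = edge[None, :, 0] * rel[:, :, 1] - edge[None, :, 1] * rel[:, :, 0]
    return np.all(cross > 0, axis=1)


# ---------------------------------------------------------------------------
# area / length oracles


def fan_triangle_area(vertices: np.ndarray) -> float:
    """Convex polygon area as a fan of triangles from vertex 0."""
    total = 0.0
    for i in range(1, len(vertices) - 1):
        a, b, c = vertices[0], vertices[i], vertices[i + 1]
        total += 0.5 * abs(
            (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
        )
    return total


def pairwise_length(points: np.ndarray) -> float:
    return float(sum(math.dist(points[i], points[i + 1]) for i in range(len(points) - 1)))


# ---------------------------------------------------------------------------
# segment intersection oracle


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    def on_seg(a, b, c):
        return (
            min(a[0], b[0]) - 1e-12 <= c[0] <= max(a[0], b[0]) + 1e-12
            and min(a[1], b[1]) - 1e-12 <= c[1] <= max(a[1], b[1]) + 1e-12
        )

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return True
    for d, a, b, c in ((d1, p3, p4, p1), (d2, p3, p4, p2), (d3, p1, p2, p3), (d4, p1, p2, p4)):
        if d == 0 and on_seg(a, b, c):
            return True
    return False


def boundary_segment_intersects(vertices: np.ndarray, seg: np.ndarray,
                                closed: bool) -> bool:
    """O(n) pairwise test of one segment against a polygon boundary or polyline."""
    n = len(vertices)
    last = n if closed else n - 1
    for i in range(last):
        a = vertices[i]
        b = vertices[(i + 1) % n]
        if _segments_intersect(a, b, seg[0], seg[1]):
            return True
    return False


# ---------------------------------------------------------------------------
# vesicle classification oracle (explicit BFS with its own distance code)


def _point_segment_distance(p, a, b) -> float:
    ax, ay = a
    bx, by = b
    px, py = p
    dx, dy = bx - ax, by - ay
    denom = dx * dx + dy * dy
    if denom == 0.0:
        return math.hypot(px - ax, py - ay)
    t = max(0.0, min(1.0, ((px - ax) * dx + (py - ay) * dy) / denom))
    return math.hypot(px - (ax + t * dx), py - (ay + t * dy))


def vesicle_partition_oracle(trace: np.ndarray, vesicles) -> tuple[set, set]:
    """(docked, undocked) index sets by explicit queue-based closure.

    ``vesicles`` is a list of (cx, cy, r).  Docked: centre within one own
    diameter (2r) of the trace.  Undocked: surface gap to any docked or
    undocked vesicle at most the candidate's own diameter, chained.
    """

    def trace_distance(p):
        return min(
            _point_segment_distance(p, trace[i], trace[i + 1])
            for i in range(len(trace) - 1)
        )

    docked = {
        i for i, (cx, cy, r) in enumerate(vesicles)
        if trace_distance((cx, cy)) <= 2.0 * r
    }
    undocked: set = set()
    queue = list(docked)
    while queue:
        i = queue.pop()
        ci = vesicles[i]
        for j, cj in enumerate(vesicles):
            if j in docked or j in undocked:
                continue
            gap = math.hypot(ci[0] - cj[0], ci[1] - cj[1]) - ci[2] - cj[2]
            if gap <= 2.0 * cj[2]:
                undocked.add(j)
                queue.append(j)
    return docked, undocked
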