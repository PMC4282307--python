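"""Single-section ultrastructural measurements per synapse profile.

Endpoints per synapse cross-section:

* presynaptic membrane length and PSD length — polyline arc lengths;
* mean synaptic-cleft width — cleft polygon area divided by the length
  of the central line, a mean-width estimator for a curved band;
* docked vesicles — small clear vesicles within one vesicle diameter of
  the presynaptic membrane;
* undocked (pool) vesicles — the transitive closure of vesicles within
  one vesicle diameter of a docked or another undocked vesicle.

When an annotation supplies the cleft polygon and central line they are
used as-is; otherwise both are derived from the membrane traces (the
polygon closes the two traces at their ends, the central line is the
pointwise midline of equal-arc-length resamplings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    GeometryError,
    Polygon2D,
    Polyline2D,
    point_polyline_distance,
    polygon_area,
    polyline_length,
    resample_polyline,
)

__all__ = [
    "VesicleCircle",
    "SynapseProfile",
    "SynapseMeasures",
    "MorphometryError",
    "membrane_lengths",
    "derive_central_line",
    "cleft_width",
    "classify_vesicles",
    "measure_profile",
    "animal_means",
]

_LENGTH_TOL = 1e-9  # μm; central lines shorter than this are degenerate


class MorphometryError(ValueError):
    """Raised for degenerate or missing morphometric inputs."""


@dataclass(frozen=True)
class VesicleCircle:
    """A small clear vesicle annotated as a circle (centre + radius, μm)."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise MorphometryError("vesicle radius must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx, self.cy])

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class SynapseProfile:
    """Annotations for one synapse cross-section on the reference section."""

    id: str
    pre_membrane: Polyline2D | None = None
    psd: Polyline2D | None = None
    cleft_polygon: Polygon2D | None = None
    central_line: Polyline2D | None = None
    vesicles: list[VesicleCircle] = field(default_factory=list)


@dataclass(frozen=True)
class SynapseMeasures:
    """Measured endpoints for one synapse; ``None`` marks an absent trace."""

    id: str
    pre_length: float | None
    psd_length: float | None
    cleft_width: float | None
    n_docked: int
    n_undocked: int


def membrane_lengths(profile: SynapseProfile) -> tuple[float | None, float | None]:
    """(presynaptic membrane length, PSD length); absent traces give None."""
    pre = polyline_length(profile.pre_membrane) if profile.pre_membrane else None
    psd = polyline_length(profile.psd) if profile.psd else None
    return pre, psd


def derive_central_line(pre: Polyline2D, post: Polyline2D, n_samples: int = 100) -> Polyline2D:
    """Midline between two membrane traces.

    Both traces are resampled at ``n_samples`` points equally spaced in
    arc length; the post trace is reversed if its endpoints pair better
    with the pre trace that way; the central line is the sequence of
    pointwise midpoints.
    """
    if pre.length <= _LENGTH_TOL or post.length <= _LENGTH_TOL:
        raise MorphometryError("cannot derive a central line from a degenerate trace")
    a = resample_polyline(pre, n_samples)
    b = resample_polyline(post, n_samples)
    direct = np.linalg.norm(a[0] - b[0]) + np.linalg.norm(a[-1] - b[-1])
    swapped = np.linalg.norm(a[0] - b[-1]) + np.linalg.norm(a[-1] - b[0])
    if swapped < direct:
        b = b[::-1]
    return Polyline2D((a + b) / 2.0)


def _derived_cleft(profile: SynapseProfile, n_samples: int) -> tuple[Polygon2D, Polyline2D]:
    if profile.pre_membrane is None or profile.psd is None:
        raise MorphometryError(
            f"profile {profile.id!r}: cleft polygon/central line absent and "
            "membrane traces unavailable to derive them"
        )
    a = resample_polyline(profile.pre_membrane, n_samples)
    b = resample_polyline(profile.psd, n_samples)
    direct = np.linalg.norm(a[0] - b[0]) + np.linalg.norm(a[-1] - b[-1])
    swapped = np.linalg.norm(a[0] - b[-1]) + np.linalg.norm(a[-1] - b[0])
    if swapped < direct:
        b = b[::-1]
    try:
        polygon = Polygon2D(np.vstack([a, b[::-1]]))
    except GeometryError as e:
        raise MorphometryError(
            f"profile {profile.id!r}: membrane traces do not close into a "
            f"simple cleft polygon ({e})"
        ) from e
    central = Polyline2D((a + b) / 2.0)
    return polygon, central


def cleft_width(profile: SynapseProfile, n_samples: int = 100) -> float:
    """Mean cleft width: cleft polygon area / central line length (μm).

    Uses explicitly annotated polygon and central line when both are
    present; otherwise derives them from the membrane traces.
    """
    if profile.cleft_polygon is not None and profile.central_line is not None:
        polygon, central = profile.cleft_polygon, profile.central_line
    else:
        polygon, central = _derived_cleft(profile, n_samples)
    length = polyline_length(central)
    if length <= _LENGTH_TOL:
        raise MorphometryError(f"profile {profile.id!r}: central line has zero length")
    return polygon_area(polygon) / length


def classify_vesicles(
    profile: SynapseProfile,
    membrane_metric: str = "center",
) -> tuple[set[int], set[int]]:
    """Partition vesicles into docked and undocked (pool) sets.

    Docked: distance to the presynaptic membrane at most one own
    diameter.  With ``membrane_metric='center'`` (default) the distance
    is centre-to-nearest-point-on-trace; ``'edge'`` subtracts the radius
    first.  Undocked: transitive closure — a vesicle joins the pool if
    its surface-to-surface gap to any docked or already-undocked vesicle
    is at most its own diameter; iterated to a fixed point (the closure
    is monotone, so the partition is order independent).  Returns
    (docked indices, undocked indices); leftovers are unclassified.
    """
    if profile.pre_membrane is None:
        raise MorphometryError(f"profile {profile.id!r}: presynaptic trace required")
    if membrane_metric not in ("center", "edge"):
        raise ValueError("membrane_metric must be 'center' or 'edge'")
    ves = profile.vesicles
    n = len(ves)
    if n == 0:
        return set(), set()
    docked: set[int] = set()
    for i, v in enumerate(ves):
        d = point_polyline_distance(v.center, profile.pre_membrane)
        if membrane_metric == "edge":
            d -= v.radius
        if d <= v.diameter:
            docked.add(i)
    centers = np.array([v.center for v in ves])
    radii = np.array([v.radius for v in ves])
    gaps = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    gaps -= radii[:, None] + radii[None, :]
    undocked: set[int] = set()
    frontier = set(docked)
    while frontier:
        reachable = {
            j
            for j in range(n)
            if j not in docked and j not in undocked
            and any(gaps[i, j] <= ves[j].diameter for i in frontier)
        }
        undocked |= reachable
        frontier = reachable
    return docked, undocked


def measure_profile(profile: SynapseProfile, n_samples: int = 100) -> SynapseMeasures:
    """All endpoints for one synapse; absent traces yield None, not zero."""
    pre, psd = membrane_lengths(profile)
    width: float | None
    try:
        width = cleft_width(profile, n_samples=n_samples)
    except MorphometryError:
        width = None
    if profile.pre_membrane is not None:
        docked, undocked = classify_vesicles(profile)
    else:
        docked, undocked = set(), set()
    return SynapseMeasures(
        id=profile.id,
        pre_length=pre,
        psd_length=psd,
        cleft_width=width,
        n_docked=len(docked),
        n_undocked=len(undocked),
    )


def animal_means(measures: list[SynapseMeasures]) -> dict[str, float]:
    """Per-animal arithmetic means over synapses.

    Fields absent on a synapse are skipped for that field's mean.  The
    number of contributing synapses is reported as ``n_synapses``.
    """
    if not measures:
        raise MorphometryError("animal_means: no synapse measurements supplied")
    out: dict[str, float] = {"n_synapses": float(len(measures))}
    for name in ("pre_length", "psd_length", "cleft_width", "n_docked", "n_undocked"):
        vals = [getattr(m, name) for m in measures if getattr(m, name) is not None]
        if vals:
            out[name] = float(np.mean(vals))
    return out
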