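"""Systematic uniform random sampling (SURS) of imaging positions.

A regular grid of candidate seeds is anchored at the lower-left corner of
the ROI bounding box and shifted by a random offset drawn uniformly from
[0, spacing)²; grid nodes falling inside the ROI polygon (ray-crossing
test) become the stage positions.  Because the common offset is uniform,
every location in the ROI has identical inclusion probability — the
defining property of SURS — while the grid keeps the positions evenly
spread.

If fewer than ``min_seeds`` nodes land inside the ROI, the spacing is
shrunk geometrically and the draw repeated with a fresh offset until the
floor is met; the spacing actually used is recorded in the plan.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import Point2D, Polygon2D, points_in_polygon

__all__ = ["SeedGrid", "SamplingPlan", "SamplingError", "generate_seeds",
           "export_stage_plan", "read_stage_plan"]

_MAX_ITER = 20


class SamplingError(RuntimeError):
    """Raised when no admissible sampling plan can be produced."""


@dataclass(frozen=True)
class SeedGrid:
    """A regular grid: ``origin + offset + (i·spacing, j·spacing)``.

    ``origin`` is the ROI bounding-box lower-left corner; only ``offset``
    carries randomness, so the estimator is translation invariant.
    """

    spacing: float
    offset: Point2D
    origin: Point2D

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise SamplingError("SeedGrid: spacing must be positive")
        if not (0 <= self.offset.x < self.spacing and 0 <= self.offset.y < self.spacing):
            raise SamplingError("SeedGrid: offset must lie in [0, spacing) on both axes")

    def nodes(self, width: float, height: float) -> np.ndarray:
        """All grid nodes covering a ``width × height`` bounding box."""
        nx = int(math.floor((width - self.offset.x) / self.spacing)) + 1
        ny = int(math.floor((height - self.offset.y) / self.spacing)) + 1
        if nx <= 0 or ny <= 0:
            return np.empty((0, 2))
        xs = self.origin.x + self.offset.x + self.spacing * np.arange(nx)
        ys = self.origin.y + self.offset.y + self.spacing * np.arange(ny)
        gx, gy = np.meshgrid(xs, ys, indexing="xy")
        # row-major order: bottom row first, left to right
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class SamplingPlan:
    """Seeds for stage positions inside an ROI, with RNG provenance."""

    roi: Polygon2D
    seeds: np.ndarray  # (n, 2) μm, row-major grid order
    rng_seed: int | None
    spacing_used: float
    min_seeds: int = 20
    offset: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        if len(self.seeds) < self.min_seeds:
            raise SamplingError(
                f"plan holds {len(self.seeds)} seeds, below the floor of {self.min_seeds}"
            )

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)


def generate_seeds(
    roi: Polygon2D,
    spacing: float,
    min_seeds: int = 20,
    rng: np.random.Generator | int | None = None,
    min_spacing: float | None = None,
) -> SamplingPlan:
    """Draw a systematic-uniform-random seed plan inside ``roi``.

    Parameters
    ----------
    roi : ROI outline polygon (μm).
    spacing : initial grid spacing in μm ("adjustable distance between
        the seeds"); shrunk automatically if fewer than ``min_seeds``
        nodes fall inside the ROI.
    min_seeds : minimum number of accepted seeds (default 20, matching
        the at-least-20-micrograph design).
    rng : integer seed or a ``numpy.random.Generator``.  The integer seed
        is recorded in the plan for provenance.
    min_spacing : optional hard floor on spacing; reaching it raises a
        ``SamplingError`` naming the achievable count.
    """
    if spacing <= 0:
        raise SamplingError("spacing must be positive")
    if min_seeds < 1:
        raise SamplingError("min_seeds must be at least 1")
    recorded_seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    xmin, ymin, xmax, ymax = roi.bounds
    origin = Point2D(xmin, ymin)
    width, height = xmax - xmin, ymax - ymin

    best = 0
    for _ in range(_MAX_ITER):
        off = gen.uniform(0.0, spacing, size=2)
        grid = SeedGrid(spacing, Point2D(float(off[0]), float(off[1])), origin)
        nodes = grid.nodes(width, height)
        inside = nodes[points_in_polygon(nodes, roi)] if len(nodes) else nodes
        n = len(inside)
        best = max(best, n)
        if n >= min_seeds:
            return SamplingPlan(
                roi=roi,
                seeds=inside,
                rng_seed=recorded_seed if recorded_seed is None else int(recorded_seed),
                spacing_used=spacing,
                min_seeds=min_seeds,
                offset=(float(off[0]), float(off[1])),
            )
        factor = min(max(math.sqrt(max(1, n) / min_seeds), 0.7), 0.95)
        spacing *= factor
        if min_spacing is not None and spacing < min_spacing:
            raise SamplingError(
                f"ROI too small: only {best} seeds achievable before reaching "
                f"the minimum spacing of {min_spacing} μm (requested {min_seeds})"
            )
    raise SamplingError(
        f"could not reach {min_seeds} seeds in {_MAX_ITER} spacing adaptations "
        f"(best attempt: {best} seeds)"
    )


def export_stage_plan(plan: SamplingPlan, path) -> None:
    """Write the stage-shift plan: a CSV of seed positions plus a JSON sidecar.

    The CSV has columns ``seed_index,x_um,y_um`` (full float precision, so
    a round trip is bit-exact).  The sidecar ``<path>.json`` records the
    RNG seed, spacing, offset and ROI vertices.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["seed_index", "x_um", "y_um"])
        for i, (x, y) in enumerate(plan.seeds):
            w.writerow([i, repr(float(x)), repr(float(y))])
    sidecar = {
        "rng_seed": plan.rng_seed,
        "spacing_used": plan.spacing_used,
        "min_seeds": plan.min_seeds,
        "offset": list(plan.offset),
        "units": "um",
        "roi_vertices": [[float(x), float(y)] for x, y in plan.roi.vertices],
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1) + "\n"
    )


def read_stage_plan(path) -> SamplingPlan:
    """Re-read a plan written by :func:`export_stage_plan`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with path.open() as fh:
        rows = list(csv.DictReader(fh))
    seeds = np.array([[float(r["x_um"]), float(r["y_um"])] for r in rows])
    return SamplingPlan(
        roi=Polygon2D(meta["roi_vertices"]),
        seeds=seeds,
        rng_seed=meta["rng_seed"],
        spacing_used=meta["spacing_used"],
        min_seeds=meta["min_seeds"],
        offset=tuple(meta["offset"]),
    )
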