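# Methods

This note documents the models and estimators implemented in
`emstereo`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Coordinate conventions and geometry

All geometry lives in a planar, physical coordinate frame (x right,
y up, micrometres).  Annotation readers convert pixel coordinates to μm
exactly once (`units: "px"` plus `pixel_size_um`), so every downstream
computation is unit-consistent.

Point-in-polygon containment uses the even-odd ray-crossing rule with a
half-open edge convention: a horizontal ray is cast towards +x and an
edge is crossed when `(y1 > y) != (y2 > y)`.  Points exactly on
bottom/left edges classify as inside, on top/right edges as outside.
The convention matters only for measure-zero inputs (grid seeds landing
exactly on the ROI border) and was chosen because it is deterministic
and tie-free; the suite cross-checks it against an independent
winding-number implementation.  ROI and footprint polygons must be
simple; validity is delegated to GEOS robust predicates, with a
degenerate-area floor of 1e-12 μm².

## Systematic uniform random sampling

A regular grid of spacing *s* is anchored at the lower-left corner of
the ROI bounding box and translated by an offset drawn uniformly from
[0, s)².  Only the offset is random, which makes the inclusion
probability of every ROI location exactly uniform (the estimator is
translation invariant); the grid structure keeps positions evenly
spread.  Grid nodes inside the ROI polygon become stage positions.

If fewer than `min_seeds` (default 20) nodes fall inside, the spacing is
multiplied by `clip(sqrt(max(1, n)/min_seeds), 0.7, 0.95)` and the draw
repeated with a fresh offset, at most 20 times.  The square-root factor
targets the deficit directly (expected hits scale with 1/s²); the 0.7
floor limits overshoot per iteration and the 0.95 ceiling guarantees
progress when the count is just short.  An optional `min_spacing`
converts an impossible request into an explicit error naming the
achievable count.  The RNG seed, offset and spacing actually used are
recorded in the exported plan, so a plan is exactly reproducible.

Seeds whose field of view extends beyond the ROI border are kept: the
counting frame, not the camera field, is the probe, and rejecting
border seeds would reintroduce the edge bias that SUR sampling removes.

## Physical disector and the counting frame

The counting unit is a pair of registered serial sections a known
distance h apart (default 0.055 μm, i.e. 55 nm thin sections; the
nominal thickness is used as-is — no shrinkage or compression
correction).  A transect on the reference section contributes to Q⁻
iff:

* (a) its footprint intersects the closed counting-frame square
  ("present within the outer borders" — profiles only partially inside
  are eligible, since a profile larger than its visible transect cannot
  be required to lie wholly inside);
* (b) it does not touch the forbidden line;
* (c) it has no corresponding transect on the lookup section.

The frame (side 5.5 μm by default) is placed uniformly at random with a
uniform random rotation in [0, π/2) — for a square probe on isotropic
material this is equivalent to [0, 2π).  Placement draws the centre
from the field bounding box shrunk by the rotated frame's half-extent
and rejects until all corners are inside (or on) the field polygon, so
centres are uniform over the feasible region.

**Forbidden line.**  The forbidden line is the frame's top border, its
right border, and the downward extension of the right border below the
bottom-right corner.  The extension closes a corner loophole: a convex
footprint that crosses the top grid line left of a frame and the right
grid line below it meets three frames of a tiling but not the diagonal
one, and with border segments alone two frames would accept it.  With
the single extension, a plane tiling of abutting frames counts every
disjoint convex footprint exactly once — the defining property of an
unbiased counting frame — which the suite asserts exhaustively on
random scenes.  One extension suffices under eligibility rule (a); a
second (above the top-left corner) is redundant here.  The two-segment
variant without the extension is available via
`count_frame(literal_borders=True)`, together with a regression test
demonstrating its double-count on the corner configuration.

**Correspondence across sections.**  Reference and lookup transects are
corresponded by greedy nearest-centroid matching of same-type transects
after mapping lookup coordinates through the pair's rigid alignment,
with a distance cap (default 0.25 μm, about half a DCV diameter below
typical transect spacing).  Candidates are processed in order of
(distance, reference id, lookup id), so matching is deterministic; each
transect is matched at most once.  Annotations that share particle ids
across sections can opt into exact id matching (`use_ids=True`).
Matching failures are not errors — unmatched reference transects are
precisely the countable events.

Counting is one-directional (reference → lookup).  The
efficiency-doubling bidirectional disector is implemented behind
`bidirectional=True` but off by default.

**Density.**  N_V = ΣQ⁻ / (n · a² · h) per particle type, pooled over
frames; the mean count per frame is reported alongside, since the
per-animal mean count is the natural unit for group statistics.

## Morphometry

Measured per synapse cross-section on the reference section; no frame
restriction applies (the frame is a counting probe, not a measurement
window), and a missing trace yields an absent measurement, never a
zero.

* **Membrane lengths** — arc length of the presynaptic-membrane and PSD
  polylines.
* **Cleft width** — cleft-polygon area divided by central-line length,
  the exact mean width of a constant-separation band and a first-order
  estimator for curved or tapering clefts.  When the annotation
  supplies the polygon and central line they are used verbatim;
  otherwise both are derived: the two membrane traces are resampled at
  `n_samples` (default 100) points equally spaced in arc length, the
  postsynaptic trace is reversed if its endpoints pair better that way,
  the polygon closes the two traces at their ends and the central line
  is the pointwise midline.  At 100 samples the discretisation error
  for smooth bands is well under 0.5%.  A central line shorter than
  1e-9 μm is a hard error naming the profile.
* **Vesicle classification** — *docked*: distance from the vesicle to
  the presynaptic trace at most one own diameter (2r).  The distance is
  centre-to-nearest-trace-point by default; an edge-based variant
  (subtracting the radius) is available via `membrane_metric="edge"`.
  *Undocked (pool)*: transitive closure — a vesicle joins the pool if
  its surface-to-surface gap to any docked or already-pooled vesicle is
  at most its own diameter; iterated to the (unique, order-independent)
  fixed point.  "Own diameter" resolves the ambiguity of whose diameter
  sets the threshold; using the candidate's own diameter makes each
  vesicle's criterion self-referential and scale-free.  Vesicles
  reached by neither rule stay unclassified and are not part of the
  pool.
* **Per-animal means** — arithmetic means over synapses, with the
  contributing count reported; fields absent on a synapse are skipped
  for that field.

## Group statistics

The animal is the statistical unit.  Per endpoint, extreme values more
than 3 interquartile ranges above Q3 or below Q1 are excluded; quartiles
use linear interpolation between order statistics (the common
statistics-package default).  Fences are computed once over both groups
pooled — pooling means exclusion cannot by itself manufacture a group
difference — and applied in a single pass with no re-computation after
removal (`pooled_exclusion=False` switches to within-group fences).
With fewer than four values quartiles are not meaningful, so nothing is
excluded and a warning is emitted.

Groups are compared with Student's pooled-variance two-sample t-test,
two-sided, df = n₁+n₂−2, reported as means ± SEM per group.  The suite
verifies the test's type-I error at α = 0.05 over 10⁴ null simulations
at n = 5 per group.

## Synthetic ground truth

`simulate_field` draws a homogeneous Poisson point process of intensity
λ (per μm³) for sphere centres in a box, with i.i.d. radii from a
pluggable sampler.  The box is toroidal: when a field is sectioned,
spheres are considered together with their 26 axis-shifted copies, so
the density ground truth has no edge deficit — a convenience real
tissue does not offer, chosen so that λ is exactly the expected top
density.

`section_field` slices a field into a reference slab [z₀, z₀+h) and a
lookup slab [z₀+h, z₀+2h).  A sphere appears on a slab iff it
intersects it (strict inequalities, so a tangent sphere with a
zero-radius footprint never appears); its footprint is the largest
cross-section circle inside the slab, centred at the sphere's (x, y).
There is no minimum-footprint visibility threshold by default: tiny
caps are assumed annotated.  This idealises real EM, where caps smaller
than the membrane resolution are invisible — a small-cap visibility
bias the pipeline would inherit from real annotations but which the
simulator deliberately excludes from ground truth.

`synthesize_study` builds a complete two-group data set at the study's
design: two groups of 5 animals, 20 disector pairs per animal, 55 nm
sections, an 11 μm square imaged field, DCV radii uniform on
0.04–0.08 μm and synapse-proxy radii uniform on 0.10–0.25 μm (fixture
parameters at the right biological scale, not biological claims).
Synapse proxies are spheres, so their transects are discs; no
orientation distribution is modelled.  Default true DCV densities are
1.0 (SE) vs 0.6 (EE) per μm³ — a 40% deficit — with synapse density
0.35 per μm³ in both groups; true cleft widths 0.020 vs 0.024 μm.
Between-animal variability is multiplicative Gaussian with CV 0.10 on
densities (half that on widths), a typical animal-to-animal spread.

Synapse profiles for morphometry are curved bands: a presynaptic arc
with the postsynaptic trace offset along local normals by the true
cleft width, so the area/central-line estimator recovers the truth
exactly up to discretisation; tracing noise (σ = 0.002 μm, about the
precision of manual tracing) acts along the normals so traces never
backtrack.  Vesicles are placed as a few docked at the membrane plus a
chained pool behind them, on the side opposite the PSD.

What passing tests therefore show: the sampling, counting and
measurement chain is unbiased and correctly calibrated *given faithful
annotations*.  What they do not show: robustness to detection failures,
mis-matched transects from poor alignment, section-thickness error or
compression, or non-Poisson spatial clustering of particles — all
properties of real data the generator does not emulate.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 50 polygons ×
1000 points for the containment oracle; 5000 sampling plans for
uniformity (5×5 bins, χ² at α = 0.01); 100 tiling scenes (exact
equality); 500 frames per cell for disector unbiasedness at
λ ∈ {0.5, 1.0, 2.0} per μm³ with two radius distributions (within
3 SEM); 500 vesicle clouds against the closure oracle; 10⁴ null t-test
simulations; and 200 replicate studies for direction-of-effect recovery
(≥ 95%).  These sizes make each check's Monte-Carlo error small
relative to its tolerance while keeping a full run in the minutes
range on one CPU.

## Known limitations

* Annotations are trusted; there is no detection from pixels and no
  plausibility checking of traces beyond geometric validity.
* The density estimator uses nominal section thickness; any systematic
  thickness error scales N_V inversely.
* Geometric matching can in principle mis-pair transects in very dense
  scenes; the greedy distance-ordered scheme makes this rare (exact
  continuations match at distance ≈ 0 first), and id-based matching is
  available when annotations provide stable ids.
* The cleft-width estimator assumes the two traces span the same cleft
  extent; clefts annotated with mismatched trace lengths are averaged
  over the resampled correspondence, which can bias the width for
  strongly asymmetric traces.
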