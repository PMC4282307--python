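"""Synthetic ground truth: 3D Poisson sphere fields sliced into serial
sections, and whole two-group studies, for validating every pipeline
stage without real data.

Particles (dense-core vesicles and synapse proxies) are spheres whose
centres form a homogeneous Poisson point process of known intensity λ
(per μm³) in a box with toroidal boundary, so the density ground truth
has no edge deficit.  Slicing a field at section thickness h produces a
reference/lookup annotation pair: a sphere appears on a slab iff it
intersects it, and its footprint is the largest cross-section circle the
slab contains.  Under this construction a sphere's topmost point falls
in exactly one slab of a tiling — the basis of the disector
unbiasedness checks.

``synthesize_study`` builds a complete two-group data set (animals ×
disector pairs × synapse profiles) mirroring the study design: 5 animals
per group, at least 20 section pairs per animal, 55 nm sections, a
5.5 μm counting frame, and group effects expressed as a DCV density
deficit and a cleft-width shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable

import numpy as np

from .disector import (
    CircleFootprint,
    DisectorPair,
    ParticleTransect,
    SectionAnnotation,
)
from .geometry import Polygon2D, Polyline2D, RigidTransform2D
from .morphometry import SynapseProfile, VesicleCircle

__all__ = [
    "ParticleField3D",
    "StudyScenario",
    "StudyData",
    "simulate_field",
    "section_field",
    "synthesize_study",
    "uniform_radii",
    "fixed_radius",
]


def uniform_radii(lo: float, hi: float) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Radius sampler: i.i.d. uniform on [lo, hi] μm."""
    if not (0 < lo <= hi):
        raise ValueError("radius bounds must satisfy 0 < lo <= hi")

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(lo, hi, size=n)

    return sample


def fixed_radius(r: float) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Radius sampler: constant radius r μm."""
    if not r > 0:
        raise ValueError("radius must be positive")

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, r)

    return sample


@dataclass(frozen=True)
class ParticleField3D:
    """A simulated sphere field in a (Lx, Ly, Lz) μm box, toroidal boundary."""

    box: tuple[float, float, float]
    centers: np.ndarray  # (n, 3) μm
    radii: np.ndarray  # (n,) μm
    particle_type: str
    intensity_lambda: float
    rng_seed: int | None = None

    @property
    def n_particles(self) -> int:
        return len(self.radii)


def simulate_field(
    box: tuple[float, float, float],
    lam: float,
    radius_sampler: Callable[[np.random.Generator, int], np.ndarray],
    rng: np.random.Generator | int | None = None,
    particle_type: str = "dcv",
) -> ParticleField3D:
    """Homogeneous Poisson sphere field of intensity ``lam`` per μm³."""
    if any(s <= 0 for s in box):
        raise ValueError("box dimensions must be positive")
    if lam < 0:
        raise ValueError("intensity must be nonnegative")
    recorded = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    volume = box[0] * box[1] * box[2]
    n = int(gen.poisson(lam * volume))
    centers = gen.uniform(0.0, 1.0, size=(n, 3)) * np.asarray(box)
    radii = np.asarray(radius_sampler(gen, n), dtype=float)
    return ParticleField3D(
        box=tuple(float(s) for s in box),
        centers=centers,
        radii=radii,
        particle_type=particle_type,
        intensity_lambda=lam,
        rng_seed=None if recorded is None else int(recorded),
    )


def _slab_transects(
    fields: list[ParticleField3D],
    z_bot: float,
    z_top: float,
) -> list[tuple[str, str, float, float, float]]:
    """(id, type, cx, cy, r_visible) for every sphere copy meeting the slab.

    Toroidal wrap: each sphere is considered together with its 26
    axis-shifted copies; copies whose sphere misses the slab or whose
    footprint cannot reach the x/y box are discarded.
    """
    out = []
    for fi, f in enumerate(fields):
        if f.n_particles == 0:
            continue
        Lx, Ly, Lz = f.box
        c, r = f.centers, f.radii
        rmax = float(r.max())
        for sx, sy, sz in product((-Lx, 0.0, Lx), (-Ly, 0.0, Ly), (-Lz, 0.0, Lz)):
            cz = c[:, 2] + sz
            # strict inequalities: a tangent sphere has zero footprint
            hit = (cz - r < z_top) & (cz + r > z_bot)
            if sx or sy:
                cx = c[:, 0] + sx
                cy = c[:, 1] + sy
                hit &= (cx - r < Lx + rmax) & (cx + r > -rmax)
                hit &= (cy - r < Ly + rmax) & (cy + r > -rmax)
            if not hit.any():
                continue
            idx = np.nonzero(hit)[0]
            cz_h = cz[idx]
            dz = np.where(
                (cz_h >= z_bot) & (cz_h <= z_top),
                0.0,
                np.minimum(np.abs(cz_h - z_bot), np.abs(cz_h - z_top)),
            )
            r_vis = np.sqrt(np.maximum(r[idx] ** 2 - dz**2, 0.0))
            cx_h = c[idx, 0] + sx
            cy_h = c[idx, 1] + sy
            # footprint must reach the imaged field [0,Lx]x[0,Ly]:
            # Euclidean distance from the centre to the rectangle <= r_vis
            ddx = np.maximum(np.maximum(-cx_h, cx_h - Lx), 0.0)
            ddy = np.maximum(np.maximum(-cy_h, cy_h - Ly), 0.0)
            ok = (r_vis > 0) & (np.hypot(ddx, ddy) <= r_vis)
            if sx == 0 and sy == 0 and sz == 0:
                tag = ""
            else:  # wrap tag: one character per axis, m/0/p for -L/0/+L
                tag = "@" + "".join(
                    "m" if s < 0 else ("p" if s > 0 else "0") for s in (sx, sy, sz)
                )
            for k in np.nonzero(ok)[0]:
                j = idx[k]
                out.append(
                    (
                        f"f{fi}p{j}{tag}",
                        f.particle_type,
                        float(cx_h[k]),
                        float(cy_h[k]),
                        float(r_vis[k]),
                    )
                )
    return out


def section_field(
    fields: ParticleField3D | list[ParticleField3D],
    z0: float,
    h: float,
) -> DisectorPair:
    """Slice field(s) into a reference/lookup annotation pair.

    The reference slab is [z0, z0+h), the lookup slab [z0+h, z0+2h);
    alignment is the identity.  A sphere whose topmost point lies in the
    reference slab appears on the reference but not the lookup section —
    the countable event.
    """
    if isinstance(fields, ParticleField3D):
        fields = [fields]
    Lx, Ly, Lz = fields[0].box
    if any(f.box != fields[0].box for f in fields):
        raise ValueError("all fields must share the same box")
    if not (0 <= z0 and z0 + 2 * h <= Lz):
        raise ValueError(f"slab pair [{z0}, {z0 + 2 * h}] outside the box depth {Lz}")
    bounds = Polygon2D([[0, 0], [Lx, 0], [Lx, Ly], [0, Ly]])
    sections = []
    for role, zb, zt in (("reference", z0, z0 + h), ("lookup", z0 + h, z0 + 2 * h)):
        transects = [
            ParticleTransect(tid, ptype, CircleFootprint(cx, cy, r))
            for tid, ptype, cx, cy, r in _slab_transects(fields, zb, zt)
        ]
        sections.append(
            SectionAnnotation(f"{role}@z{z0:.4f}", role, transects, bounds)
        )
    return DisectorPair(
        reference=sections[0],
        lookup=sections[1],
        alignment=RigidTransform2D.identity(),
        thickness=h,
    )


# ---------------------------------------------------------------------------
# two-group study synthesis


@dataclass(frozen=True)
class StudyScenario:
    """Design of a synthetic two-group EM study.

    Defaults mirror the study conditions: two housing groups, 5 animals
    per group, ≥20 disector pairs per animal, 55 nm sections, and group
    effects of a 40% DCV-density deficit plus a wider synaptic cleft in
    the second group.  Densities are per μm³, lengths in μm.
    """

    groups: tuple[str, str] = ("SE", "EE")
    n_per_group: int = 5
    pairs_per_animal: int = 20
    dcv_density: dict[str, float] = field(
        default_factory=lambda: {"SE": 1.0, "EE": 0.6}
    )
    synapse_density: dict[str, float] = field(
        default_factory=lambda: {"SE": 0.35, "EE": 0.35}
    )
    cleft_width: dict[str, float] = field(
        default_factory=lambda: {"SE": 0.020, "EE": 0.024}
    )
    section_thickness: float = 0.055
    field_size: float = 11.0  # μm, side of the square imaged field
    field_depth: float = 0.6  # μm, simulated slab depth per pair
    dcv_radius: tuple[float, float] = (0.04, 0.08)
    synapse_radius: tuple[float, float] = (0.10, 0.25)
    synapses_per_animal: tuple[int, int] = (19, 29)
    trace_noise_sd: float = 0.002  # μm, vertex jitter on membrane traces
    animal_cv: float = 0.10  # between-animal coefficient of variation
    vesicle_radius: tuple[float, float] = (0.015, 0.025)

    def animal_ids(self) -> list[tuple[str, str]]:
        return [
            (f"{g}{i + 1:02d}", g)
            for g in self.groups
            for i in range(self.n_per_group)
        ]


@dataclass
class StudyData:
    """In-memory synthetic study: per-animal pairs, profiles and ground truth."""

    scenario: StudyScenario
    groups: dict[str, str]  # animal_id -> group label
    pairs: dict[str, list[DisectorPair]]
    profiles: dict[str, list[SynapseProfile]]
    truth: dict[str, dict[str, float]]  # animal_id -> true parameters


def _animal_value(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Between-animal variability: multiplicative Gaussian, floored at 10%."""
    return float(mean * max(1.0 + cv * rng.standard_normal(), 0.1))


def _make_profile(
    rng: np.random.Generator,
    pid: str,
    width: float,
    noise_sd: float,
    vesicle_radius: tuple[float, float],
    n_pts: int = 40,
) -> SynapseProfile:
    """One synapse cross-section: a curved band of constant normal width.

    The PSD trace is the presynaptic trace offset along local normals by
    the cleft width, so the area/central-line estimator recovers the
    width exactly up to discretisation; Gaussian vertex jitter models
    tracing noise.  Vesicles: a few docked at the membrane and a chained
    pool behind them.
    """
    L = rng.uniform(0.25, 0.40)
    amp = rng.uniform(0.0, 0.03)
    x = np.linspace(0.0, L, n_pts)
    y = amp * np.sin(math.pi * x / L)
    pre = np.column_stack([x, y])
    # unit normals of the pre trace
    tx = np.gradient(pre[:, 0])
    ty = np.gradient(pre[:, 1])
    norm = np.hypot(tx, ty)
    normals = np.column_stack([-ty / norm, tx / norm])
    psd = pre + width * normals
    if noise_sd > 0:
        # tracing jitter acts along the local normal so traces never backtrack
        pre = pre + normals * rng.normal(0.0, noise_sd, (n_pts, 1))
        psd = psd + normals * rng.normal(0.0, noise_sd, (n_pts, 1))
    # vesicles on the presynaptic side (opposite the PSD): docked at the
    # membrane, then a chained pool receding from it
    vesicles: list[VesicleCircle] = []
    n_docked = 1 + rng.poisson(2.0)
    n_pool = rng.poisson(3.0)
    side = -1.0  # opposite the normal direction used for the PSD
    for k in range(n_docked):
        r = rng.uniform(*vesicle_radius)
        i = rng.integers(1, n_pts - 1)
        d = rng.uniform(0.2, 1.8) * r  # within one own diameter of the trace
        c = pre[i] + side * normals[i] * d
        vesicles.append(VesicleCircle(float(c[0]), float(c[1]), float(r)))
    for k in range(n_pool):
        r = rng.uniform(*vesicle_radius)
        prev = vesicles[-1]
        gap = rng.uniform(0.1, 1.5) * r  # within one own diameter of the chain
        ang = rng.uniform(-math.pi, 0.0)
        dist = prev.radius + r + gap
        c = prev.center + dist * np.array([math.cos(ang), math.sin(ang)])
        vesicles.append(VesicleCircle(float(c[0]), float(c[1]), float(r)))
    pose = RigidTransform2D(
        angle=float(rng.uniform(0.0, 2.0 * math.pi)),
        dx=float(rng.uniform(0.0, 5.0)),
        dy=float(rng.uniform(0.0, 5.0)),
    )
    pre_t = Polyline2D(pose.apply(pre))
    psd_t = Polyline2D(pose.apply(psd))
    ves_t = [
        VesicleCircle(*pose.apply(v.center), v.radius) for v in vesicles
    ]
    return SynapseProfile(id=pid, pre_membrane=pre_t, psd=psd_t, vesicles=ves_t)


def synthesize_study(
    scenario: StudyScenario,
    rng: np.random.Generator | int | None = None,
) -> StudyData:
    """Generate a full two-group study at the scenario's true parameters."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sc = scenario
    h = sc.section_thickness
    box = (sc.field_size, sc.field_size, sc.field_depth)
    groups: dict[str, str] = {}
    pairs: dict[str, list[DisectorPair]] = {}
    profiles: dict[str, list[SynapseProfile]] = {}
    truth: dict[str, dict[str, float]] = {}
    for animal_id, group in sc.animal_ids():
        groups[animal_id] = group
        lam_dcv = _animal_value(gen, sc.dcv_density[group], sc.animal_cv)
        lam_syn = _animal_value(gen, sc.synapse_density[group], sc.animal_cv)
        width = _animal_value(gen, sc.cleft_width[group], sc.animal_cv / 2.0)
        truth[animal_id] = {
            "dcv_density": lam_dcv,
            "synapse_density": lam_syn,
            "cleft_width": width,
        }
        animal_pairs = []
        for _ in range(sc.pairs_per_animal):
            f_dcv = simulate_field(box, lam_dcv, uniform_radii(*sc.dcv_radius), gen, "dcv")
            f_syn = simulate_field(
                box, lam_syn, uniform_radii(*sc.synapse_radius), gen, "synapse"
            )
            z0 = float(gen.uniform(0.0, sc.field_depth - 2 * h))
            animal_pairs.append(section_field([f_dcv, f_syn], z0, h))
        pairs[animal_id] = animal_pairs
        n_syn = int(gen.integers(sc.synapses_per_animal[0], sc.synapses_per_animal[1] + 1))
        profiles[animal_id] = [
            _make_profile(
                gen,
                f"{animal_id}-syn{k:03d}",
                width,
                sc.trace_noise_sd,
                sc.vesicle_radius,
            )
            for k in range(n_syn)
        ]
    return StudyData(scenario=sc, groups=groups, pairs=pairs, profiles=profiles, truth=truth)
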