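import math

import numpy as np
import pytest
from scipy import stats as sps

from emstereo.disector import (
    CircleFootprint,
    CountingFrame,
    DisectorPair,
    FramePlacementError,
    ParticleTransect,
    SectionAnnotation,
    count_frame,
    match_transects,
    numerical_density,
    place_frame,
)
from emstereo.geometry import Polygon2D, RigidTransform2D

FIELD_20 = Polygon2D([[0, 0], [20, 0], [20, 20], [0, 20]])


def make_pair(ref_transects, lookup_transects, bounds=FIELD_20,
              alignment=None, h=0.055):
    return DisectorPair(
        reference=SectionAnnotation("r", "reference", ref_transects, bounds),
        lookup=SectionAnnotation("l", "lookup", lookup_transects, bounds),
        alignment=alignment or RigidTransform2D.identity(),
        thickness=h,
    )


def circle(tid, x, y, r=0.05, ptype="dcv"):
    return ParticleTransect(tid, ptype, CircleFootprint(x, y, r))


class TestPlaceFrame:
    def test_always_fully_inside_large_field(self, rng):
        for _ in range(200):
            frame = place_frame(FIELD_20, 5.5, rng)
            c = frame.corners
            assert (c >= -1e-9).all() and (c <= 20 + 1e-9).all()

    def test_exact_fit_field_forces_central_placement(self):
        field = Polygon2D([[0, 0], [5.5, 0], [5.5, 5.5], [0, 5.5]])
        frame = place_frame(field, 5.5, rng=0, angle=0.0)
        assert np.allclose(frame.center, [2.75, 2.75])

    def test_field_too_small_raises(self):
        field = Polygon2D([[0, 0], [3, 0], [3, 3], [0, 3]])
        with pytest.raises(FramePlacementError):
            place_frame(field, 5.5, rng=0, max_attempts=100)

    def test_centers_uniform_over_feasible_region(self, rng):
        # fixed angle 0 on a square field: feasible centres fill an inner
        # square; bin them 5x5 and chi-square against uniformity
        centers = np.array(
            [place_frame(FIELD_20, 5.5, rng, angle=0.0).center for _ in range(30_000)]
        )
        lo, hi = 2.75, 20 - 2.75
        hist, _, _ = np.histogram2d(
            centers[:, 0], centers[:, 1], bins=5, range=[[lo, hi], [lo, hi]]
        )
        p = sps.chisquare(hist.ravel()).pvalue
        assert p > 0.01

    def test_angle_restricted_to_first_quadrant(self, rng):
        angles = [place_frame(FIELD_20, 5.5, rng).angle for _ in range(200)]
        assert all(0 <= a < math.pi / 2 for a in angles)


class TestMatchTransects:
    def test_identical_annotations_fully_matched(self):
        ts = [circle("a", 5, 5), circle("b", 8, 8, ptype="synapse", r=0.3)]
        pair = make_pair(ts, [circle("a2", 5, 5), circle("b2", 8, 8, ptype="synapse", r=0.3)])
        m = match_transects(pair)
        assert m == {"a": "a2", "b": "b2"}

    def test_extra_reference_dcv_stays_unmatched(self):
        pair = make_pair(
            [circle("a", 5, 5), circle("extra", 12, 12)],
            [circle("a2", 5, 5)],
        )
        m = match_transects(pair)
        assert m == {"a": "a2"}

    def test_type_mismatch_never_matches(self):
        pair = make_pair([circle("a", 5, 5, ptype="dcv")],
                         [circle("b", 5, 5, ptype="synapse", r=0.3)])
        assert match_transects(pair) == {}

    def test_respects_alignment_transform(self):
        shift = RigidTransform2D(0.0, 1.0, -2.0)
        # lookup coordinates are pre-shift; alignment maps them onto reference
        pair = make_pair([circle("a", 5, 5)], [circle("a2", 4, 7)], alignment=shift)
        assert match_transects(pair) == {"a": "a2"}

    def test_jittered_pairs_recover_ground_truth_matching(self, rng):
        tol = 0.25
        for _ in range(200):
            n = rng.integers(3, 12)
            pts = rng.uniform(1, 19, (n, 2))
            ref = [circle(f"r{i}", *pts[i]) for i in range(n)]
            jitter = rng.uniform(-tol / (2 * math.sqrt(2)), tol / (2 * math.sqrt(2)), (n, 2))
            lk = [circle(f"l{i}", *(pts[i] + jitter[i])) for i in range(n)]
            m = match_transects(make_pair(ref, lk), tolerance=tol)
            assert m == {f"r{i}": f"l{i}" for i in range(n)}

    def test_strict_id_mode(self):
        pair = make_pair([circle("x", 2, 2)], [circle("x", 9, 9)])
        assert match_transects(pair, use_ids=True) == {"x": "x"}


class TestCountFrame:
    FRAME = CountingFrame((10, 10), 5.5, 0.0)

    def test_inside_and_absent_from_lookup_is_counted(self):
        pair = make_pair([circle("a", 10, 10)], [])
        c = count_frame(pair, self.FRAME)
        assert c.classifications["a"] == "counted"
        assert c.q_minus["dcv"] == 1

    def test_straddling_top_border_is_forbidden(self):
        # top border at y = 10 + 2.75
        pair = make_pair([circle("a", 10, 12.75, r=0.1)], [])
        c = count_frame(pair, self.FRAME)
        assert c.classifications["a"] == "excluded_forbidden"
        assert c.q_minus["dcv"] == 0

    def test_straddling_right_border_is_forbidden(self):
        pair = make_pair([circle("a", 12.75, 10, r=0.1)], [])
        c = count_frame(pair, self.FRAME)
        assert c.classifications["a"] == "excluded_forbidden"

    def test_straddling_left_border_still_counts(self):
        pair = make_pair([circle("a", 7.25, 10, r=0.1)], [])
        c = count_frame(pair, self.FRAME)
        assert c.classifications["a"] == "counted"

    def test_present_on_both_sections_not_counted(self):
        pair = make_pair([circle("a", 10, 10)], [circle("a2", 10, 10)])
        c = count_frame(pair, self.FRAME)
        assert c.classifications["a"] == "present_in_lookup"
        assert c.q_minus["dcv"] == 0

    def test_outside_frame_labelled_outside(self):
        pair = make_pair([circle("a", 2, 2)], [])
        c = count_frame(pair, self.FRAME)
        assert c.classifications["a"] == "outside"

    def test_polygon_footprints_supported(self):
        tri = Polygon2D([[9.5, 9.5], [10.5, 9.5], [10.0, 10.3]])
        pair = make_pair([ParticleTransect("p", "synapse", tri)], [])
        c = count_frame(pair, self.FRAME)
        assert c.classifications["p"] == "counted"
        assert c.q_minus["synapse"] == 1

    def test_invariant_under_joint_rotation_of_scene_and_frame(self, rng):
        for _ in range(50):
            n = rng.integers(1, 10)
            pts = rng.uniform(6, 14, (n, 2))
            radii = rng.uniform(0.05, 0.8, n)
            ref = [circle(f"t{i}", *pts[i], r=radii[i]) for i in range(n)]
            base = count_frame(make_pair(ref, []), self.FRAME)
            theta = rng.uniform(0, 2 * math.pi)
            rot = RigidTransform2D(theta, 0.0, 0.0)
            big = Polygon2D([[-40, -40], [40, -40], [40, 40], [-40, 40]])
            ref_rot = [
                circle(f"t{i}", *rot.apply(pts[i]), r=radii[i]) for i in range(n)
            ]
            frame_rot = CountingFrame(rot.apply(self.FRAME.center), 5.5, theta)
            rotated = count_frame(make_pair(ref_rot, [], bounds=big), frame_rot)
            assert rotated.classifications == base.classifications

    def test_q_never_decreases_when_lookup_transect_deleted(self, rng):
        for _ in range(50):
            n = rng.integers(1, 8)
            pts = rng.uniform(7, 13, (n, 2))
            ref = [circle(f"t{i}", *pts[i]) for i in range(n)]
            lk = [circle(f"l{i}", *pts[i]) for i in range(n) if rng.uniform() < 0.7]
            full = count_frame(make_pair(ref, lk), self.FRAME).q_minus["dcv"]
            fewer = count_frame(make_pair(ref, lk[:-1] if lk else []), self.FRAME)
            assert fewer.q_minus["dcv"] >= full

    def test_bidirectional_counts_lookup_only_particles(self):
        pair = make_pair([circle("a", 10, 10)], [circle("b", 9, 9)])
        one_way = count_frame(pair, self.FRAME)
        both = count_frame(pair, self.FRAME, bidirectional=True)
        assert one_way.q_minus["dcv"] == 1
        assert both.q_minus["dcv"] == 2


class TestTilingCompleteness:
    def test_disjoint_convex_footprints_counted_exactly_once(self, rng):
        # abutting unrotated frames tile the plane; with forbidden top and
        # right borders each convex footprint is counted in exactly one tile
        a = 5.5
        for _ in range(20):
            n = int(rng.integers(5, 25))
            centers, radii = [], []
            while len(centers) < n:
                c = rng.uniform(0, 20, 2)
                r = rng.uniform(0.05, 1.0)
                if all(np.linalg.norm(c - c2) > r + r2 + 1e-6
                       for c2, r2 in zip(centers, radii)):
                    centers.append(c)
                    radii.append(r)
            big = Polygon2D([[-30, -30], [50, -30], [50, 50], [-30, 50]])
            ref = [circle(f"t{i}", *centers[i], r=radii[i]) for i in range(n)]
            pair = make_pair(ref, [], bounds=big)
            total = 0
            for i in range(-2, 6):
                for j in range(-2, 6):
                    frame = CountingFrame((a / 2 + i * a, a / 2 + j * a), a, 0.0)
                    total += count_frame(pair, frame).q_minus["dcv"]
            assert total == n


class TestForbiddenLineExtension:
    def test_corner_spanning_footprint_counted_once_only_with_extension(self):
        # circle crossing the x=11 grid line below y=11 and the y=11 line
        # left of x=11, while missing the diagonal tile [11,16.5]²: the
        # two-segment literal rule accepts it in two tiles, the default
        # extended forbidden line in exactly one
        a = 5.5
        c, r = (10.1, 10.6), 0.95
        big = Polygon2D([[-30, -30], [50, -30], [50, 50], [-30, 50]])
        pair = make_pair([circle("t", *c, r=r)], [], bounds=big)

        def tiling_count(literal):
            total = 0
            for i in range(-2, 6):
                for j in range(-2, 6):
                    frame = CountingFrame((a / 2 + i * a, a / 2 + j * a), a, 0.0)
                    cnt = count_frame(pair, frame, literal_borders=literal)
                    total += cnt.q_minus["dcv"]
            return total

        assert tiling_count(literal=False) == 1
        assert tiling_count(literal=True) == 2


class TestNumericalDensity:
    def test_hand_computed_single_frame(self):
        pair = make_pair([circle("a", 10, 10), circle("b", 11, 11)], [])
        c = count_frame(pair, CountingFrame((10, 10), 5.5, 0.0))
        est = numerical_density([c], 5.5, 0.055)["dcv"]
        assert est.total_q == 2
        # 2 / (5.5 * 5.5 * 0.055) = 2 / 1.66375
        assert est.n_v == pytest.approx(2 / 1.66375, rel=1e-12)
        assert est.n_v == pytest.approx(1.2021, abs=1e-4)

    def test_empty_frames_give_zero(self):
        pair = make_pair([], [])
        counts = [count_frame(pair, CountingFrame((10, 10), 5.5, 0.0))
                  for _ in range(5)]
        for est in numerical_density(counts, 5.5, 0.055).values():
            assert est.n_v == 0.0

    def test_linearity_over_frames(self, rng):
        counts = []
        s = 0
        for _ in range(20):
            n = int(rng.integers(0, 5))
            ref = [circle(f"t{i}", *rng.uniform(8, 12, 2)) for i in range(n)]
            c = count_frame(make_pair(ref, []), CountingFrame((10, 10), 5.5, 0.0))
            s += c.q_minus["dcv"]
            counts.append(c)
        est = numerical_density(counts, 5.5, 0.055)["dcv"]
        assert est.n_v == pytest.approx(s / (20 * 1.66375), rel=1e-12)
        assert est.mean_q_per_frame == pytest.approx(s / 20)

    def test_no_frames_raises(self):
        with pytest.raises(ValueError):
            numerical_density([], 5.5, 0.055)


class TestValidation:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SectionAnnotation("s", "reference",
                              [circle("a", 5, 5), circle("a", 6, 6)], FIELD_20)

    def test_footprint_outside_field_rejected(self):
        with pytest.raises(ValueError, match="outside the field"):
            SectionAnnotation("s", "reference", [circle("a", 50, 50)], FIELD_20)

    def test_wrong_roles_rejected(self):
        ref = SectionAnnotation("r", "reference", [], FIELD_20)
        with pytest.raises(ValueError):
            DisectorPair(reference=ref, lookup=ref)
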