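import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rotdet.geometry import (
    HorizontalBox,
    RotatedBox,
    boxes_to_array,
    canonicalize,
    circumscribed_hbb,
    convex_intersection_area,
    corners_batch,
    corners_to_rbox,
    hbb_iou,
    intersection_areas_one_to_many,
    normalize_angle,
    rbox_to_corners,
    rotated_nms,
    skew_iof,
    skew_iou,
    skew_iou_one_to_many,
)
from conftest import mc_skew_iou, random_rbox

PI = math.pi
OCTAGON = 8 * (math.sqrt(2) - 1)  # overlap of unit squares rotated 45 deg, scaled by 4


class TestAngles:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            (3 * PI / 4, -PI / 4),  # upper boundary wraps by one period
            (0.0, 0.0),
            (-PI / 2, PI / 2),
            (PI, 0.0),
            (-PI / 4, -PI / 4),  # lower boundary is inclusive
        ],
    )
    def test_normalize_examples(self, theta, expected):
        assert normalize_angle(theta) == pytest.approx(expected, abs=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            normalize_angle(float("nan"))

    @given(st.floats(-50.0, 50.0))
    @settings(max_examples=200, derandomize=True)
    def test_normalize_idempotent_and_congruent(self, theta):
        a = normalize_angle(theta)
        assert -PI / 4 <= a < 3 * PI / 4
        assert normalize_angle(a) == a
        # congruent modulo pi
        assert math.isclose(math.sin(a - theta), 0.0, abs_tol=1e-9)


class TestCanonicalize:
    @pytest.mark.parametrize(
        "params, expected",
        [
            ((0, 0, 2, 4, 0), (0, 0, 4, 2, PI / 2)),
            ((0, 0, 4, 2, PI), (0, 0, 4, 2, 0)),
            ((1, 1, 3, 3, -PI / 3), (1, 1, 3, 3, 2 * PI / 3)),
        ],
    )
    def test_examples(self, params, expected):
        b = canonicalize(*params)
        assert b.astuple() == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_edges(self):
        with pytest.raises(ValueError):
            canonicalize(0, 0, 0.0, 2, 0)

    @given(
        st.floats(1.0, 50.0), st.floats(1.0, 50.0), st.floats(-6.0, 6.0)
    )
    @settings(max_examples=200, derandomize=True)
    def test_idempotent_and_area_preserving(self, w, h, theta):
        b = canonicalize(0, 0, w, h, theta)
        again = canonicalize(*b.astuple())
        assert again == b
        assert b.area == pytest.approx(w * h, rel=1e-12)
        assert b.w >= b.h


class TestCorners:
    def test_axis_aligned(self):
        q = rbox_to_corners(RotatedBox(0, 0, 4, 2, 0))
        assert q == pytest.approx(
            np.array([(-2, -1), (2, -1), (2, 1), (-2, 1)]), abs=1e-12
        )

    def test_rotated_square(self):
        q = rbox_to_corners(canonicalize(0, 0, 2, 2, PI / 4))
        r2 = math.sqrt(2)
        assert q == pytest.approx(
            np.array([(0, -r2), (r2, 0), (0, r2), (-r2, 0)]), abs=1e-12
        )

    def test_translation_equivariance(self):
        q0 = rbox_to_corners(RotatedBox(0, 0, 4, 2, 0))
        q1 = rbox_to_corners(RotatedBox(5, 7, 4, 2, 0))
        assert q1 - q0 == pytest.approx(np.array([[5.0, 7.0]] * 4))

    def test_shoelace_area_matches(self, rng):
        for _ in range(50):
            b = random_rbox(rng)
            q = rbox_to_corners(b)
            x, y = q[:, 0], q[:, 1]
            area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
            assert area == pytest.approx(b.area, rel=1e-9)

    def test_round_trip(self, rng):
        for _ in range(50):
            b = random_rbox(rng)
            r = corners_to_rbox(rbox_to_corners(b))
            assert r.astuple() == pytest.approx(b.astuple(), abs=1e-9)

    def test_round_trip_rotated_start(self):
        b = canonicalize(3, 3, 5, 1, PI / 3)
        q = rbox_to_corners(b)
        r = corners_to_rbox(np.roll(q, 1, axis=0))
        assert r.astuple() == pytest.approx(b.astuple(), abs=1e-9)

    def test_rejects_non_rectangle(self):
        with pytest.raises(ValueError):
            corners_to_rbox([(0, 0), (4, 0), (5, 3), (0, 2)])

    def test_corners_batch_matches_scalar(self, rng):
        boxes = [random_rbox(rng) for _ in range(20)]
        batch = corners_batch(boxes_to_array(boxes))
        for b, q in zip(boxes, batch):
            assert q == pytest.approx(rbox_to_corners(b), abs=1e-9)


class TestCircumscription:
    @pytest.mark.parametrize(
        "box, expected",
        [
            (canonicalize(0, 0, 4, 2, PI / 2), (-1, -2, 1, 2)),
            (canonicalize(0, 0, 2, 2, PI / 4), (-math.sqrt(2),) * 2 + (math.sqrt(2),) * 2),
            (RotatedBox(0, 0, 4, 2, 0), (-2, -1, 2, 1)),
        ],
    )
    def test_examples(self, box, expected):
        assert circumscribed_hbb(box).astuple() == pytest.approx(expected, abs=1e-12)

    def test_never_smaller_than_box(self, rng):
        for _ in range(50):
            b = random_rbox(rng)
            assert circumscribed_hbb(b).area >= b.area - 1e-9


class TestIntersection:
    def test_self_intersection(self):
        b = canonicalize(1, 2, 5, 3, 0.7)
        assert convex_intersection_area(b, b) == pytest.approx(b.area, rel=1e-9)

    def test_axis_aligned_overlap(self):
        a = RotatedBox(2, 1, 4, 2, 0)
        b = RotatedBox(3, 1, 4, 2, 0)
        assert convex_intersection_area(a, b) == pytest.approx(6.0, abs=1e-9)

    def test_octagon_closed_form(self):
        a = RotatedBox(0, 0, 2, 2, 0)
        b = canonicalize(0, 0, 2, 2, PI / 4)
        assert convex_intersection_area(a, b) == pytest.approx(OCTAGON, abs=1e-9)

    def test_shared_edge_is_zero(self):
        a = RotatedBox(0, 0, 2, 2, 0)
        b = RotatedBox(2, 0, 2, 2, 0)
        assert convex_intersection_area(a, b) == 0.0

    def test_against_shapely(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Polygon

        for _ in range(100):
            a, b = random_rbox(rng), random_rbox(rng)
            ours = convex_intersection_area(a, b)
            ref = Polygon(rbox_to_corners(a)).intersection(
                Polygon(rbox_to_corners(b))
            ).area
            assert ours == pytest.approx(ref, abs=1e-6)


class TestSkewIoU:
    def test_identical(self):
        b = canonicalize(5, 5, 8, 2, 1.0)
        assert skew_iou(b, b) == pytest.approx(1.0, rel=1e-12)

    def test_disjoint(self):
        assert skew_iou(RotatedBox(0, 0, 4, 2, 0), RotatedBox(100, 100, 4, 2, 0)) == 0.0

    def test_rotated_squares_closed_form(self):
        a = RotatedBox(0, 0, 2, 2, 0)
        b = canonicalize(0, 0, 2, 2, PI / 4)
        expected = OCTAGON / (8 - OCTAGON)
        assert skew_iou(a, b) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.70710678, abs=1e-6)

    def test_symmetry_and_range(self, rng):
        for _ in range(100):
            a, b = random_rbox(rng), random_rbox(rng)
            v = skew_iou(a, b)
            assert v == skew_iou(b, a)
            assert 0.0 <= v <= 1.0 + 1e-12

    def test_rigid_motion_invariance(self, rng):
        for _ in range(30):
            a, b = random_rbox(rng), random_rbox(rng)
            base = skew_iou(a, b)
            dx, dy = rng.uniform(-50, 50, 2)
            phi = rng.uniform(-PI, PI)
            c, s = math.cos(phi), math.sin(phi)

            def move(bx: RotatedBox) -> RotatedBox:
                nx = c * bx.x - s * bx.y + dx
                ny = s * bx.x + c * bx.y + dy
                return canonicalize(nx, ny, bx.w, bx.h, bx.theta + phi)

            assert skew_iou(move(a), move(b)) == pytest.approx(base, abs=1e-9)

    def test_monte_carlo_oracle_sample(self, rng):
        # small-n version of the full oracle sweep in the acceptance suite
        for _ in range(20):
            a, b = random_rbox(rng), random_rbox(rng)
            est = mc_skew_iou(a, b, rng, n=200_000)
            assert abs(skew_iou(a, b) - est) <= 0.02

    def test_slender_gt_hbb_bound(self, rng):
        # the skew IoU of a horizontal anchor with a slender oblique gt is
        # bounded by the plain IoU of the anchor with the gt's circumscribed
        # horizontal box (the motivation for adaptive sample selection)
        hits = 0
        n = 0
        while n < 200:
            gt = random_rbox(rng, min_aspect=3.0)
            # genuinely oblique: at least 0.2 rad away from both image axes
            # (for near-axis-aligned gts the two overlaps coincide and the
            # inequality can flip by a hair)
            if min(
                abs(gt.theta), abs(gt.theta - PI / 2),
                abs(gt.theta + PI / 4), abs(gt.theta - 3 * PI / 4),
            ) < 0.2:
                continue
            n += 1
            ext = circumscribed_hbb(gt)
            anchor = canonicalize(
                gt.x + rng.uniform(-5, 5), gt.y + rng.uniform(-5, 5),
                ext.width * rng.uniform(0.7, 1.3),
                ext.height * rng.uniform(0.7, 1.3), 0.0
            )
            lhs = skew_iou(anchor, gt)
            rhs = hbb_iou(circumscribed_hbb(anchor), circumscribed_hbb(gt))
            if lhs <= rhs + 1e-9:
                hits += 1
        assert hits / n >= 0.99

    def test_one_to_many_matches_scalar(self, rng):
        probe = random_rbox(rng)
        others = [random_rbox(rng) for _ in range(50)]
        batch = skew_iou_one_to_many(
            np.array(probe.astuple()), boxes_to_array(others)
        )
        for v, o in zip(batch, others):
            assert v == pytest.approx(skew_iou(probe, o), abs=1e-9)

    def test_one_to_many_intersection_empty(self):
        probe = np.array([0, 0, 4, 2, 0.0])
        assert intersection_areas_one_to_many(probe, np.zeros((0, 5))).shape == (0,)


class TestSkewIoF:
    def test_det_inside_gt(self):
        det = RotatedBox(0, 0, 2, 1, 0)
        gt = RotatedBox(0, 0, 10, 10, 0)
        assert skew_iof(det, gt) == pytest.approx(1.0, rel=1e-12)

    def test_half_overlap(self):
        det = RotatedBox(1, 0, 4, 2, 0)
        gt = RotatedBox(0, 0, 2, 2, 0)
        assert skew_iof(det, gt) == pytest.approx(0.5, abs=1e-12)

    def test_disjoint(self):
        assert skew_iof(RotatedBox(0, 0, 4, 2, 0), RotatedBox(50, 50, 4, 2, 0)) == 0.0

    def test_dominates_iou(self, rng):
        for _ in range(50):
            a, b = random_rbox(rng), random_rbox(rng)
            assert skew_iof(a, b) >= skew_iou(a, b) - 1e-12


class TestRotatedNMS:
    def test_identical_boxes(self):
        b = canonicalize(5, 5, 6, 2, 0.3)
        keep = rotated_nms([b, b], [0.9, 0.8], 0.5)
        assert keep == [0]

    def test_disjoint_boxes(self):
        a = RotatedBox(0, 0, 4, 2, 0)
        b = RotatedBox(100, 100, 4, 2, 0)
        assert sorted(rotated_nms([a, b], [0.3, 0.9], 0.5)) == [0, 1]

    def test_suppression_chain(self):
        # A suppresses B; C survives because it only overlaps B, not A
        a = RotatedBox(0, 0, 10, 4, 0)
        b = RotatedBox(3, 0, 10, 4, 0)
        c = RotatedBox(6, 0, 10, 4, 0)
        assert skew_iou(a, b) > 0.5 and skew_iou(b, c) > 0.5 and skew_iou(a, c) < 0.5
        assert rotated_nms([a, b, c], [0.9, 0.8, 0.7], 0.5) == [0, 2]

    def test_idempotent(self, rng):
        boxes = [random_rbox(rng, span=40) for _ in range(30)]
        scores = rng.uniform(0, 1, 30)
        keep = rotated_nms(boxes, scores, 0.4)
        again = rotated_nms([boxes[i] for i in keep], [scores[i] for i in keep], 0.4)
        assert [keep[i] for i in again] == keep

    def test_score_tie_stable(self):
        b = canonicalize(5, 5, 6, 2, 0.3)
        assert rotated_nms([b, b], [0.5, 0.5], 0.9) == [0]

    def test_empty(self):
        assert rotated_nms([], [], 0.5) == []


def test_horizontal_box_validation():
    with pytest.raises(ValueError):
        HorizontalBox(2, 0, 1, 5)
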