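import math

import numpy as np
import pytest

from rotdet.anchors import (
    NEGATIVE,
    adaptive_assign,
    adaptive_threshold,
    build_anchor_pyramid,
    sample_training_batch,
)
from rotdet.geometry import boxes_to_array, canonicalize, skew_iou
from rotdet.synthetic import SceneSpec, generate_scene

PI = math.pi


def brute_force_assign(pyramid, gts, n_per_level=9):
    """Reference assignment: explicit loops and scalar skew IoU, mirroring
    the documented rules (center-closest candidates per level, mean+std
    threshold, larger-IoU conflict resolution, per-instance fallback)."""
    from rotdet.geometry import array_to_boxes

    gt_boxes = array_to_boxes(gts)
    flat = pyramid.flat
    anchor_boxes = array_to_boxes(flat)
    n_anchors = len(anchor_boxes)
    labels = [NEGATIVE] * n_anchors

    candidates, cand_ious, wanted = [], [], []
    for gt_arr, gt in zip(gts, gt_boxes):
        cand = []
        for lvl in range(pyramid.n_levels):
            offs = pyramid.level_offsets[lvl]
            anchors = pyramid.anchors[lvl]
            dists = []
            for i in range(len(anchors)):
                d2 = (anchors[i, 0] - gt_arr[0]) ** 2 + (anchors[i, 1] - gt_arr[1]) ** 2
                dists.append((d2, i))
            dists.sort()
            cand.extend(offs + i for _, i in dists[:n_per_level])
        ious = [skew_iou(anchor_boxes[a], gt) for a in cand]
        arr = np.array(ious)
        t = float(arr.mean() + arr.std())
        pos = [a for a, v in zip(cand, ious) if v >= t]
        if not pos:
            best_j = max(range(len(ious)), key=lambda j: (ious[j], -j))
            pos = [cand[best_j]]
        candidates.append(cand)
        cand_ious.append(ious)
        wanted.append(pos)

    best_iou = [-1.0] * n_anchors
    for g in range(len(gt_boxes)):
        iou_of = dict(zip(candidates[g], cand_ious[g]))
        for a in wanted[g]:
            if iou_of[a] > best_iou[a] + 1e-12:
                best_iou[a] = iou_of[a]
                labels[a] = g

    counts = [0] * len(gt_boxes)
    for lab in labels:
        if lab != NEGATIVE:
            counts[lab] += 1
    for g in range(len(gt_boxes)):
        if counts[g] > 0:
            continue
        order = sorted(range(len(candidates[g])), key=lambda j: (-cand_ious[g][j], j))
        claimed = None
        for j in order:
            a = candidates[g][j]
            owner = labels[a]
            if owner == NEGATIVE or counts[owner] > 1:
                claimed = a
                break
        if claimed is None:
            claimed = candidates[g][order[0]]
        owner = labels[claimed]
        if owner != NEGATIVE:
            counts[owner] -= 1
        labels[claimed] = g
        counts[g] += 1
    return np.array(labels)


class TestAnchorPyramid:
    def test_level_counts(self):
        pyr = build_anchor_pyramid((64, 64), strides=(4,), areas=(32.0**2,))
        assert pyr.grid_sizes == [(16, 16)]
        assert pyr.n_anchors == 16 * 16 * 3

    def test_full_pyramid_counts_and_areas(self):
        pyr = build_anchor_pyramid((256, 256))
        assert pyr.n_levels == 5
        for lvl, (s, area) in enumerate(zip(pyr.strides, (32, 64, 128, 256, 512))):
            anchors = pyr.anchors[lvl]
            gw, gh = pyr.grid_sizes[lvl]
            assert gw == math.ceil(256 / s) and len(anchors) == gw * gh * 3
            assert anchors[:, 2] * anchors[:, 3] == pytest.approx(area**2, rel=1e-9)

    def test_square_anchor_geometry(self):
        pyr = build_anchor_pyramid((64, 64), strides=(4,), areas=(32.0**2,))
        # ratio order (0.5, 1, 2); index 1 is the square anchor at cell (0,0)
        sq = pyr.anchors[0][1]
        assert sq == pytest.approx((2.0, 2.0, 32.0, 32.0, 0.0))

    def test_tall_anchor_canonicalized(self):
        pyr = build_anchor_pyramid((64, 64), strides=(4,), areas=(32.0**2,))
        tall = pyr.anchors[0][0]  # ratio 0.5 => h = 2w before canonicalization
        assert tall[2] > tall[3]
        assert tall[4] == pytest.approx(PI / 2)
        wide = pyr.anchors[0][2]  # ratio 2 stays horizontal
        assert wide[4] == 0.0
        assert wide[2] == pytest.approx(tall[2])

    def test_ceil_grid(self):
        pyr = build_anchor_pyramid((65, 63), strides=(4,), areas=(32.0**2,))
        assert pyr.grid_sizes == [(17, 16)]

    def test_empty_strides_rejected(self):
        with pytest.raises(ValueError):
            build_anchor_pyramid((64, 64), strides=(), areas=())


class TestAdaptiveThreshold:
    def test_single_good_candidate(self):
        ious = np.array([0.5, 0.0, 0.0])
        t = adaptive_threshold(ious)
        assert t == pytest.approx(1 / 6 + math.sqrt(1 / 18), abs=1e-9)
        assert (ious >= t).sum() == 1

    def test_all_equal_all_positive(self):
        ious = np.full(5, 0.4)
        t = adaptive_threshold(ious)
        assert t == pytest.approx(0.4)
        assert (ious >= t).all()

    def test_fallback_needed_when_threshold_exceeds_max(self):
        ious = np.array([1.0, 1.0, 0.0])
        t = adaptive_threshold(ious)
        assert t == pytest.approx(2 / 3 + math.sqrt(2) / 3, abs=1e-9)
        assert t > ious.max()  # bare rule yields no positives: fallback required


class TestAdaptiveAssign:
    def test_zero_gts_all_negative(self):
        pyr = build_anchor_pyramid((32, 32), strides=(4,), areas=(32.0**2,))
        res = adaptive_assign(pyr, np.zeros((0, 5)))
        assert (res.labels == NEGATIVE).all()

    def test_every_gt_gets_positive_on_scenes(self):
        pyr = build_anchor_pyramid((128, 128))
        for seed in range(20):
            scene = generate_scene(
                SceneSpec(n_instances="sparse", image_size=(128, 128),
                          length_range=(20, 80), seed=seed)
            )
            gts = boxes_to_array(scene.record.instances)
            res = adaptive_assign(pyr, gts)
            assert (res.positive_counts >= 1).all()
            # each positive anchor maps to exactly one gt by construction
            assert res.positives.size >= len(gts)

    def test_agrees_with_brute_force(self, rng):
        from conftest import random_rbox

        for trial in range(20):
            size = int(rng.integers(24, 41))
            pyr = build_anchor_pyramid(
                (size, size), strides=(4, 8), areas=(16.0**2, 32.0**2)
            )
            assert pyr.n_anchors <= 500
            n_gt = int(rng.integers(1, 6))
            gts = boxes_to_array(
                [random_rbox(rng, span=size, edge_lo=3, edge_hi=size) for _ in range(n_gt)]
            )
            fast = adaptive_assign(pyr, gts, n_per_level=5).labels
            slow = brute_force_assign(pyr, gts, n_per_level=5)
            np.testing.assert_array_equal(fast, slow)

    def test_accepts_box_objects(self):
        pyr = build_anchor_pyramid((64, 64), strides=(4,), areas=(16.0**2,))
        res = adaptive_assign(pyr, [canonicalize(32, 32, 30, 6, 0.4)])
        assert res.positive_counts[0] >= 1


class TestSampling:
    def _assignment(self, n_pos, n_total=1000):
        from rotdet.anchors import AssignmentResult

        labels = np.full(n_total, NEGATIVE)
        labels[:n_pos] = 0
        return AssignmentResult(
            labels=labels, thresholds=np.zeros(1),
            candidates=[np.arange(n_pos)], positive_counts=np.array([n_pos]),
        )

    def test_one_to_one_ratio(self):
        batch = sample_training_batch(self._assignment(10), seed=0)
        assert batch.n_pos == 10
        assert len(batch.negative_indices) == 10

    def test_cap_at_half(self):
        batch = sample_training_batch(self._assignment(300), n_samples=256, seed=0)
        assert batch.n_pos == 128
        assert batch.n_total == 256

    def test_deterministic(self):
        a = sample_training_batch(self._assignment(300), seed=42)
        b = sample_training_batch(self._assignment(300), seed=42)
        np.testing.assert_array_equal(a.positive_indices, b.positive_indices)
        np.testing.assert_array_equal(a.negative_indices, b.negative_indices)

    def test_no_negatives_rejected(self):
        with pytest.raises(ValueError):
            sample_training_batch(self._assignment(5, n_total=5), seed=0)
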