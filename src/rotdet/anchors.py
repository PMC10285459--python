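"""Anchor generation and adaptive positive-sample selection.

The proposal stage lays three horizontal anchors (aspect ratios 0.5, 1, 2)
at every cell of the feature pyramid levels P2-P6 (strides 4-64, anchor
areas 32^2-512^2) and regresses rotated proposals from them. Because the
targets are slender and arbitrarily oriented, a fixed skew-IoU threshold
separates positives poorly: a well-placed horizontal anchor rarely exceeds
a conventional 0.5 overlap with an oblique sliver. Sample selection is
therefore adaptive, per ground truth: gather the ``n`` center-closest
anchors on each pyramid level, compute their skew IoU with the ground
truth, and threshold at ``mean + std`` of those IoUs. Any ground truth
whose candidates all fall below its own threshold still receives its
best-overlapping candidate, so every instance owns at least one positive.

Training batches are then drawn at a strict 1:1 positive:negative ratio up
to ``N = 256`` samples per image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import canonicalize, skew_iou

__all__ = [
    "AnchorPyramid",
    "AssignmentResult",
    "SampledBatch",
    "build_anchor_pyramid",
    "adaptive_assign",
    "adaptive_threshold",
    "sample_training_batch",
    "DEFAULT_STRIDES",
    "DEFAULT_AREAS",
    "DEFAULT_RATIOS",
]

DEFAULT_STRIDES: tuple[int, ...] = (4, 8, 16, 32, 64)
DEFAULT_AREAS: tuple[float, ...] = (32.0**2, 64.0**2, 128.0**2, 256.0**2, 512.0**2)
DEFAULT_RATIOS: tuple[float, ...] = (0.5, 1.0, 2.0)

NEGATIVE = -1


@dataclass
class AnchorPyramid:
    """Per-level anchor sets with flat global indexing.

    ``anchors[l]`` is an (N_l, 5) array in the canonical long-edge
    convention (ratio-0.5 anchors become theta = pi/2 boxes). Flat order is
    level-major, then row-major over the grid, then the per-location
    anchors in ratio order.
    """

    strides: tuple[int, ...]
    grid_sizes: list[tuple[int, int]]  # (W_l, H_l)
    anchors: list[np.ndarray]
    level_offsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.level_offsets:
            offs, total = [], 0
            for a in self.anchors:
                offs.append(total)
                total += len(a)
            self.level_offsets = offs

    @property
    def n_levels(self) -> int:
        return len(self.anchors)

    @property
    def n_anchors(self) -> int:
        return sum(len(a) for a in self.anchors)

    @property
    def flat(self) -> np.ndarray:
        return np.concatenate(self.anchors, axis=0)

    def level_slice(self, level: int) -> slice:
        start = self.level_offsets[level]
        return slice(start, start + len(self.anchors[level]))


@dataclass
class AssignmentResult:
    """Per-anchor labels plus per-ground-truth bookkeeping.

    ``labels[i]`` is the index of the ground truth anchor ``i`` is positive
    for, or ``NEGATIVE``. ``thresholds[g]`` is the adaptive mean+std skew-IoU
    threshold of ground truth ``g``; ``candidates[g]`` its center-closest
    candidate anchor indices.
    """

    labels: np.ndarray
    thresholds: np.ndarray
    candidates: list[np.ndarray]
    positive_counts: np.ndarray

    @property
    def positives(self) -> np.ndarray:
        return np.nonzero(self.labels != NEGATIVE)[0]

    @property
    def negatives(self) -> np.ndarray:
        return np.nonzero(self.labels == NEGATIVE)[0]


@dataclass
class SampledBatch:
    positive_indices: np.ndarray
    negative_indices: np.ndarray

    @property
    def n_pos(self) -> int:
        return len(self.positive_indices)

    @property
    def n_total(self) -> int:
        return len(self.positive_indices) + len(self.negative_indices)


def build_anchor_pyramid(
    image_size: tuple[int, int],
    strides: tuple[int, ...] = DEFAULT_STRIDES,
    areas: tuple[float, ...] = DEFAULT_AREAS,
    ratios: tuple[float, ...] = DEFAULT_RATIOS,
) -> AnchorPyramid:
    """Generate horizontal anchors over every pyramid level.

    Cell (i, j) at stride ``s`` centers its anchors at ((i+0.5)s, (j+0.5)s).
    An anchor of area A and ratio r = w/h has edges (sqrt(A*r), sqrt(A/r))
    before canonicalization. Grid sizes are ceil(W/s) x ceil(H/s).
    """
    if not strides:
        raise ValueError("at least one pyramid level required")
    if len(strides) != len(areas):
        raise ValueError("strides and areas must align")
    w_img, h_img = image_size
    grid_sizes: list[tuple[int, int]] = []
    per_level: list[np.ndarray] = []
    for s, area in zip(strides, areas):
        gw = math.ceil(w_img / s)
        gh = math.ceil(h_img / s)
        grid_sizes.append((gw, gh))
        shapes = np.array(
            [canonicalize(0, 0, math.sqrt(area * r), math.sqrt(area / r), 0.0).astuple()
             for r in ratios]
        )  # (R, 5), theta in {0, pi/2}
        cx = (np.arange(gw) + 0.5) * s
        cy = (np.arange(gh) + 0.5) * s
        # row-major grid, then ratio
        gx, gy = np.meshgrid(cx, cy)  # (gh, gw)
        centers = np.stack([gx.ravel(), gy.ravel()], axis=1)  # (gh*gw, 2)
        n_loc = len(centers)
        block = np.repeat(shapes[None, :, :], n_loc, axis=0).reshape(-1, 5)
        block[:, 0] = np.repeat(centers[:, 0], len(ratios))
        block[:, 1] = np.repeat(centers[:, 1], len(ratios))
        per_level.append(block)
    return AnchorPyramid(strides=tuple(strides), grid_sizes=grid_sizes, anchors=per_level)


def adaptive_threshold(ious: np.ndarray) -> float:
    """The per-instance positive threshold: mean + population std of the
    candidate skew IoUs."""
    ious = np.asarray(ious, dtype=float)
    return float(ious.mean() + ious.std())


def adaptive_assign(
    pyramid: AnchorPyramid,
    gts: np.ndarray,
    n_per_level: int = 9,
) -> AssignmentResult:
    """Adaptive positive/negative split of all anchors against ground truths.

    For each ground truth: the ``n_per_level`` anchors closest to its
    center on each level are candidates; candidates with skew IoU at or
    above the instance's mean+std threshold are positive. A ground truth
    with no candidate above threshold claims its best-overlap candidate.
    Anchors wanted by several ground truths go to the one with the larger
    IoU (ties: lower ground-truth index); if that reassignment strips a
    ground truth of all positives it reclaims its best available candidate.
    ``gts`` may be an (G, 5) array or a list of RotatedBox.
    """
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    if not isinstance(gts, np.ndarray):
        from .geometry import boxes_to_array

        gts = boxes_to_array(gts)
    gts = np.asarray(gts, dtype=float).reshape(-1, 5)
    n_anchors = pyramid.n_anchors
    n_gt = len(gts)
    labels = np.full(n_anchors, NEGATIVE, dtype=int)
    if n_gt == 0:
        return AssignmentResult(
            labels=labels,
            thresholds=np.zeros(0),
            candidates=[],
            positive_counts=np.zeros(0, dtype=int),
        )

    flat = pyramid.flat
    thresholds = np.zeros(n_gt)
    candidates: list[np.ndarray] = []
    cand_ious: list[np.ndarray] = []
    wanted: list[np.ndarray] = []  # per gt: candidate indices above threshold

    for g in range(n_gt):
        gt = gts[g]
        idxs: list[np.ndarray] = []
        for lvl in range(pyramid.n_levels):
            anchors = pyramid.anchors[lvl]
            d2 = (anchors[:, 0] - gt[0]) ** 2 + (anchors[:, 1] - gt[1]) ** 2
            k = min(n_per_level, len(anchors))
            # deterministic top-k by (distance, index)
            order = np.lexsort((np.arange(len(d2)), d2))[:k]
            idxs.append(order + pyramid.level_offsets[lvl])
        cand = np.concatenate(idxs)
        # scalar IoU per candidate: candidate sets are small (m*n per gt)
        # and the pairwise path keeps threshold comparisons bit-stable
        gt_box = canonicalize(*gt)
        ious = np.array(
            [skew_iou(canonicalize(*flat[a]), gt_box) for a in cand]
        )
        t = adaptive_threshold(ious)
        pos = cand[ious >= t]
        if len(pos) == 0:
            best = cand[int(np.argmax(ious))]
            pos = np.array([best])
        candidates.append(cand)
        cand_ious.append(ious)
        thresholds[g] = t
        wanted.append(pos)

    # resolve multi-claimed anchors: larger IoU wins, ties to lower gt index
    best_iou = np.full(n_anchors, -1.0)
    for g in range(n_gt):
        iou_map = dict(zip(candidates[g].tolist(), cand_ious[g].tolist()))
        for a in wanted[g]:
            iou = iou_map[int(a)]
            if iou > best_iou[a] + 1e-12:
                best_iou[a] = iou
                labels[a] = g

    # fallback pass: every gt must keep at least one positive
    counts = np.bincount(labels[labels != NEGATIVE], minlength=n_gt)
    for g in range(n_gt):
        if counts[g] > 0:
            continue
        order = np.argsort(-cand_ious[g], kind="stable")
        claimed = None
        for j in order:
            a = int(candidates[g][j])
            owner = labels[a]
            if owner == NEGATIVE or counts[owner] > 1:
                claimed = a
                break
        if claimed is None:  # all candidates are sole positives of other gts
            claimed = int(candidates[g][order[0]])
        owner = labels[claimed]
        if owner != NEGATIVE:
            counts[owner] -= 1
        labels[claimed] = g
        counts[g] += 1

    return AssignmentResult(
        labels=labels,
        thresholds=thresholds,
        candidates=candidates,
        positive_counts=counts,
    )


def sample_training_batch(
    assignment: AssignmentResult,
    n_samples: int = 256,
    seed: int | np.random.Generator = 0,
) -> SampledBatch:
    """Draw the per-image training batch at a strict 1:1 pos:neg ratio.

    Up to ``n_samples/2`` positives are kept (uniform subsample without
    replacement when there are more); the same number of negatives is drawn
    uniformly. Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = assignment.positives
    neg = assignment.negatives
    if len(neg) == 0:
        raise ValueError("no negative anchors available (degenerate configuration)")
    half = n_samples // 2
    if len(pos) > half:
        pos = np.sort(rng.choice(pos, size=half, replace=False))
    n_neg = min(len(pos), len(neg))
    neg = np.sort(rng.choice(neg, size=n_neg, replace=False))
    return SampledBatch(positive_indices=pos, negative_indices=neg)
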