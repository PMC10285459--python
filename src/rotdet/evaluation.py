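"""Rotated-detection scoring: greedy matching, precision-recall, AP.

Detections are matched to ground truth per image in descending score
order: a detection is a true positive if its best-overlapping *unmatched*
ground truth meets the overlap threshold, under either criterion:

* **IoU** — skew intersection over union;
* **IoF** — skew intersection over foreground (overlap / detection area),
  forgiving toward detections that cover part of a truncated symptom.

Precision P = TP/(TP+FP) and recall R = TP/(TP+FN) are swept over every
distinct confidence score; AP integrates precision over recall
(all-points interpolation with the monotone precision envelope; an
11-point variant is available). Reports can be broken down by density
subset (sparse / medium / dense).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotations import AnnotationRecord, split_subsets
from .geometry import (
    RotatedBox,
    boxes_to_array,
    intersection_areas_one_to_many,
    skew_iou_one_to_many,
)

__all__ = [
    "MatchResult",
    "PRCurve",
    "EvalSummary",
    "match_detections",
    "pr_curve_ap",
    "evaluate",
    "brute_force_ap",
]


@dataclass
class MatchResult:
    """Per-detection TP/FP flags (in descending score order) and per-gt
    matched flags for one image."""

    detection_is_tp: np.ndarray  # bool, aligned with sorted detections
    detection_scores: np.ndarray  # sorted descending
    gt_matched: np.ndarray
    threshold: float
    criterion: str

    @property
    def n_tp(self) -> int:
        return int(self.detection_is_tp.sum())

    @property
    def n_fn(self) -> int:
        return int((~self.gt_matched).sum())


@dataclass
class PRCurve:
    scores: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    ap: float


@dataclass
class EvalSummary:
    """AP per (criterion, threshold) and per subset, with counts."""

    results: dict = field(default_factory=dict)
    n_images: int = 0
    n_gts: int = 0
    n_detections: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_images": self.n_images,
                "n_gts": self.n_gts,
                "n_detections": self.n_detections,
                "results": self.results,
            },
            indent=2,
        )


def _overlap(
    det_row: np.ndarray, gts: np.ndarray, criterion: str
) -> np.ndarray:
    if criterion == "iou":
        return skew_iou_one_to_many(det_row, gts)
    if criterion == "iof":
        inter = intersection_areas_one_to_many(det_row, gts)
        return inter / (det_row[2] * det_row[3])
    raise ValueError(f"unknown criterion {criterion!r}; expected 'iou' or 'iof'")


def match_detections(
    det_boxes: Sequence[RotatedBox] | np.ndarray,
    det_scores: Sequence[float] | np.ndarray,
    gt_boxes: Sequence[RotatedBox] | np.ndarray,
    threshold: float,
    criterion: str = "iou",
) -> MatchResult:
    """Greedy single-image matching.

    Detections are processed in descending score order (ties by original
    index); each claims its highest-overlap unmatched ground truth if the
    overlap meets the threshold (gt ties broken by index). Ground truths
    match at most once; leftover detections are FP, leftover gts FN.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    dets = (
        np.asarray(det_boxes, dtype=float).reshape(-1, 5)
        if isinstance(det_boxes, np.ndarray)
        else boxes_to_array(det_boxes)
    )
    gts = (
        np.asarray(gt_boxes, dtype=float).reshape(-1, 5)
        if isinstance(gt_boxes, np.ndarray)
        else boxes_to_array(gt_boxes)
    )
    scores = np.asarray(det_scores, dtype=float)
    if len(dets) != len(scores):
        raise ValueError("detections and scores length mismatch")
    order = np.argsort(-scores, kind="stable")
    gt_matched = np.zeros(len(gts), dtype=bool)
    is_tp = np.zeros(len(dets), dtype=bool)
    for rank, di in enumerate(order):
        if len(gts) == 0:
            break
        ov = _overlap(dets[di], gts, criterion)
        ov = np.where(gt_matched, -1.0, ov)
        best = int(np.argmax(ov))
        if ov[best] >= threshold:
            gt_matched[best] = True
            is_tp[rank] = True
    return MatchResult(
        detection_is_tp=is_tp,
        detection_scores=scores[order],
        gt_matched=gt_matched,
        threshold=threshold,
        criterion=criterion,
    )


def _envelope_ap(precision: np.ndarray, recall: np.ndarray) -> float:
    """Area under the monotone precision envelope vs recall
    (all-points interpolation)."""
    p = np.concatenate([[0.0], precision, [0.0]])
    r = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    steps = np.nonzero(np.diff(r) > 0)[0]
    return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))


def _eleven_point_ap(precision: np.ndarray, recall: np.ndarray) -> float:
    total = 0.0
    for t in np.linspace(0, 1, 11):
        mask = recall >= t
        total += precision[mask].max() if mask.any() else 0.0
    return total / 11.0


def pr_curve_ap(
    matches: Iterable[MatchResult], eleven_point: bool = False
) -> PRCurve:
    """Pool per-image matches into one dataset-level PR curve and its AP.

    All detections are merged and sorted by score; cumulative TP/FP counts
    against the total ground-truth count give (P, R) at every distinct
    score threshold.
    """
    matches = list(matches)
    n_gt = sum(len(m.gt_matched) for m in matches)
    if n_gt == 0:
        raise ValueError("AP undefined without ground-truth instances")
    scores = np.concatenate([m.detection_scores for m in matches]) if matches else np.zeros(0)
    flags = np.concatenate([m.detection_is_tp for m in matches]) if matches else np.zeros(0, bool)
    if len(scores) == 0:
        return PRCurve(scores=scores, precision=np.zeros(0), recall=np.zeros(0), ap=0.0)
    order = np.argsort(-scores, kind="stable")
    scores = scores[order]
    flags = flags[order]
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    precision = tp / (tp + fp)
    recall = tp / n_gt
    ap = _eleven_point_ap(precision, recall) if eleven_point else _envelope_ap(precision, recall)
    return PRCurve(scores=scores, precision=precision, recall=recall, ap=ap)


def brute_force_ap(
    per_image: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    threshold: float,
    criterion: str = "iou",
) -> float:
    """Independent AP evaluator: re-matches from scratch at every distinct
    score cutoff and integrates the resulting staircase exactly.

    ``per_image`` holds (det_boxes, det_scores, gt_boxes) triples. Slow by
    construction; used as the oracle in tests.
    """
    n_gt = sum(len(g) for _, _, g in per_image)
    if n_gt == 0:
        raise ValueError("AP undefined without ground-truth instances")
    all_scores = np.concatenate([s for _, s, _ in per_image]) if per_image else np.zeros(0)
    if len(all_scores) == 0:
        return 0.0
    cutoffs = np.unique(all_scores)[::-1]
    points = []
    for cut in cutoffs:
        tp = fp = 0
        for dets, scores, gts in per_image:
            keep = scores >= cut
            m = match_detections(dets[keep], scores[keep], gts, threshold, criterion)
            tp += m.n_tp
            fp += int((~m.detection_is_tp).sum())
        if tp + fp == 0:
            continue
        points.append((tp / n_gt, tp / (tp + fp)))
    points.sort()
    ap = 0.0
    prev_r = 0.0
    # integrate with the precision envelope, as in the fast path
    rs = np.array([r for r, _ in points])
    ps = np.array([p for _, p in points])
    for i in range(len(ps) - 2, -1, -1):
        ps[i] = max(ps[i], ps[i + 1])
    for r, p in zip(rs, ps):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def evaluate(
    gt_records: Sequence[AnnotationRecord],
    detections: Mapping[str, Sequence[tuple[RotatedBox, float]]],
    thresholds: Sequence[float] = (0.5, 0.75),
    criteria: Sequence[str] = ("iou", "iof"),
    subsets: bool = True,
    eleven_point: bool = False,
) -> EvalSummary:
    """Dataset-level AP report.

    ``detections`` maps image_id to (box, score) pairs; every detection
    image_id must exist among the ground-truth records. APs are computed
    per (criterion, threshold) on the full set and, optionally, per
    density subset.
    """
    gt_ids = {r.image_id for r in gt_records}
    stray = sorted(set(detections) - gt_ids)
    if stray:
        raise ValueError(f"detections reference unknown image ids: {stray}")

    per_image: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for rec in gt_records:
        pairs = detections.get(rec.image_id, [])
        dets = boxes_to_array([b for b, _ in pairs])
        scores = np.array([s for _, s in pairs], dtype=float)
        per_image[rec.image_id] = (dets, scores, boxes_to_array(rec.instances))

    labels = split_subsets(gt_records) if subsets else {}
    groups: dict[str, list[str]] = {"all": [r.image_id for r in gt_records]}
    if subsets:
        for name in ("sparse", "medium", "dense"):
            ids = [i for i, lab in labels.items() if lab == name]
            if ids:
                groups[name] = ids

    summary = EvalSummary(
        n_images=len(gt_records),
        n_gts=sum(len(v[2]) for v in per_image.values()),
        n_detections=sum(len(v[1]) for v in per_image.values()),
    )
    for criterion in criteria:
        for thr in thresholds:
            for group, ids in groups.items():
                matches = [
                    match_detections(*per_image[i][:2], per_image[i][2], thr, criterion)
                    for i in ids
                ]
                if sum(len(m.gt_matched) for m in matches) == 0:
                    continue
                curve = pr_curve_ap(matches, eleven_point=eleven_point)
                summary.results.setdefault(criterion, {}).setdefault(
                    f"{thr:g}", {}
                )[group] = {
                    "ap": curve.ap,
                    "n_images": len(ids),
                    "precision": curve.precision.tolist(),
                    "recall": curve.recall.tolist(),
                }
    return summary
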