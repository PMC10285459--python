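"""Delta coding between rotated boxes and anchors, and the detection loss.

A target box is regressed relative to an anchor (or, in the second stage, a
proposal) through the five offsets

    d_x = (x_t - x_a) / w_a        d_y = (y_t - y_a) / h_a
    d_w = log(w_t / w_a)           d_h = log(h_t / h_a)
    d_theta = theta_t - theta_a

Decoding inverts these and then wraps the angle back into the long-edge
range via ``theta = (d_theta + theta_a + pi/4) % pi - pi/4``, followed by
canonicalization.

The training loss is the classification cross-entropy over all ``N``
sampled anchors plus the smooth-L1 regression penalty over the ``Np``
positives, with a *shared* ``1/N`` normalization:

    L = (sum_N CE + sum_Np sum_{x,y,w,h,theta} smoothL1(d_gt - d_dt)) / N

Note the single 1/N factor applies to both sums (most detection frameworks
normalize the regression term by Np instead; here the combined form is
used as specified).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import RotatedBox, canonicalize, normalize_angle

__all__ = [
    "DeltaVector",
    "LossBreakdown",
    "encode_deltas",
    "decode_deltas",
    "encode_batch",
    "decode_batch",
    "smooth_l1",
    "binary_cross_entropy",
    "detection_loss",
]

# decoded edges beyond this many pixels are clamped (runaway exp(d_w))
MAX_DECODED_EDGE = 1e6


@dataclass(frozen=True)
class DeltaVector:
    d_x: float
    d_y: float
    d_w: float
    d_h: float
    d_theta: float

    def asarray(self) -> np.ndarray:
        return np.array([self.d_x, self.d_y, self.d_w, self.d_h, self.d_theta])


@dataclass(frozen=True)
class LossBreakdown:
    """Total loss with its components; ``total = (cls_sum + reg_sum) / n``."""

    total: float
    classification: float  # sum of CE terms (unnormalized)
    regression: float  # sum of smooth-L1 terms (unnormalized)
    n: int
    n_pos: int


def encode_deltas(
    target: RotatedBox, anchor: RotatedBox, wrap_angle: bool = False
) -> DeltaVector:
    """Offsets of ``target`` relative to ``anchor``.

    ``wrap_angle=True`` additionally wraps d_theta into (-pi/2, pi/2] so a
    target aliased across the angular boundary is regressed the short way
    round; the default keeps the raw difference.
    """
    d_theta = target.theta - anchor.theta
    if wrap_angle:
        d_theta = math.remainder(d_theta, math.pi)
        if d_theta <= -math.pi / 2:
            d_theta += math.pi
    return DeltaVector(
        d_x=(target.x - anchor.x) / anchor.w,
        d_y=(target.y - anchor.y) / anchor.h,
        d_w=math.log(target.w / anchor.w),
        d_h=math.log(target.h / anchor.h),
        d_theta=d_theta,
    )


def decode_deltas(delta: DeltaVector, anchor: RotatedBox) -> RotatedBox:
    """Inverse of :func:`encode_deltas` with angle normalization.

    The decoded angle is wrapped into [-pi/4, 3pi/4) and the box
    canonicalized. Edges decoding beyond ``MAX_DECODED_EDGE`` pixels are
    clamped with a warning.
    """
    arr = delta.asarray()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite deltas: {delta}")
    w = anchor.w * math.exp(delta.d_w)
    h = anchor.h * math.exp(delta.d_h)
    if w > MAX_DECODED_EDGE or h > MAX_DECODED_EDGE:
        warnings.warn("decoded edge exceeds clamp; clipping", stacklevel=2)
        w = min(w, MAX_DECODED_EDGE)
        h = min(h, MAX_DECODED_EDGE)
    theta = normalize_angle(delta.d_theta + anchor.theta)
    return canonicalize(
        anchor.x + delta.d_x * anchor.w,
        anchor.y + delta.d_y * anchor.h,
        w,
        h,
        theta,
    )


def encode_batch(targets: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Vectorized :func:`encode_deltas` on (N, 5) arrays."""
    targets = np.asarray(targets, dtype=float).reshape(-1, 5)
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 5)
    out = np.empty_like(targets)
    out[:, 0] = (targets[:, 0] - anchors[:, 0]) / anchors[:, 2]
    out[:, 1] = (targets[:, 1] - anchors[:, 1]) / anchors[:, 3]
    out[:, 2] = np.log(targets[:, 2] / anchors[:, 2])
    out[:, 3] = np.log(targets[:, 3] / anchors[:, 3])
    out[:, 4] = targets[:, 4] - anchors[:, 4]
    return out


def decode_batch(
    deltas: np.ndarray, anchors: np.ndarray, max_edge: float = MAX_DECODED_EDGE
) -> np.ndarray:
    """Vectorized :func:`decode_deltas`; output rows are canonical
    long-edge parameters."""
    deltas = np.asarray(deltas, dtype=float).reshape(-1, 5)
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 5)
    x = anchors[:, 0] + deltas[:, 0] * anchors[:, 2]
    y = anchors[:, 1] + deltas[:, 1] * anchors[:, 3]
    w = anchors[:, 2] * np.exp(np.clip(deltas[:, 2], -20, 20))
    h = anchors[:, 3] * np.exp(np.clip(deltas[:, 3], -20, 20))
    w = np.minimum(w, max_edge)
    h = np.minimum(h, max_edge)
    # enforce positive edges and the long-edge convention
    w = np.maximum(w, 1e-4)
    h = np.maximum(h, 1e-4)
    theta = deltas[:, 4] + anchors[:, 4]
    swap = w < h
    w2 = np.where(swap, h, w)
    h2 = np.where(swap, w, h)
    theta = np.where(swap, theta + math.pi / 2, theta)
    theta = (theta + math.pi / 4) % math.pi - math.pi / 4
    return np.stack([x, y, w2, h2, theta], axis=1)


def smooth_l1(x: float | np.ndarray) -> float | np.ndarray:
    """Huber-style penalty: 0.5 x^2 for |x| < 1, |x| - 0.5 otherwise."""
    ax = np.abs(x)
    out = np.where(ax < 1.0, 0.5 * np.square(x), ax - 0.5)
    return float(out) if np.isscalar(x) else out


def binary_cross_entropy(
    probs: np.ndarray, targets: np.ndarray, eps: float = 1e-12
) -> np.ndarray:
    """Elementwise CE between foreground probabilities and 0/1 labels."""
    p = np.clip(np.asarray(probs, dtype=float), eps, 1.0 - eps)
    t = np.asarray(targets, dtype=float)
    return -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))


def detection_loss(
    class_probs: np.ndarray,
    class_targets: np.ndarray,
    pred_deltas: np.ndarray,
    target_deltas: np.ndarray,
) -> LossBreakdown:
    """Combined detection loss over one sampled batch.

    ``class_probs``/``class_targets`` cover all N samples; the delta pairs
    cover the Np positives only (Np <= N). Both sums share the single 1/N
    factor.
    """
    class_probs = np.asarray(class_probs, dtype=float).ravel()
    class_targets = np.asarray(class_targets, dtype=float).ravel()
    if class_probs.shape != class_targets.shape:
        raise ValueError("classification terms must align")
    n = len(class_probs)
    pred_deltas = np.asarray(pred_deltas, dtype=float).reshape(-1, 5)
    target_deltas = np.asarray(target_deltas, dtype=float).reshape(-1, 5)
    if pred_deltas.shape != target_deltas.shape:
        raise ValueError("delta arrays must align")
    n_pos = len(pred_deltas)
    if n_pos > n:
        raise ValueError(f"Np={n_pos} exceeds N={n}")
    if n == 0:
        raise ValueError("empty batch")
    cls_sum = float(binary_cross_entropy(class_probs, class_targets).sum())
    reg_sum = float(smooth_l1(target_deltas - pred_deltas).sum())
    return LossBreakdown(
        total=(cls_sum + reg_sum) / n,
        classification=cls_sum,
        regression=reg_sum,
        n=n,
        n_pos=n_pos,
    )
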