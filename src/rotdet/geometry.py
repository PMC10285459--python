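"""Rotated-box algebra.

The universal geometric currency of this package is the *long-edge* rotated
box: a rectangle parameterised by its center ``(x, y)``, its long edge ``w``,
its short edge ``h`` (``w >= h``) and the angle ``theta`` between the long
edge and the image x-axis. Image coordinates have the origin at the top-left
corner with y growing downward; clockwise angles (as seen on screen) are
positive. ``theta`` lives in the half-open interval ``[-pi/4, 3*pi/4)``,
whose period is ``pi`` because a rectangle is invariant under a half turn.

Overlap between two rotated boxes is computed exactly: the convex
intersection polygon is obtained by Sutherland-Hodgman clipping of one
corner quadrilateral against the other, and its area by the shoelace
formula. This equals the triangular-dissection value over the intersection
points and drives skew IoU, skew IoF and rotated non-maximum suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RotatedBox",
    "HorizontalBox",
    "normalize_angle",
    "canonicalize",
    "rbox_to_corners",
    "corners_to_rbox",
    "circumscribed_hbb",
    "convex_intersection_area",
    "skew_iou",
    "skew_iof",
    "rotated_nms",
    "hbb_iou",
    "boxes_to_array",
    "array_to_boxes",
    "corners_batch",
    "intersection_areas_one_to_many",
    "skew_iou_one_to_many",
]

# Boxes thinner than this are rejected at construction: the annotation tool
# and the detector should never produce degenerate rectangles, and the
# clipping code assumes positive area.
_MIN_EDGE = 1e-6
# Collinearity tolerance used when validating corner quads.
_RECT_TOL = 1e-6

_QUARTER_PI = math.pi / 4.0


def normalize_angle(theta: float) -> float:
    """Wrap an angle into the long-edge range ``[-pi/4, 3*pi/4)``.

    The result is congruent to ``theta`` modulo ``pi`` (the symmetry period
    of a rectangle). Mirrors the closing normalisation of the proposal
    decoder: ``theta = (d_theta + theta_a + pi/4) % pi - pi/4``.
    """
    theta = float(theta)
    if not math.isfinite(theta):
        raise ValueError(f"angle must be finite, got {theta!r}")
    return (theta + _QUARTER_PI) % math.pi - _QUARTER_PI


def _normalize_angle_arr(theta: np.ndarray) -> np.ndarray:
    return (theta + _QUARTER_PI) % math.pi - _QUARTER_PI


@dataclass(frozen=True)
class RotatedBox:
    """Long-edge rotated box: center, long edge, short edge, angle.

    Invariants (enforced at construction): ``w >= h > 0`` and
    ``theta in [-pi/4, 3*pi/4)``. Use :func:`canonicalize` to build a box
    from unconstrained ``(x, y, w, h, theta)`` parameters.
    """

    x: float
    y: float
    w: float
    h: float
    theta: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h", "theta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"RotatedBox.{name} must be finite, got {v!r}")
        if self.w < _MIN_EDGE or self.h < _MIN_EDGE:
            raise ValueError(
                f"degenerate box: edges ({self.w}, {self.h}) below {_MIN_EDGE}"
            )
        if self.w < self.h:
            raise ValueError(
                f"long-edge convention violated: w={self.w} < h={self.h}; "
                "use canonicalize()"
            )
        if not (-_QUARTER_PI <= self.theta < 3 * _QUARTER_PI):
            raise ValueError(
                f"theta={self.theta} outside [-pi/4, 3pi/4); use canonicalize()"
            )

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def aspect_ratio(self) -> float:
        """Long edge over short edge, always >= 1."""
        return self.w / self.h

    def astuple(self) -> tuple[float, float, float, float, float]:
        return (self.x, self.y, self.w, self.h, self.theta)


@dataclass(frozen=True)
class HorizontalBox:
    """Axis-aligned box given by top-left and bottom-right corners."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(
                f"HorizontalBox requires x1<x2 and y1<y2, got "
                f"({self.x1},{self.y1},{self.x2},{self.y2})"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)


def canonicalize(x: float, y: float, w: float, h: float, theta: float) -> RotatedBox:
    """Build a :class:`RotatedBox` from unconstrained parameters.

    If ``w < h`` the edges are swapped and the angle rotated by ``pi/2`` —
    the same rectangle re-described with its long edge first — and the angle
    is then wrapped into ``[-pi/4, 3*pi/4)``.
    """
    if not (w > 0 and h > 0):
        raise ValueError(f"edges must be positive, got w={w}, h={h}")
    if w < h:
        w, h = h, w
        theta = theta + math.pi / 2.0
    return RotatedBox(float(x), float(y), float(w), float(h), normalize_angle(theta))


def rbox_to_corners(b: RotatedBox) -> np.ndarray:
    """Corner quadrilateral of ``b`` as a (4, 2) array.

    Corners are ``center + R(theta) @ (±w/2, ±h/2)`` in the fixed order
    (-w/2,-h/2), (+w/2,-h/2), (+w/2,+h/2), (-w/2,+h/2), which winds
    clockwise on screen (y down). The shoelace area equals ``w*h``.
    """
    c, s = math.cos(b.theta), math.sin(b.theta)
    hw, hh = b.w / 2.0, b.h / 2.0
    local = np.array([(-hw, -hh), (hw, -hh), (hw, hh), (-hw, hh)])
    rot = np.array([(c, -s), (s, c)])
    return local @ rot.T + np.array([b.x, b.y])


def corners_to_rbox(quad: Sequence[Sequence[float]] | np.ndarray) -> RotatedBox:
    """Recover the rotated box whose corners are ``quad`` (any starting vertex).

    Raises ``ValueError`` if the four points do not form a rectangle within
    a relative tolerance of 1e-6.
    """
    q = np.asarray(quad, dtype=float)
    if q.shape != (4, 2):
        raise ValueError(f"expected four 2-D vertices, got shape {q.shape}")
    e1 = q[1] - q[0]
    e2 = q[2] - q[1]
    scale = max(np.linalg.norm(e1), np.linalg.norm(e2))
    if scale <= 0:
        raise ValueError("degenerate quad")
    if abs(float(np.dot(e1, e2))) > _RECT_TOL * scale * scale:
        raise ValueError("corners do not form a rectangle (adjacent edges not orthogonal)")
    if np.max(np.abs((q[3] - q[2]) + e1)) > _RECT_TOL * scale or np.max(
        np.abs((q[0] - q[3]) + e2)
    ) > _RECT_TOL * scale:
        raise ValueError("corners do not form a rectangle (opposite edges differ)")
    cx, cy = q.mean(axis=0)
    w0 = float(np.linalg.norm(e1))
    h0 = float(np.linalg.norm(e2))
    theta0 = math.atan2(e1[1], e1[0])
    return canonicalize(cx, cy, w0, h0, theta0)


def circumscribed_hbb(b: RotatedBox) -> HorizontalBox:
    """Smallest axis-aligned box containing ``b`` (min/max over corners)."""
    q = rbox_to_corners(b)
    x1, y1 = q.min(axis=0)
    x2, y2 = q.max(axis=0)
    return HorizontalBox(float(x1), float(y1), float(x2), float(y2))


# ---------------------------------------------------------------------------
# Convex polygon clipping (Sutherland-Hodgman) and shoelace areas
# ---------------------------------------------------------------------------

def _shoelace_area(poly: np.ndarray) -> float:
    if len(poly) < 3:
        return 0.0
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _clip_polygon(subject: np.ndarray, clip_quad: np.ndarray) -> np.ndarray:
    """Clip a convex polygon against a convex quad (both CCW in math frame)."""
    out = subject
    n_clip = len(clip_quad)
    for i in range(n_clip):
        if len(out) == 0:
            break
        a = clip_quad[i]
        b = clip_quad[(i + 1) % n_clip]
        edge = b - a
        # signed side: >= 0 keeps (interior for CCW winding)
        d = (out[:, 0] - a[0]) * edge[1] - (out[:, 1] - a[1]) * edge[0]
        d = -d  # interior of CCW polygon is left of edge: cross(edge, p-a) >= 0
        new_pts: list[np.ndarray] = []
        m = len(out)
        for j in range(m):
            k = (j + 1) % m
            pj, pk = out[j], out[k]
            dj, dk = d[j], d[k]
            if dj >= 0:
                new_pts.append(pj)
            if (dj > 0 and dk < 0) or (dj < 0 and dk > 0):
                t = dj / (dj - dk)
                new_pts.append(pj + t * (pk - pj))
        out = np.array(new_pts) if new_pts else np.empty((0, 2))
    return out


def _ccw(quad: np.ndarray) -> np.ndarray:
    """Reorient a quad to positive (counter-clockwise) shoelace sign."""
    x, y = quad[:, 0], quad[:, 1]
    signed = float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return quad if signed >= 0 else quad[::-1]


def convex_intersection_area(a: RotatedBox, b: RotatedBox) -> float:
    """Area of the convex intersection polygon of two rotated boxes.

    Symmetric in its arguments; zero for disjoint boxes and for degenerate
    contact along a shared edge or vertex. The argument pair is ordered
    canonically before clipping so the result is bitwise symmetric.
    """
    if b.astuple() < a.astuple():
        a, b = b, a
    qa = _ccw(rbox_to_corners(a))
    qb = _ccw(rbox_to_corners(b))
    # cheap reject via circumscribed extents
    if (
        qa[:, 0].max() <= qb[:, 0].min()
        or qb[:, 0].max() <= qa[:, 0].min()
        or qa[:, 1].max() <= qb[:, 1].min()
        or qb[:, 1].max() <= qa[:, 1].min()
    ):
        return 0.0
    return _shoelace_area(_clip_polygon(qa, qb))


def skew_iou(a: RotatedBox, b: RotatedBox) -> float:
    """Intersection over union on rotated boxes via exact polygon dissection."""
    inter = convex_intersection_area(a, b)
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def skew_iof(det: RotatedBox, gt: RotatedBox) -> float:
    """Intersection over foreground: overlap area divided by the detection's area.

    Asymmetric and never smaller than :func:`skew_iou` for the same pair;
    forgiving toward detections that cover only part of a truncated symptom.
    """
    return convex_intersection_area(det, gt) / det.area


def hbb_iou(a: HorizontalBox, b: HorizontalBox) -> float:
    """Plain axis-aligned IoU (used for horizontal-baseline comparisons)."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# Array-based helpers (hot paths: NMS, anchor assignment, proposal filtering)
# ---------------------------------------------------------------------------

def boxes_to_array(boxes: Iterable[RotatedBox]) -> np.ndarray:
    """Stack boxes into an (N, 5) float array of (x, y, w, h, theta)."""
    arr = np.array([b.astuple() for b in boxes], dtype=float)
    return arr.reshape(-1, 5)


def array_to_boxes(arr: np.ndarray) -> list[RotatedBox]:
    """Inverse of :func:`boxes_to_array`, canonicalizing each row."""
    return [canonicalize(*row) for row in np.asarray(arr, dtype=float)]


def corners_batch(arr: np.ndarray) -> np.ndarray:
    """Corners of (N, 5) box parameters as an (N, 4, 2) array (same order
    as :func:`rbox_to_corners`)."""
    arr = np.asarray(arr, dtype=float).reshape(-1, 5)
    x, y, w, h, t = arr.T
    c, s = np.cos(t), np.sin(t)
    hw, hh = w / 2.0, h / 2.0
    lx = np.stack([-hw, hw, hw, -hw], axis=1)
    ly = np.stack([-hh, -hh, hh, hh], axis=1)
    cx = c[:, None] * lx - s[:, None] * ly + x[:, None]
    cy = s[:, None] * lx + c[:, None] * ly + y[:, None]
    return np.stack([cx, cy], axis=2)


def intersection_areas_one_to_many(box: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Intersection areas between one box and N others, vectorised.

    ``box`` is a length-5 parameter vector, ``others`` an (N, 5) array.
    Clips every subject quad against the four half-planes of ``box``
    simultaneously; a convex quad clipped by a convex quad has at most
    eight vertices, so fixed-capacity buffers suffice.
    """
    others = np.asarray(others, dtype=float).reshape(-1, 5)
    n = len(others)
    if n == 0:
        return np.zeros(0)
    clip = _ccw(rbox_to_corners(RotatedBox(*canonicalize(*box).astuple())))
    subj = corners_batch(others)  # (N, 4, 2); winding already CCW (math frame)

    cap = 8
    poly = np.zeros((n, cap, 2))
    poly[:, :4] = subj
    count = np.full(n, 4, dtype=int)
    idx = np.arange(n)

    for i in range(4):
        a = clip[i]
        b = clip[(i + 1) % 4]
        ex, ey = b - a
        # interior (left of CCW edge): cross(edge, p - a) >= 0
        d = ex * (poly[..., 1] - a[1]) - ey * (poly[..., 0] - a[0])
        new_poly = np.zeros_like(poly)
        new_count = np.zeros_like(count)
        first = poly[:, 0]
        d_first = d[:, 0]
        for j in range(cap):
            active = j < count
            if not active.any():
                break
            wrap = (j + 1 >= count)[:, None]
            pj = poly[:, j]
            dj = d[:, j]
            if j + 1 < cap:
                pk = np.where(wrap, first, poly[:, j + 1])
                dk = np.where(wrap[:, 0], d_first, d[:, j + 1])
            else:
                pk, dk = first, d_first
            keep = active & (dj >= 0)
            rows = idx[keep]
            new_poly[rows, new_count[rows]] = pj[keep]
            new_count[rows] += 1
            crossing = active & (((dj > 0) & (dk < 0)) | ((dj < 0) & (dk > 0)))
            rows = idx[crossing]
            t = (dj[crossing] / (dj[crossing] - dk[crossing]))[:, None]
            new_poly[rows, new_count[rows]] = pj[crossing] + t * (pk[crossing] - pj[crossing])
            new_count[rows] += 1
        poly, count = new_poly, new_count

    # shoelace over ragged rows (wrap each row at its own vertex count)
    area = np.zeros(n)
    first = poly[:, 0]
    for j in range(cap):
        active = j < count
        if not active.any():
            break
        wrap = (j + 1 >= count)[:, None]
        pj = poly[:, j]
        pk = np.where(wrap, first, poly[:, min(j + 1, cap - 1)])
        contrib = pj[:, 0] * pk[:, 1] - pk[:, 0] * pj[:, 1]
        area[active] += contrib[active]
    area = 0.5 * np.abs(area)
    area[count < 3] = 0.0
    return area


def skew_iou_one_to_many(box: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Skew IoU between one (5,) box and an (N, 5) array of boxes."""
    others = np.asarray(others, dtype=float).reshape(-1, 5)
    inter = intersection_areas_one_to_many(box, others)
    area_box = float(box[2]) * float(box[3])
    areas = others[:, 2] * others[:, 3]
    union = area_box + areas - inter
    out = np.zeros(len(others))
    ok = union > 0
    out[ok] = inter[ok] / union[ok]
    return out


def rotated_nms(
    boxes: Sequence[RotatedBox] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
    iou_threshold: float,
    max_keep: int | None = None,
) -> list[int]:
    """Greedy rotated non-maximum suppression.

    Processes boxes by descending score (ties broken by ascending original
    index), suppressing any remaining box whose skew IoU with the kept box
    exceeds ``iou_threshold``. Returns kept indices in descending-score
    order; idempotent on its own output. ``max_keep`` stops the sweep once
    that many survivors exist (identical to truncating the full result).

    Pairs whose axis-aligned extents do not overlap have zero IoU and are
    skipped before the polygon clipper runs.
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must be in [0,1], got {iou_threshold}")
    if isinstance(boxes, np.ndarray):
        arr = np.asarray(boxes, dtype=float).reshape(-1, 5)
    else:
        arr = boxes_to_array(boxes)
    scores = np.asarray(scores, dtype=float)
    if len(arr) != len(scores):
        raise ValueError("boxes and scores length mismatch")
    if len(arr) == 0:
        return []
    corners = corners_batch(arr)
    lo = corners.min(axis=1)  # (N, 2)
    hi = corners.max(axis=1)
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    while order.size > 0:
        top = int(order[0])
        keep.append(top)
        if max_keep is not None and len(keep) >= max_keep:
            break
        rest = order[1:]
        if rest.size == 0:
            break
        touching = np.all(lo[rest] < hi[top], axis=1) & np.all(
            hi[rest] > lo[top], axis=1
        )
        ious = np.zeros(rest.size)
        if touching.any():
            ious[touching] = skew_iou_one_to_many(arr[top], arr[rest[touching]])
        order = rest[ious <= iou_threshold]
    return keep
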