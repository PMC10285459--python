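import math

import numpy as np
import pytest

from rotdet.geometry import RotatedBox, canonicalize


def random_rbox(rng: np.random.Generator, *, span: float = 100.0,
                edge_lo: float = 2.0, edge_hi: float = 60.0,
                min_aspect: float = 1.0) -> RotatedBox:
    """Random long-edge box with edges in [edge_lo, edge_hi]."""
    w = rng.uniform(edge_lo * min_aspect, edge_hi)
    h = rng.uniform(edge_lo, min(edge_hi, w / min_aspect))
    x, y = rng.uniform(0, span, size=2)
    theta = rng.uniform(-math.pi, math.pi)
    return canonicalize(x, y, max(w, h), min(w, h), theta)


def points_inside(box: RotatedBox, pts: np.ndarray) -> np.ndarray:
    """Membership test used by the rasterization oracle: a point is inside a
    rotated box iff its coordinates in the box's local frame fall within
    [-w/2, w/2] x [-h/2, h/2]."""
    c, s = math.cos(box.theta), math.sin(box.theta)
    dx = pts[:, 0] - box.x
    dy = pts[:, 1] - box.y
    lx = c * dx + s * dy
    ly = -s * dx + c * dy
    return (np.abs(lx) <= box.w / 2) & (np.abs(ly) <= box.h / 2)


def mc_skew_iou(a: RotatedBox, b: RotatedBox, rng: np.random.Generator,
                n: int = 1_000_000) -> float:
    """Monte-Carlo rasterization estimate of skew IoU: uniform samples over
    the joint axis-aligned extent, IoU = P(in both) / P(in either)."""
    from rotdet.geometry import rbox_to_corners

    qa = rbox_to_corners(a)
    qb = rbox_to_corners(b)
    lo = np.minimum(qa.min(axis=0), qb.min(axis=0))
    hi = np.maximum(qa.max(axis=0), qb.max(axis=0))
    pts = rng.uniform(lo, hi, size=(n, 2))
    in_a = points_inside(a, pts)
    in_b = points_inside(b, pts)
    either = int(np.count_nonzero(in_a | in_b))
    both = int(np.count_nonzero(in_a & in_b))
    return both / either if either else 0.0


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230608)
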