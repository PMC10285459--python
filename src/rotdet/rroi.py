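"""Rotated region-of-interest alignment.

A rotated proposal ``(x_p, y_p, w_p, h_p, theta)`` is first projected onto
a feature map of stride ``s``:

    w_f = w_p / s,  h_f = h_p / s,  x_f = floor(x_p / s),  y_f = floor(y_p / s)

(the centers are floored; the ≤0.5-cell quantization this introduces can be
disabled with ``floor_centers=False`` for ablation). The projected region
is then pooled into a ``k x k`` grid: bin ``(m, n)`` draws ``l`` sample
points at sub-bin centers in the proposal's local frame
``[0, w_f] x [0, h_f]``, maps each through

    R_theta(x, y) = [[cos t, -sin t], [sin t, cos t]] @ (x - w_f/2, y - h_f/2) + (x_f, y_f)

reads the feature map by bilinear interpolation (cell centers at integer
coordinates, zero padding outside the map), and averages. The first pooled
axis (``m``) runs along the proposal's long edge.

A horizontal RoIAlign with the identical sampling scheme is provided as
the axis-aligned baseline; for ``theta = 0`` and ``s = 1`` the two
operators agree to numerical precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import HorizontalBox, RotatedBox, canonicalize

__all__ = [
    "FeatureMap",
    "PooledRegion",
    "project_proposal",
    "rroi_align",
    "hroi_align",
    "sampling_points",
    "bilinear_sample",
]


@dataclass
class FeatureMap:
    """C x H x W activations at a given pixel stride."""

    values: np.ndarray
    stride: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected C x H x W array, got shape {self.values.shape}")
        if self.stride <= 0:
            raise ValueError("stride must be positive")


@dataclass
class PooledRegion:
    """C x k x k pooled activations for one proposal."""

    values: np.ndarray
    proposal: RotatedBox
    k: int
    l: int


def project_proposal(
    p: RotatedBox, stride: float, floor_centers: bool = True
) -> RotatedBox:
    """Project a proposal from image coordinates to the feature frame.

    Edges are divided by the stride; centers are divided and floored
    (set ``floor_centers=False`` to keep continuous centers). The angle is
    unchanged.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    x = p.x / stride
    y = p.y / stride
    if floor_centers:
        x = math.floor(x)
        y = math.floor(y)
    return RotatedBox(
        float(x), float(y), max(p.w / stride, 1e-4), max(p.h / stride, 1e-4), p.theta
    )


def _sub_centers(k: int, l: int) -> tuple[np.ndarray, int]:
    root = int(round(math.sqrt(l)))
    if root * root != l:
        raise ValueError(f"l must be a perfect square (got {l})")
    # fractional positions of the l sub-bin centers within one bin
    frac = (np.arange(root) + 0.5) / root
    return frac, root


def sampling_points(region: RotatedBox, k: int, l: int) -> np.ndarray:
    """Feature-frame sample coordinates, shaped (k, k, l, 2).

    ``out[m, n, j]`` is the j-th sample of bin (m, n); m runs along the
    region's long edge, n along its short edge.
    """
    if k < 1 or l < 1:
        raise ValueError("k and l must be >= 1")
    frac, root = _sub_centers(k, l)
    wf, hf = region.w, region.h
    # local coordinates in [0, wf] x [0, hf]
    lx = (np.arange(k)[:, None] + frac[None, :]) * (wf / k)  # (k, root)
    ly = (np.arange(k)[:, None] + frac[None, :]) * (hf / k)
    c, s = math.cos(region.theta), math.sin(region.theta)
    gx = lx[:, None, :, None] - wf / 2.0  # (k, 1, root, 1)
    gy = ly[None, :, None, :] - hf / 2.0  # (1, k, 1, root)
    px = c * gx - s * gy + region.x
    py = s * gx + c * gy + region.y
    pts = np.stack(
        [np.broadcast_to(px, (k, k, root, root)),
         np.broadcast_to(py, (k, k, root, root))], axis=-1
    )
    return pts.reshape(k, k, l, 2)


def bilinear_sample(values: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a C x H x W array at (..., 2) points
    given as (x, y); zero padding outside the map."""
    c_dim, h, w = values.shape
    x = pts[..., 0]
    y = pts[..., 1]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    tx = x - x0
    ty = y - y0

    out = np.zeros((c_dim,) + x.shape)
    for dy in (0, 1):
        for dx in (0, 1):
            xi = x0 + dx
            yi = y0 + dy
            weight = (tx if dx else 1 - tx) * (ty if dy else 1 - ty)
            valid = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            xi_c = np.clip(xi, 0, w - 1)
            yi_c = np.clip(yi, 0, h - 1)
            vals = values[:, yi_c, xi_c]  # (C, ...)
            out += vals * (weight * valid)[None]
    return out


def rroi_align(
    feature: FeatureMap,
    proposal: RotatedBox,
    k: int = 7,
    l: int = 4,
    floor_centers: bool = True,
) -> PooledRegion:
    """Pool a rotated proposal (image coordinates) into a C x k x k grid."""
    region = project_proposal(proposal, feature.stride, floor_centers=floor_centers)
    pts = sampling_points(region, k, l)
    _, h, w = feature.values.shape
    xs, ys = pts[..., 0], pts[..., 1]
    if xs.max() < -1 or xs.min() > w or ys.max() < -1 or ys.min() > h:
        warnings.warn("proposal lies fully outside the feature map", stacklevel=2)
    sampled = bilinear_sample(feature.values, pts)  # (C, k, k, l)
    return PooledRegion(
        values=sampled.mean(axis=-1), proposal=proposal, k=k, l=l
    )


def hroi_align(
    feature: FeatureMap, box: HorizontalBox, k: int = 7, l: int = 4,
    floor_centers: bool = True,
) -> PooledRegion:
    """Axis-aligned RoIAlign baseline with the identical sampling scheme.

    The box is treated as a zero-angle region (long edge along x when
    width >= height); pooling follows the same projection and sub-bin
    center rules as :func:`rroi_align`.
    """
    cx = (box.x1 + box.x2) / 2.0
    cy = (box.y1 + box.y2) / 2.0
    w = box.width
    h = box.height
    region = project_proposal(
        canonicalize(cx, cy, max(w, h), max(min(w, h), 1e-4),
                     0.0 if w >= h else math.pi / 2),
        feature.stride, floor_centers=floor_centers,
    )
    pts = sampling_points(region, k, l)
    sampled = bilinear_sample(feature.values, pts)
    return PooledRegion(values=sampled.mean(axis=-1), proposal=region, k=k, l=l)
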