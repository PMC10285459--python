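"""Minimal reverse-mode autodiff and neural-network layers on NumPy.

This is a small, self-contained NN toolkit sized for the needs of this
package: defining the detector graph, counting its parameters, running CPU
inference, and training the reduced demo configuration end to end. It
supports exactly the operations the detector uses — single-image 2-D
convolution (im2col), max pooling, nearest-neighbour upsampling, dense
layers, ReLU/sigmoid, row gathering/stacking, the detection losses, and a
rotated-RoI pooling op whose gradient flows into the feature map.

Gradients are accumulated by a topological backward sweep over a dynamic
graph of :class:`Tensor` nodes. Everything is float64 and deterministic.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "Sequential",
    "SGD",
    "add",
    "relu",
    "sigmoid",
    "matmul",
    "conv2d",
    "maxpool2d",
    "upsample_nearest2",
    "gather_rows",
    "stack_rows",
    "bce_with_logits_sum",
    "softmax_ce_sum",
    "smooth_l1_sum",
    "scale",
]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> np.ndarray:
        return self.data

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)


def _op(
    data: np.ndarray, parents: tuple[Tensor, ...],
    backward: Callable[[np.ndarray], None],
) -> Tensor:
    needs = any(p.requires_grad for p in parents)
    return Tensor(data, parents=parents if needs else (),
                  backward=backward if needs else None)


def add(a: Tensor, b: Tensor) -> Tensor:
    def back(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return _op(a.data + b.data, (a, b), back)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def scale(a: Tensor, c: float) -> Tensor:
    def back(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g * c)

    return _op(a.data * c, (a,), back)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def back(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g * mask)

    return _op(a.data * mask, (a,), back)


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data))

    def back(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g * out * (1.0 - out))

    return _op(out, (a,), back)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def back(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    return _op(a.data @ b.data, (a, b), back)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = a.data.shape

    def back(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g.reshape(orig))

    return _op(a.data.reshape(shape), (a,), back)


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    inv = tuple(int(np.argsort(axes)[i]) for i in range(len(axes)))

    def back(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g.transpose(inv))

    return _op(a.data.transpose(axes), (a,), back)


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows of a 1-D or 2-D tensor; backward scatter-adds."""
    idx = np.asarray(idx, dtype=int)

    def back(g: np.ndarray) -> None:
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a.accumulate(full)

    return _op(a.data[idx], (a,), back)


def stack_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Stack equal-shape tensors along a new leading axis."""
    data = np.stack([t.data for t in tensors])

    def back(g: np.ndarray) -> None:
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t.accumulate(g[i])

    return _op(data, tuple(tensors), back)


# ---------------------------------------------------------------------------
# convolution / pooling on single images (C, H, W)
# ---------------------------------------------------------------------------

def _im2col_indices(
    c_in: int, h: int, w: int, kh: int, kw: int, stride: int, pad: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    h_out = (h + 2 * pad - kh) // stride + 1
    w_out = (w + 2 * pad - kw) // stride + 1
    k = np.arange(c_in * kh * kw)
    c_idx = k // (kh * kw)
    ky = (k // kw) % kh
    kx = k % kw
    oy, ox = np.meshgrid(np.arange(h_out), np.arange(w_out), indexing="ij")
    y_in = ky[:, None] + (oy.ravel() * stride)[None, :]
    x_in = kx[:, None] + (ox.ravel() * stride)[None, :]
    return c_idx[:, None].repeat(y_in.shape[1], 1), y_in, x_in, h_out, w_out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution of a (C, H, W) tensor with (O, C, kh, kw) weights."""
    c_in, h, w = x.data.shape
    o, c_w, kh, kw = weight.data.shape
    if c_w != c_in:
        raise ValueError(f"channel mismatch: input {c_in}, weight {c_w}")
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad))) if pad else x.data
    ci, yi, xi, h_out, w_out = _im2col_indices(c_in, h, w, kh, kw, stride, pad)
    cols = xp[ci, yi, xi]  # (C*kh*kw, h_out*w_out)
    w_mat = weight.data.reshape(o, -1)
    out = w_mat @ cols
    if bias is not None:
        out += bias.data[:, None]
    out = out.reshape(o, h_out, w_out)

    def back(g: np.ndarray) -> None:
        g_mat = g.reshape(o, -1)
        if weight.requires_grad:
            weight.accumulate((g_mat @ cols.T).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias.accumulate(g_mat.sum(axis=1))
        if x.requires_grad:
            dcols = w_mat.T @ g_mat
            dxp = np.zeros((c_in, h + 2 * pad, w + 2 * pad))
            np.add.at(dxp, (ci, yi, xi), dcols)
            dx = dxp[:, pad:pad + h, pad:pad + w] if pad else dxp
            x.accumulate(dx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _op(out, parents, back)


def maxpool2d(x: Tensor, kernel: int, stride: int, pad: int = 0) -> Tensor:
    c_in, h, w = x.data.shape
    fill = -np.inf
    xp = (
        np.pad(x.data, ((0, 0), (pad, pad), (pad, pad)), constant_values=fill)
        if pad else x.data
    )
    ci, yi, xi, h_out, w_out = _im2col_indices(1, h, w, kernel, kernel, stride, pad)
    # per channel windows: (C, k*k, h_out*w_out)
    windows = xp[:, yi, xi]
    arg = windows.argmax(axis=1)
    out = np.take_along_axis(windows, arg[:, None, :], axis=1)[:, 0, :]
    out = out.reshape(c_in, h_out, w_out)

    def back(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        g_flat = g.reshape(c_in, -1)
        dxp = np.zeros((c_in, h + 2 * pad, w + 2 * pad))
        ymax = np.take_along_axis(yi[None].repeat(c_in, 0), arg[:, None, :], 1)[:, 0, :]
        xmax = np.take_along_axis(xi[None].repeat(c_in, 0), arg[:, None, :], 1)[:, 0, :]
        cc = np.arange(c_in)[:, None].repeat(g_flat.shape[1], 1)
        np.add.at(dxp, (cc, ymax, xmax), g_flat)
        dx = dxp[:, pad:pad + h, pad:pad + w] if pad else dxp
        x.accumulate(dx)

    return _op(out, (x,), back)


def upsample_nearest2(x: Tensor, out_hw: tuple[int, int] | None = None) -> Tensor:
    """Nearest-neighbour x2 upsampling, optionally cropped to ``out_hw``
    (to match odd-sized lateral maps in the pyramid)."""
    up = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)
    if out_hw is not None:
        up = up[:, : out_hw[0], : out_hw[1]]
    c_in, h, w = x.data.shape

    def back(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        full = np.zeros((c_in, 2 * h, 2 * w))
        full[:, : g.shape[1], : g.shape[2]] = g
        dx = full.reshape(c_in, h, 2, w, 2).sum(axis=(2, 4))
        x.accumulate(dx)

    return _op(up, (x,), back)


# ---------------------------------------------------------------------------
# losses (sums, so the caller controls normalization)
# ---------------------------------------------------------------------------

def bce_with_logits_sum(logits: Tensor, targets: np.ndarray) -> Tensor:
    t = np.asarray(targets, dtype=float)
    z = logits.data
    # stable formulation: max(z,0) - z*t + log(1 + exp(-|z|))
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-z))

    def back(g: np.ndarray) -> None:
        if logits.requires_grad:
            logits.accumulate(g * (p - t))

    return _op(loss.sum(), (logits,), back)


def softmax_ce_sum(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Cross-entropy of (N, K) logits against integer labels, summed."""
    t = np.asarray(targets, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(t)
    loss = -np.log(np.clip(p[np.arange(n), t], 1e-300, None)).sum()

    def back(g: np.ndarray) -> None:
        if logits.requires_grad:
            dz = p.copy()
            dz[np.arange(n), t] -= 1.0
            logits.accumulate(g * dz)

    return _op(loss, (logits,), back)


def smooth_l1_sum(pred: Tensor, target: np.ndarray) -> Tensor:
    t = np.asarray(target, dtype=float)
    d = pred.data - t
    ad = np.abs(d)
    loss = np.where(ad < 1.0, 0.5 * d * d, ad - 0.5).sum()

    def back(g: np.ndarray) -> None:
        if pred.requires_grad:
            pred.accumulate(g * np.where(ad < 1.0, d, np.sign(d)))

    return _op(loss, (pred,), back)


def rroi_pool(
    x: Tensor, idx: np.ndarray, weights: np.ndarray, k: int
) -> Tensor:
    """Pool one proposal's k*k grid from a (C, H, W) feature tensor given
    precomputed bilinear sample indices/weights.

    ``idx``/``weights`` have shape (k*k*l, 4): flat spatial indices into
    H*W and their bilinear weights (zero where out of bounds). Returns a
    flattened (C*k*k,) tensor (bin-major, channels fastest varying last).
    """
    c_dim = x.data.shape[0]
    flat = x.data.reshape(c_dim, -1)
    n_samples, _ = idx.shape
    l = n_samples // (k * k)
    gathered = flat[:, idx] * weights[None]  # (C, k*k*l, 4)
    pooled = gathered.sum(axis=2).reshape(c_dim, k * k, l).mean(axis=2)

    def back(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        gk = g.reshape(c_dim, k * k)
        gs = np.repeat(gk, l, axis=1) / l  # (C, k*k*l)
        contrib = gs[:, :, None] * weights[None]
        dflat = np.zeros_like(flat)
        cc = np.arange(c_dim)[:, None, None]
        np.add.at(dflat, (np.broadcast_to(cc, contrib.shape), idx[None]), contrib)
        x.accumulate(dflat.reshape(x.data.shape))

    return _op(pooled.reshape(-1), (x,), back)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []

        def visit(value) -> None:
            if isinstance(value, Tensor):
                if value.requires_grad:
                    out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for v in value:
                    visit(v)

        for value in vars(self).values():
            visit(value)
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 stride: int = 1, pad: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 init_std: float | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        std = math.sqrt(2.0 / fan_in) if init_std is None else init_std
        self.weight = Tensor(
            rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None,
                 init_std: float | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / d_in) if init_std is None else init_std
        self.weight = Tensor(rng.normal(0.0, std, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class BatchNorm2d(Module):
    """Batch normalization in inference form (running statistics).

    The affine scale/shift are trainable parameters and counted as such;
    running mean/var are fixed buffers. The demo trainer uses the
    normalization-free reduced backbone, so no batch-statistics update is
    implemented here.
    """

    def __init__(self, c: int) -> None:
        self.weight = Tensor(np.ones(c), requires_grad=True)
        self.bias = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.eps = 1e-5

    def __call__(self, x: Tensor) -> Tensor:
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        w = (self.weight.data * inv)[:, None, None]
        b = (self.bias.data - self.running_mean * self.weight.data * inv)[:, None, None]
        weight, bias = self.weight, self.bias
        mean, var, eps = self.running_mean, self.running_var, self.eps

        def back(g: np.ndarray) -> None:
            inv_ = 1.0 / np.sqrt(var + eps)
            if weight.requires_grad:
                weight.accumulate(
                    ((x.data - mean[:, None, None]) * inv_[:, None, None] * g).sum((1, 2))
                )
            if bias.requires_grad:
                bias.accumulate(g.sum((1, 2)))
            if x.requires_grad:
                x.accumulate(g * (weight.data * inv_)[:, None, None])

        return _op(x.data * w + b, (x, weight, bias), back)


class Sequential(Module):
    def __init__(self, *layers) -> None:
        self.layers = list(layers)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, (Module,)) else layer(x)
        return x

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.layers:
            if isinstance(layer, Module):
                out.extend(layer.parameters())
        return out


class _Lambda(Module):
    def __init__(self, fn: Callable[[Tensor], Tensor]) -> None:
        self.fn = fn

    def __call__(self, x: Tensor) -> Tensor:
        return self.fn(x)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: Iterable[Tensor], lr: float, momentum: float = 0.9) -> None:
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
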