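"""A small reverse-mode automatic differentiation engine over numpy arrays.

Only the operations the registration network needs are implemented: 3D
convolution (via im2col + BLAS matmul), batch normalization, ReLU, 2x max-
and average-pooling, trilinear resizing, concatenation, weighted sums, a
differentiable trilinear warp (the spatial transformer), and the two training
losses.  Arrays are channels-last ``(D, H, W, C)``; the batch size is always
one, as in the training procedure this serves.

Graphs are built eagerly; :func:`backward` runs a topological sweep.  The
:func:`no_grad` context disables graph construction for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A numpy array plus the closures needed to backpropagate through it."""

    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, requires_grad=False, parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in parents
        )
        self.parents = tuple(parents) if (_grad_enabled and self.requires_grad) else ()

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g


def _make(data, parents):
    return Tensor(data, parents=parents)


def backward(root: Tensor, seed=1.0):
    """Backpropagate d(root)/d(leaf) into every reachable leaf's ``.grad``."""
    topo, seen = [], set()

    def visit(t):
        if id(t) in seen:
            return
        seen.add(id(t))
        for p, _ in t.parents:
            visit(p)
        topo.append(t)

    visit(root)
    root.accumulate(np.asarray(seed, dtype=root.data.dtype))
    for t in reversed(topo):
        if t.grad is None:
            continue
        for parent, grad_fn in t.parents:
            parent.accumulate(grad_fn(t.grad))


# ---------------------------------------------------------------------------
# Elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data + b.data, [(a, lambda g: g), (b, lambda g: g)])


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    """Add per-channel bias ``b (C,)`` to ``x (..., C)``."""
    ndim = x.data.ndim
    axes = tuple(range(ndim - 1))
    return _make(
        x.data + b.data,
        [(x, lambda g: g), (b, lambda g: g.sum(axis=axes))],
    )


def scale(x: Tensor, s: float) -> Tensor:
    return _make(x.data * s, [(x, lambda g: g * s)])


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return _make(x.data * mask, [(x, lambda g: g * mask)])


def concat(a: Tensor, b: Tensor) -> Tensor:
    na = a.data.shape[-1]
    return _make(
        np.concatenate([a.data, b.data], axis=-1),
        [(a, lambda g: g[..., :na]), (b, lambda g: g[..., na:])],
    )


def weighted_sum(tensors: list[Tensor], weights) -> Tensor:
    out = sum(w * t.data for t, w in zip(tensors, weights) if w != 0.0)
    parents = [
        (t, (lambda w_: (lambda g: g * w_))(w))
        for t, w in zip(tensors, weights)
        if w != 0.0
    ]
    return _make(out, parents)


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def _offsets(k: int):
    return [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 3D convolution.

    ``x (D, H, W, Cin)``, ``w (k, k, k, Cin, Cout)``, optional ``b (Cout,)``.
    Computed as a sum of k^3 shifted matrix products, which keeps everything
    in BLAS without materializing an im2col matrix.
    """
    k = w.data.shape[0]
    cin, cout = w.data.shape[3], w.data.shape[4]
    d, h, ww = x.data.shape[:3]
    n = d * h * ww
    pad = k // 2

    if k == 1:
        out = x.data.reshape(n, cin) @ w.data.reshape(cin, cout)
    else:
        xp = np.pad(x.data, ((pad, pad), (pad, pad), (pad, pad), (0, 0)))
        out = np.zeros((n, cout), dtype=x.data.dtype)
        for a, bb, c in _offsets(k):
            sl = xp[a : a + d, bb : bb + h, c : c + ww].reshape(n, cin)
            out += sl @ w.data[a, bb, c]
    if b is not None:
        out += b.data
    out = out.reshape((d, h, ww, cout))

    def grad_x(g):
        gflat = g.reshape(n, cout)
        if k == 1:
            return (gflat @ w.data.reshape(cin, cout).T).reshape(x.data.shape)
        dxp = np.zeros((d + 2 * pad, h + 2 * pad, ww + 2 * pad, cin),
                       dtype=x.data.dtype)
        for a, bb, c in _offsets(k):
            dxp[a : a + d, bb : bb + h, c : c + ww] += (
                gflat @ w.data[a, bb, c].T
            ).reshape(d, h, ww, cin)
        return dxp[pad : pad + d, pad : pad + h, pad : pad + ww]

    def grad_w(g):
        gflat = g.reshape(n, cout)
        if k == 1:
            return (x.data.reshape(n, cin).T @ gflat).reshape(w.data.shape)
        xp = np.pad(x.data, ((pad, pad), (pad, pad), (pad, pad), (0, 0)))
        dw = np.empty_like(w.data)
        for a, bb, c in _offsets(k):
            sl = xp[a : a + d, bb : bb + h, c : c + ww].reshape(n, cin)
            dw[a, bb, c] = sl.T @ gflat
        return dw

    parents = [(x, grad_x), (w, grad_w)]
    if b is not None:
        parents.append((b, lambda g: g.reshape(-1, cout).sum(axis=0)))
    return _make(out, parents)


# ---------------------------------------------------------------------------
# Pooling and resizing
# ---------------------------------------------------------------------------

def _pool_view(x: np.ndarray):
    d, h, w, c = x.shape
    v = x.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c)
    v = v.transpose(0, 2, 4, 1, 3, 5, 6)
    return v.reshape(d // 2, h // 2, w // 2, 8, c)


def maxpool2(x: Tensor) -> Tensor:
    v = _pool_view(x.data)
    idx = v.argmax(axis=3)
    out = np.take_along_axis(v, idx[..., None, :], axis=3)[..., 0, :]

    def grad_x(g):
        gv = np.zeros_like(v)
        np.put_along_axis(gv, idx[..., None, :], g[..., None, :], axis=3)
        d2, h2, w2, _, c = v.shape
        gv = gv.reshape(d2, h2, w2, 2, 2, 2, c).transpose(0, 3, 1, 4, 2, 5, 6)
        return gv.reshape(x.data.shape)

    return _make(out, [(x, grad_x)])


def avgpool2(x: Tensor) -> Tensor:
    v = _pool_view(x.data)
    out = v.mean(axis=3)

    def grad_x(g):
        gv = np.repeat(g[..., None, :] / 8.0, 8, axis=3)
        d2, h2, w2, _, c = v.shape
        gv = gv.reshape(d2, h2, w2, 2, 2, 2, c).transpose(0, 3, 1, 4, 2, 5, 6)
        return gv.reshape(x.data.shape)

    return _make(out, [(x, grad_x)])


def _linear_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Align-corners linear interpolation matrix (n_out, n_in)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    pos = np.arange(n_out) * (n_in - 1) / (n_out - 1) if n_out > 1 else np.zeros(1)
    i0 = np.clip(np.floor(pos).astype(int), 0, n_in - 2)
    f = pos - i0
    m[np.arange(n_out), i0] = 1.0 - f
    m[np.arange(n_out), i0 + 1] += f
    return m


def _apply_axis(mat: np.ndarray, x: np.ndarray, axis: int) -> np.ndarray:
    return np.moveaxis(np.tensordot(mat, x, axes=(1, axis)), 0, axis)


def resize_linear(x: Tensor, shape: tuple[int, int, int]) -> Tensor:
    """Trilinear (align-corners) resize of the three spatial axes."""
    mats = [
        _linear_matrix(shape[ax], x.data.shape[ax], x.data.dtype) for ax in range(3)
    ]
    out = x.data
    for ax in range(3):
        out = _apply_axis(mats[ax], out, ax)

    def grad_x(g):
        for ax in range(3):
            g = _apply_axis(mats[ax].T, g, ax)
        return g

    return _make(out, [(x, grad_x)])


# ---------------------------------------------------------------------------
# Batch normalization
# ---------------------------------------------------------------------------

class BNStat:
    """Exponential-moving-average statistics of one normalization layer."""

    __slots__ = ("mean", "var", "initialized")

    def __init__(self, channels: int, dtype=np.float32):
        self.mean = np.zeros(channels, dtype=dtype)
        self.var = np.ones(channels, dtype=dtype)
        self.initialized = False


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, stat: BNStat,
              training: bool, ema_decay: float = 0.99, eps: float = 1e-5) -> Tensor:
    axes = (0, 1, 2)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        if stat.initialized:
            stat.mean = ema_decay * stat.mean + (1 - ema_decay) * mean
            stat.var = ema_decay * stat.var + (1 - ema_decay) * var
        else:
            stat.mean, stat.var = mean.copy(), var.copy()
            stat.initialized = True
    else:
        mean, var = stat.mean, stat.var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    out = gamma.data * xhat + beta.data

    n = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]

    def grad_x(g):
        if not training:
            return g * (gamma.data * inv)
        gs = g * gamma.data
        return inv * (
            gs - gs.mean(axis=axes) - xhat * (gs * xhat).sum(axis=axes) / n
        )

    return _make(
        out,
        [
            (x, grad_x),
            (gamma, lambda g: (g * xhat).sum(axis=axes)),
            (beta, lambda g: g.sum(axis=axes)),
        ],
    )


# ---------------------------------------------------------------------------
# Spatial transformer (differentiable trilinear pull-warp)
# ---------------------------------------------------------------------------

def warp_trilinear(values: np.ndarray, field: Tensor) -> Tensor:
    """Differentiable pull-warp ``out(x) = values(x + u(x))``.

    ``values`` is a constant ``(D, H, W)`` volume, ``field`` a ``(D, H, W, 3)``
    displacement in voxel units.  Sampling is trilinear with zero outside the
    grid; gradients flow into the field only.
    """
    d, h, w = values.shape
    base = np.stack(
        np.meshgrid(
            np.arange(d), np.arange(h), np.arange(w), indexing="ij"
        ),
        axis=-1,
    ).astype(field.data.dtype)
    pts = base + field.data  # (D, H, W, 3)

    vp = np.pad(values, 1).astype(field.data.dtype)  # zero ring
    p = pts + 1.0
    dims = np.array(vp.shape)
    inb = np.logical_and.reduce(
        [(p[..., ax] >= 0) & (p[..., ax] <= dims[ax] - 1) for ax in range(3)]
    )
    i0 = np.floor(p).astype(np.int64)
    for ax in range(3):
        np.clip(i0[..., ax], 0, dims[ax] - 2, out=i0[..., ax])
    f = np.clip(p - i0, 0.0, 1.0)

    c = {}
    for a in (0, 1):
        for b_ in (0, 1):
            for cc in (0, 1):
                c[a, b_, cc] = vp[i0[..., 0] + a, i0[..., 1] + b_, i0[..., 2] + cc]
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    wx = (1 - fx, fx)
    wy = (1 - fy, fy)
    wz = (1 - fz, fz)
    out = sum(
        c[a, b_, cc] * wx[a] * wy[b_] * wz[cc]
        for a in (0, 1) for b_ in (0, 1) for cc in (0, 1)
    )

    def grad_field(g):
        gx = sum((c[1, b_, cc] - c[0, b_, cc]) * wy[b_] * wz[cc]
                 for b_ in (0, 1) for cc in (0, 1))
        gy = sum((c[a, 1, cc] - c[a, 0, cc]) * wx[a] * wz[cc]
                 for a in (0, 1) for cc in (0, 1))
        gz = sum((c[a, b_, 1] - c[a, b_, 0]) * wx[a] * wy[b_]
                 for a in (0, 1) for b_ in (0, 1))
        grad = np.stack([gx, gy, gz], axis=-1)
        grad *= inb[..., None]
        return grad * g[..., None]

    return _make(out, [(field, grad_field)])


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def soft_dice_loss(pred: Tensor, truth: np.ndarray, eps: float = 1e-5) -> Tensor:
    """1 - soft Dice of a [0,1] prediction against a binary truth."""
    t = truth.astype(pred.data.dtype)
    inter = float((t * pred.data).sum())
    denom = float(t.sum() + pred.data.sum()) + eps
    out = 1.0 - 2.0 * inter / denom

    def grad_pred(g):
        return g * (-2.0) * (t * denom - (t * pred.data).sum()) / denom**2

    return _make(np.asarray(out, dtype=pred.data.dtype), [(pred, grad_pred)])


def field_mse_loss(pred: Tensor, truth: np.ndarray) -> Tensor:
    """Mean over voxels of the squared 3-vector field difference."""
    t = truth.astype(pred.data.dtype)
    diff = pred.data - t
    nvox = diff.size // 3
    out = float((diff * diff).sum()) / nvox

    def grad_pred(g):
        return g * 2.0 * diff / nvox

    return _make(np.asarray(out, dtype=pred.data.dtype), [(pred, grad_pred)])
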