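"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides the handful of differentiable primitives the
segmentation network needs: broadcast-aware arithmetic, reductions,
sigmoid/relu, strided 2-D convolution (im2col + BLAS), 2x max pooling,
2x bilinear upsampling, 2x transposed convolution, channel-axis max,
concatenation, and a fused weighted cross-entropy.  Every primitive
carries a hand-derived backward pass; the test suite checks each one
against central finite differences.

Data is float64 by default; float32 arrays are kept as float32 (the
training loop uses single precision for speed).  Gradients accumulate
into ``Tensor.grad`` when ``Tensor.backward()`` is called on a scalar
output.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def _accum(self, g):
        # rebinds rather than updating in place, so aliased gradient views
        # (pass-through ops) stay safe without defensive copies
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # break closure/node reference cycles so the graph frees promptly
        for node in topo:
            node._backward = None
            node._parents = ()

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _pair(a, b):
    """Wrap operands, matching a bare scalar/array to its peer's dtype."""
    if isinstance(a, Tensor) and not isinstance(b, Tensor):
        return a, Tensor(np.asarray(b, dtype=a.data.dtype))
    if isinstance(b, Tensor) and not isinstance(a, Tensor):
        return Tensor(np.asarray(a, dtype=b.data.dtype)), b
    return as_tensor(a), as_tensor(b)


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _node(data, parents, backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data, req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward(out)
    return out


# ---------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------

def add(a, b):
    a, b = _pair(a, b)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad, b.data.shape))
        return run

    return _node(a.data + b.data, (a, b), bw)


def sub(a, b):
    a, b = _pair(a, b)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-out.grad, b.data.shape))
        return run

    return _node(a.data - b.data, (a, b), bw)


def mul(a, b):
    a, b = _pair(a, b)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad * a.data, b.data.shape))
        return run

    return _node(a.data * b.data, (a, b), bw)


def div(a, b):
    a, b = _pair(a, b)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-out.grad * a.data / (b.data * b.data),
                                      b.data.shape))
        return run

    return _node(a.data / b.data, (a, b), bw)


def sqrt(a):
    a = as_tensor(a)
    root = np.sqrt(a.data)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(out.grad * 0.5 / root)
        return run

    return _node(root, (a,), bw)


def sigmoid(a):
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(out.grad * s * (1.0 - s))
        return run

    return _node(s, (a,), bw)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(out.grad * mask)
        return run

    return _node(a.data * mask, (a,), bw)


# ---------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(out):
        def run():
            if not a.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape))
        return run

    return _node(out_data, (a,), bw)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    a = as_tensor(a)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(out.grad.reshape(a.data.shape))
        return run

    return _node(a.data.reshape(shape), (a,), bw)


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(out):
        def run():
            pieces = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, pieces):
                if t.requires_grad:
                    t._accum(g)
        return run

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bw)


def channel_max(a):
    """Max over the channel axis (axis 1) with keepdims.

    Ties route the gradient to the lowest channel index (NumPy argmax).
    """
    a = as_tensor(a)
    idx = np.argmax(a.data, axis=1)
    out_data = np.take_along_axis(a.data, idx[:, None], axis=1)

    def bw(out):
        def run():
            if a.requires_grad:
                g = np.zeros_like(a.data)
                np.put_along_axis(g, idx[:, None], out.grad, axis=1)
                a._accum(g)
        return run

    return _node(out_data, (a,), bw)


def batch_normalize(x, axes=(0, 2, 3), eps=1e-5):
    """Fused (x - mean) / sqrt(var + eps) over ``axes`` with batch statistics.

    Returns ``(xhat, mean, var)``; mean/var are plain arrays (for running-
    statistic updates).  The backward pass uses the standard closed form
    dL/dx = (g - mean(g) - xhat * mean(g * xhat)) / sqrt(var + eps).
    """
    x = as_tensor(x)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat_data = (x.data - mu) * inv

    def bw(out):
        def run():
            if not x.requires_grad:
                return
            g = out.grad
            gm = g.mean(axis=axes, keepdims=True)
            gx = (g * xhat_data).mean(axis=axes, keepdims=True)
            x._accum((g - gm - xhat_data * gx) * inv)
        return run

    return _node(xhat_data, (x,), bw), mu, var


def fixed_normalize(x, mean, var, eps=1e-5):
    """(x - mean) / sqrt(var + eps) with constant statistics (inference)."""
    x = as_tensor(x)
    inv = 1.0 / np.sqrt(np.asarray(var) + eps)

    def bw(out):
        def run():
            if x.requires_grad:
                x._accum(out.grad * inv)
        return run

    return _node((x.data - np.asarray(mean)) * inv, (x,), bw)


def channel_affine(x, scale, shift):
    """Per-channel affine x * scale[c] + shift[c] on NCHW input."""
    x, scale, shift = as_tensor(x), as_tensor(scale), as_tensor(shift)
    C = x.data.shape[1]
    sh = (1, C, 1, 1)
    out_data = x.data * scale.data.reshape(sh) + shift.data.reshape(sh)

    def bw(out):
        def run():
            g = out.grad
            if x.requires_grad:
                x._accum(g * scale.data.reshape(sh))
            if scale.requires_grad:
                scale._accum(np.einsum("bchw,bchw->c", g, x.data))
            if shift.requires_grad:
                shift._accum(g.sum(axis=(0, 2, 3)))
        return run

    return _node(out_data, (x, scale, shift), bw)


# ---------------------------------------------------------------------
# spatial primitives
# ---------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    B, Cin, H, W = x.data.shape
    O, Cin2, kh, kw = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"conv2d channel mismatch: input {Cin}, kernel {Cin2}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    OH = (H + 2 * p - kh) // s + 1
    OW = (W + 2 * p - kw) // s + 1
    view = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # (B, Cin, OH, OW, kh, kw) -> (B, Cin*kh*kw, OH*OW)
    cols = np.ascontiguousarray(view.transpose(0, 1, 4, 5, 2, 3)).reshape(
        B, Cin * kh * kw, OH * OW)
    w2 = w.data.reshape(O, -1)
    out_data = (w2 @ cols).reshape(B, O, OH, OW)
    if b is not None:
        out_data = out_data + b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(out):
        def run():
            go = out.grad.reshape(B, O, OH * OW)
            if w.requires_grad:
                gw = np.tensordot(go, cols, axes=([0, 2], [0, 2]))
                w._accum(gw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(out.grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gcols = (w2.T @ go).reshape(B, Cin, kh, kw, OH, OW)
                gxp = np.zeros((B, Cin, H + 2 * p, W + 2 * p), dtype=x.data.dtype)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + s * OH:s, j:j + s * OW:s] += gcols[:, :, i, j]
                gx = gxp[:, :, p:p + H, p:p + W] if p else gxp
                x._accum(gx)
        return run

    return _node(out_data, parents, bw)


def conv_transpose2x(x, w, b=None):
    """Transposed convolution, kernel 2x2, stride 2 (exact x2 upsampling).

    ``w`` has shape (Cin, Cout, 2, 2).
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    B, Cin, H, W = x.data.shape
    Cin2, O, kh, kw = w.data.shape
    if Cin != Cin2 or (kh, kw) != (2, 2):
        raise ValueError("conv_transpose2x expects (Cin, Cout, 2, 2) kernel")
    y6 = np.einsum("bchw,cokl->bohkwl", x.data, w.data)
    out_data = y6.reshape(B, O, 2 * H, 2 * W)
    if b is not None:
        out_data = out_data + b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(out):
        def run():
            g6 = out.grad.reshape(B, O, H, 2, W, 2)
            if x.requires_grad:
                x._accum(np.einsum("bohkwl,cokl->bchw", g6, w.data))
            if w.requires_grad:
                w._accum(np.einsum("bchw,bohkwl->cokl", x.data, g6))
            if b is not None and b.requires_grad:
                b._accum(out.grad.sum(axis=(0, 2, 3)))
        return run

    return _node(out_data, parents, bw)


def maxpool2x(x):
    """2x2 max pooling, stride 2; spatial extents must be even."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x requires even spatial extents")
    v = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = np.ascontiguousarray(v).reshape(B, C, H // 2, W // 2, 4)
    idx = np.argmax(v, axis=-1)
    out_data = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def bw(out):
        def run():
            if x.requires_grad:
                g = np.zeros_like(v)
                np.put_along_axis(g, idx[..., None], out.grad[..., None], axis=-1)
                g = g.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
                x._accum(g.reshape(B, C, H, W))
        return run

    return _node(out_data, (x,), bw)


_INTERP_CACHE: dict = {}


def _interp_matrix(n: int, dtype=np.float64) -> np.ndarray:
    """Dense (2n, n) matrix for x2 linear interpolation of a length-n axis.

    Half-pixel-centre convention: target i samples source (i + 0.5)/2 - 0.5,
    clamped to the valid range.
    """
    key = (n, np.dtype(dtype).str)
    if key not in _INTERP_CACHE:
        src = np.clip((np.arange(2 * n) + 0.5) / 2.0 - 0.5, 0, n - 1)
        i0 = np.floor(src).astype(np.intp)
        i1 = np.minimum(i0 + 1, n - 1)
        frac = src - i0
        m = np.zeros((2 * n, n))
        m[np.arange(2 * n), i0] += 1 - frac
        m[np.arange(2 * n), i1] += frac
        _INTERP_CACHE[key] = m.astype(dtype)
    return _INTERP_CACHE[key]


def _apply_axis(a: np.ndarray, m: np.ndarray, axis: int) -> np.ndarray:
    """Apply linear map ``m`` along ``axis`` of ``a``."""
    moved = np.tensordot(m, a, axes=(1, axis))      # new axis leads
    return np.moveaxis(moved, 0, axis)


def upsample_bilinear2x(x):
    """Exact x2 bilinear upsampling (half-pixel centres, clamped edges)."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    dt = x.data.dtype
    mh, mw = _interp_matrix(H, dt), _interp_matrix(W, dt)
    out_data = _apply_axis(_apply_axis(x.data, mh, 2), mw, 3)

    def bw(out):
        def run():
            if x.requires_grad:
                g = _apply_axis(_apply_axis(out.grad, mh.T, 2), mw.T, 3)
                x._accum(g)
        return run

    return _node(out_data, (x,), bw)


# ---------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------

def weighted_cross_entropy_loss(scores, targets, class_weights):
    """Per-pixel weighted categorical cross-entropy.

    loss = sum_p w[y_p] * (-log softmax(scores_p)[y_p]) / sum_p w[y_p]

    ``scores``: (B, K, H, W) tensor; ``targets``: (B, H, W) int array with
    values in [0, K); ``class_weights``: length-K positive array.
    """
    scores = as_tensor(scores)
    targets = np.asarray(targets)
    cw = np.asarray(class_weights, dtype=np.float64)
    # cast after validation so float32 score maps stay float32 throughout
    B, K, H, W = scores.data.shape
    if targets.shape != (B, H, W):
        raise ValueError("targets shape must match scores batch/spatial shape")
    if targets.min() < 0 or targets.max() >= K:
        bad = int(targets.min()) if targets.min() < 0 else int(targets.max())
        raise ValueError(f"target label {bad} outside [0, {K})")
    if cw.shape != (K,):
        raise ValueError(f"class_weights must have length {K}")

    cw = cw.astype(scores.data.dtype)
    m = scores.data.max(axis=1, keepdims=True)
    z = scores.data - m
    lse = m + np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = scores.data - lse                       # (B, K, H, W)
    nll = -np.take_along_axis(logp, targets[:, None], axis=1)[:, 0]
    wmap = cw[targets]                             # (B, H, W)
    wsum = wmap.sum()
    loss = (wmap * nll).sum() / wsum

    def bw(out):
        def run():
            if not scores.requires_grad:
                return
            g = np.exp(logp)
            taken = np.take_along_axis(g, targets[:, None], axis=1) - 1.0
            np.put_along_axis(g, targets[:, None], taken, axis=1)
            g *= (wmap / wsum)[:, None]
            scores._accum(g * out.grad)
        return run

    return _node(loss, (scores,), bw)
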