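"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides exactly the operator set needed by the dual-branch
transformer/CNN model: broadcast-aware arithmetic, (batched) matrix
multiplication, ReLU, softmax / log-softmax, layer normalisation, tensor
reshaping, concatenation, patch extraction for convolution (im2col) and
2x2 max pooling.  Gradients are accumulated by a topologically sorted
backward sweep over the recorded tape.

All arithmetic is float64: the model sizes used here are small enough
that the extra precision is cheap, and it keeps oracle comparisons tight.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor", "use_dtype",
    "add", "sub", "mul", "neg", "scale", "power",
    "matmul", "relu", "softmax", "log_softmax", "layer_norm",
    "reshape", "transpose", "concat", "sum_", "mean_",
    "im2col", "maxpool2x2", "conv2d_tokens", "maxpool2x2_tokens", "dropout_mask",
]

_DEFAULT_DTYPE = np.dtype(np.float64)


@contextmanager
def use_dtype(dtype):
    """Temporarily change the dtype new tensors are created with.

    Training loops run under float32 for speed; the float64 default keeps
    API-level numerics tight.
    """
    global _DEFAULT_DTYPE
    old = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        _DEFAULT_DTYPE = old


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=_DEFAULT_DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}{tag})"

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.array(grad)   # copy: the buffer may feed other parents
        else:
            self.grad += grad

    def backward(self, grad=None):
        """Run reverse-mode accumulation from this (typically scalar) node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs here can be a few thousand nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- primitive ops ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    return add(a, neg(_wrap(b)))


def neg(a) -> Tensor:
    a = _wrap(a)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(-grad)

    return Tensor._make(-a.data, (a,), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad * a.data, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def scale(a, s: float) -> Tensor:
    a = _wrap(a)
    s = float(s)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * s)

    return Tensor._make(a.data * s, (a,), backward)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    p = float(p)
    out_data = a.data ** p

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * p * a.data ** (p - 1.0))

    return Tensor._make(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    """Batched matrix product with standard NumPy stacking semantics."""
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(grad):
        if a.requires_grad:
            ga = grad @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ grad
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * mask)

    return Tensor._make(a.data * mask, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis` (fused forward/backward)."""
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(grad):
        if a.requires_grad:
            dot = (grad * y).sum(axis=axis, keepdims=True)
            a._accumulate(y * (grad - dot))

    return Tensor._make(y, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    y = np.exp(out_data)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad - y * grad.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (a,), backward)


def layer_norm(a, eps: float = 1e-5) -> Tensor:
    """Normalise the last axis to zero mean / unit variance (no affine)."""
    a = _wrap(a)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv

    def backward(grad):
        if a.requires_grad:
            n = a.data.shape[-1]
            g_mean = grad.mean(axis=-1, keepdims=True)
            gx_mean = (grad * xhat).mean(axis=-1, keepdims=True)
            a._accumulate(inv * (grad - g_mean - xhat * gx_mean))
            _ = n  # dimension folded into the means above

    return Tensor._make(xhat, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    old = a.data.shape

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad.reshape(old))

    return Tensor._make(a.data.reshape(shape), (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    inv = np.argsort(axes)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad.transpose(inv))

    return Tensor._make(a.data.transpose(axes), (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        pieces = np.split(grad, splits, axis=axis)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(g)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(grad):
        if a.requires_grad:
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return Tensor._make(out_data, (a,), backward)


def mean_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return scale(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def im2col(a, kh: int, kw: int) -> Tensor:
    """Extract same-padded kh x kw patches from a (B, C, H, W) tensor.

    Returns (B, H*W, C*kh*kw); pairs with a weight matmul to express a
    same-padding 2-D convolution.  Backward scatter-adds into the padded
    input.
    """
    a = _wrap(a)
    B, C, H, W = a.data.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(a.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(2, 3))
    # win: (B, C, H, W, kh, kw) -> (B, H*W, C*kh*kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * kh * kw)

    def backward(grad):
        if not a.requires_grad:
            return
        g = grad.reshape(B, H, W, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gpad = np.zeros_like(padded)
        for di in range(kh):
            for dj in range(kw):
                gpad[:, :, di:di + H, dj:dj + W] += g[:, :, :, :, di, dj]
        a._accumulate(gpad[:, :, ph:ph + H, pw:pw + W])

    return Tensor._make(np.ascontiguousarray(cols), (a,), backward)


def maxpool2x2(a) -> Tensor:
    """2x2 / stride-2 max pooling over the trailing two axes of (B, C, H, W).

    Odd trailing rows/columns are dropped, matching the usual floor
    behaviour of pooling layers.
    """
    a = _wrap(a)
    B, C, H, W = a.data.shape
    H2, W2 = H // 2, W // 2
    x = a.data[:, :, :H2 * 2, :W2 * 2]
    blocks = x.reshape(B, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, 4)
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(grad):
        if not a.requires_grad:
            return
        gblocks = np.zeros_like(blocks)
        np.put_along_axis(gblocks, idx[..., None], grad[..., None], axis=-1)
        gx = gblocks.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2 * 2, W2 * 2)
        gfull = np.zeros_like(a.data)
        gfull[:, :, :H2 * 2, :W2 * 2] = gx
        a._accumulate(gfull)

    return Tensor._make(out_data, (a,), backward)


_GRID_CACHE: dict = {}


def _conv_indices(H: int, W: int, k: int):
    """Neighbour index tables for same-padded k x k convolution on an
    (H, W) grid flattened row-major, with a (H+2p) x (W+2p) padded grid."""
    key = (H, W, k)
    if key not in _GRID_CACHE:
        p = k // 2
        Wp = W + 2 * p
        rows = np.arange(H)[:, None] + p
        cols = np.arange(W)[None, :] + p
        interior = (rows * Wp + cols).ravel()                      # (H*W,)
        offs = [(di - p) * Wp + (dj - p) for di in range(k) for dj in range(k)]
        nidx = interior[:, None] + np.array(offs)[None, :]         # (H*W, k*k)
        _GRID_CACHE[key] = (interior, nidx, (H + 2 * p) * Wp)
    return _GRID_CACHE[key]


def _pool_indices(H: int, W: int):
    """Index table for 2x2/stride-2 pooling on a flattened (H, W) grid."""
    key = ("pool", H, W)
    if key not in _GRID_CACHE:
        H2, W2 = H // 2, W // 2
        r = np.arange(H2) * 2
        c = np.arange(W2) * 2
        base = (r[:, None] * W + c[None, :]).ravel()               # (H2*W2,)
        pidx = base[:, None] + np.array([0, 1, W, W + 1])[None, :]
        _GRID_CACHE[key] = pidx
    return _GRID_CACHE[key]


def conv2d_tokens(x, weight, bias, H: int, W: int, k: int) -> Tensor:
    """Same-padded k x k convolution on a token-layout map.

    ``x`` is (B, H*W, C_in) — positions row-major over the (H, W) grid —
    and ``weight`` is (k*k*C_in, C_out), offset-major.  Output stays in
    token layout (B, H*W, C_out), avoiding image-layout transposes.
    """
    x, weight, bias = _wrap(x), _wrap(weight), _wrap(bias)
    B, P, C = x.data.shape
    if P != H * W:
        raise ValueError(f"token map of {P} positions does not match {H}x{W}")
    interior, nidx, Ppad = _conv_indices(H, W, k)
    xp = np.zeros((B, Ppad, C), dtype=x.data.dtype)
    xp[:, interior, :] = x.data
    cols = xp[:, nidx, :].reshape(B, P, k * k * C)
    out_data = cols @ weight.data + bias.data

    def backward(grad):
        if bias.requires_grad:
            bias._accumulate(grad.sum(axis=(0, 1)))
        if weight.requires_grad:
            weight._accumulate(
                cols.reshape(B * P, -1).T @ grad.reshape(B * P, -1))
        if x.requires_grad:
            dcols = (grad @ weight.data.T).reshape(B, P, k * k, C)
            gxp = np.zeros_like(xp)
            for j in range(k * k):
                # each offset is a pure translation -> unique indices
                gxp[:, nidx[:, j], :] += dcols[:, :, j, :]
            x._accumulate(gxp[:, interior, :])

    return Tensor._make(out_data, (x, weight, bias), backward)


def maxpool2x2_tokens(x, H: int, W: int) -> Tensor:
    """2x2 / stride-2 max pooling on a (B, H*W, C) token-layout map.

    Returns (B, (H//2)*(W//2), C); odd trailing rows/columns are dropped.
    """
    x = _wrap(x)
    B, P, C = x.data.shape
    if P != H * W:
        raise ValueError(f"token map of {P} positions does not match {H}x{W}")
    pidx = _pool_indices(H, W)
    blocks = x.data[:, pidx, :]                        # (B, P2, 4, C)
    am = blocks.argmax(axis=2)
    out_data = np.take_along_axis(blocks, am[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(grad):
        if not x.requires_grad:
            return
        gblocks = np.zeros_like(blocks)
        np.put_along_axis(gblocks, am[:, :, None, :], grad[:, :, None, :], axis=2)
        gx = np.zeros_like(x.data)
        for j in range(4):
            gx[:, pidx[:, j], :] += gblocks[:, :, j, :]
        x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)


def dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with probability `rate`, else 1/(1-rate)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return np.ones(shape, dtype=_DEFAULT_DTYPE)
    keep = rng.random(shape) >= rate
    return (keep / (1.0 - rate)).astype(_DEFAULT_DTYPE)
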