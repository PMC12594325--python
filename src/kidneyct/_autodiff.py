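"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The trainable parts of the pipeline (learnable CT windowing, gated fusion,
the ConvNeXtV2-style backbone, channel-attention fusion and the auxiliary
histogram/MMD losses) need gradients; this module provides exactly the
tensor primitives they are composed of, in float64 NCHW convention, and
nothing more.  Every operation records a vector-Jacobian product closure;
``Tensor.backward`` runs an iterative topological sweep so arbitrarily deep
graphs (the backbone unrolls to a few thousand nodes) do not hit the Python
recursion limit.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import special

__all__ = [
    "Tensor",
    "astensor",
    "concat",
    "conv2d",
    "depthwise_conv2d",
    "adaptive_avg_pool2d",
    "upsample_nearest",
    "resize_bilinear",
    "softmax_cross_entropy",
]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus gradient bookkeeping.

    ``requires_grad`` is inherited from parents, so any graph touching a
    parameter is differentiable end to end.  Intermediate nodes also receive
    ``.grad`` during backward, which Grad-CAM relies on.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence["Tensor"] = (),
                 _vjp: Callable[[np.ndarray], tuple] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._vjp = _vjp

    # ------------------------------------------------------------------ util
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological order (graphs are deep; avoid recursion)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        for node in topo:
            if node is not self:
                node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    # ---------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = astensor(other)
        a, b = self, other
        return Tensor(a.data + b.data, _parents=(a, b),
                      _vjp=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor(-a.data, _parents=(a,), _vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        a, b = self, other
        return Tensor(a.data * b.data, _parents=(a, b),
                      _vjp=lambda g: (_unbroadcast(g * b.data, a.shape),
                                      _unbroadcast(g * a.data, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        a, b = self, other
        return Tensor(a.data / b.data, _parents=(a, b),
                      _vjp=lambda g: (_unbroadcast(g / b.data, a.shape),
                                      _unbroadcast(-g * a.data / b.data ** 2, b.shape)))

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        a = self
        return Tensor(a.data ** p, _parents=(a,),
                      _vjp=lambda g: (g * p * a.data ** (p - 1),))

    def __matmul__(self, other):
        other = astensor(other)
        a, b = self, other
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        return Tensor(a.data @ b.data, _parents=(a, b),
                      _vjp=lambda g: (g @ b.data.T, a.data.T @ g))

    # ------------------------------------------------------------ pointwise
    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor(out, _parents=(a,), _vjp=lambda g: (g * out,))

    def log(self):
        a = self
        return Tensor(np.log(a.data), _parents=(a,), _vjp=lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)
        return Tensor(out, _parents=(a,), _vjp=lambda g: (g * 0.5 / out,))

    def tanh(self):
        a = self
        out = np.tanh(a.data)
        return Tensor(out, _parents=(a,), _vjp=lambda g: (g * (1.0 - out ** 2),))

    def sigmoid(self):
        a = self
        out = special.expit(a.data)
        return Tensor(out, _parents=(a,), _vjp=lambda g: (g * out * (1.0 - out),))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor(a.data * mask, _parents=(a,), _vjp=lambda g: (g * mask,))

    def abs(self):
        a = self
        sign = np.sign(a.data)
        return Tensor(np.abs(a.data), _parents=(a,), _vjp=lambda g: (g * sign,))

    def gelu(self):
        """Exact (erf-based) GELU: x * Phi(x)."""
        a = self
        phi = 0.5 * (1.0 + special.erf(a.data * _INV_SQRT2))
        pdf = np.exp(-0.5 * a.data ** 2) * _INV_SQRT_2PI
        return Tensor(a.data * phi, _parents=(a,),
                      _vjp=lambda g: (g * (phi + a.data * pdf),))

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).astype(np.float64, copy=True),)
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(x % a.data.ndim for x in axes):
                    gg = np.expand_dims(gg, ax)
            return (np.broadcast_to(gg, a.shape).astype(np.float64, copy=True),)

        return Tensor(out, _parents=(a,), _vjp=vjp)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------------- shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor(a.data.reshape(shape), _parents=(a,),
                      _vjp=lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))
        return Tensor(a.data.transpose(axes), _parents=(a,),
                      _vjp=lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        a = self

        def vjp(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(a.data[idx], _parents=(a,), _vjp=vjp)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        slicer = [slice(None)] * g.ndim
        outs = []
        for i in range(len(tensors)):
            slicer[axis] = slice(offsets[i], offsets[i + 1])
            outs.append(g[tuple(slicer)])
        return tuple(outs)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  _parents=tensors, _vjp=vjp)


# ---------------------------------------------------------------- conv ops

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, zero padding."""
    x, w = astensor(x), astensor(w)
    Cout, Cin, kh, kw = w.shape
    if x.shape[1] != Cin:
        raise ValueError(f"conv2d: expected {Cin} input channels, got {x.shape[1]}")
    parents = (x, w) if b is None else (x, w, b)

    if kh == kw == 1 and stride == 1 and padding == 0:
        # pointwise fast path: a channel matmul
        wmat = w.data.reshape(Cout, Cin)
        out = np.einsum("oc,bchw->bohw", wmat, x.data, optimize=True)
        if b is not None:
            out = out + b.data.reshape(1, Cout, 1, 1)

        def vjp1(g):
            gw = np.einsum("bohw,bchw->oc", g, x.data, optimize=True).reshape(w.shape)
            gx = np.einsum("oc,bohw->bchw", wmat, g, optimize=True)
            if b is None:
                return gx, gw
            return gx, gw, g.sum(axis=(0, 2, 3))

        return Tensor(out, _parents=parents, _vjp=vjp1)

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, Cin, Ho, Wo, kh, kw)
    out = np.einsum("bchwij,ocij->bohw", win, w.data, optimize=True)
    Ho, Wo = out.shape[2], out.shape[3]
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)

    def vjp(g):
        gw = np.einsum("bchwij,bohw->ocij", win, g, optimize=True)
        gx = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                    np.einsum("bohw,oc->bchw", g, w.data[:, :, i, j], optimize=True)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return Tensor(out, _parents=parents, _vjp=vjp)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     padding: int = 0) -> Tensor:
    """Depthwise convolution, one k x k kernel per channel (stride 1)."""
    x, w = astensor(x), astensor(w)
    C, kh, kw = w.shape
    if x.shape[1] != C:
        raise ValueError("depthwise_conv2d: channel mismatch")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out = np.einsum("bchwij,cij->bchw", win, w.data, optimize=True)
    Ho, Wo = out.shape[2], out.shape[3]
    if b is not None:
        out = out + b.data.reshape(1, C, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def vjp(g):
        gw = np.einsum("bchwij,bchw->cij", win, g, optimize=True)
        gx = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i:i + Ho, j:j + Wo] += g * w.data[None, :, i, j, None, None]
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return Tensor(out, _parents=parents, _vjp=vjp)


# ---------------------------------------------------------------- pooling

def _pool_bins(n: int, s: int):
    edges = [(i * n) // s for i in range(s + 1)]
    return [(edges[i], edges[i + 1]) for i in range(s)]


def adaptive_avg_pool2d(x: Tensor, s: int) -> Tensor:
    """Average-pool to an s x s grid (bins as even as integer division allows)."""
    x = astensor(x)
    B, C, H, W = x.shape
    hb, wb = _pool_bins(H, s), _pool_bins(W, s)
    out = np.empty((B, C, s, s))
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            out[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def vjp(g):
        gx = np.zeros((B, C, H, W))
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                gx[:, :, h0:h1, w0:w1] += g[:, :, i, j, None, None] / ((h1 - h0) * (w1 - w0))
        return (gx,)

    return Tensor(out, _parents=(x,), _vjp=vjp)


def upsample_nearest(x: Tensor, size: tuple) -> Tensor:
    """Nearest-neighbour upsample; inverse index map of the adaptive pooling bins."""
    x = astensor(x)
    B, C, h, w = x.shape
    H, W = size
    ih = (np.arange(H) * h) // H
    iw = (np.arange(W) * w) // W
    out = x.data[:, :, ih][:, :, :, iw]

    def vjp(g):
        gx = np.zeros((B, C, h, W))
        np.add.at(gx, (slice(None), slice(None), ih), g)
        gx2 = np.zeros((B, C, h, w))
        np.add.at(gx2.transpose(0, 1, 3, 2), (slice(None), slice(None), iw),
                  gx.transpose(0, 1, 3, 2))
        return (gx2,)

    return Tensor(out, _parents=(x,), _vjp=vjp)


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic interpolation matrix (align_corners=False convention)."""
    R = np.zeros((n_out, n_in))
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = src - i0
    R[np.arange(n_out), i0] += 1 - t
    R[np.arange(n_out), i1] += t
    return R


def resize_bilinear(x: Tensor, size: tuple) -> Tensor:
    """Differentiable bilinear resize of an NCHW tensor (separable linear map)."""
    x = astensor(x)
    B, C, h, w = x.shape
    H, W = size
    Rh = _bilinear_matrix(H, h)
    Rw = _bilinear_matrix(W, w)
    out = np.einsum("oh,bchw,pw->bcop", Rh, x.data, Rw, optimize=True)

    def vjp(g):
        return (np.einsum("oh,bcop,pw->bchw", Rh, g, Rw, optimize=True),)

    return Tensor(out, _parents=(x,), _vjp=vjp)


# -------------------------------------------------------------------- loss

def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over a batch of integer labels (fused, stable)."""
    logits = astensor(logits)
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-300))

    def vjp(g):
        gl = p.copy()
        gl[np.arange(n), labels] -= 1.0
        return (gl * (float(g) / n),)

    return Tensor(nll.mean(), _parents=(logits,), _vjp=vjp)
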