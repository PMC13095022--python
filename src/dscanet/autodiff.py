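"""Reverse-mode automatic differentiation on NumPy arrays.

A compact define-by-run tensor engine: every operation builds a node in a
DAG whose backward closures accumulate gradients into their parents.
Only the primitives the segmentation network needs are implemented
(elementwise arithmetic, matmul, reductions, shape ops, 2-D convolution
and pooling, bilinear resampling, indexed gather).  All arithmetic is
float32 unless the caller supplies float64 inputs.

A global multiply-accumulate (MAC) counter can be switched on around a
forward pass to obtain the analytic operation count of matmuls and
convolutions; see :func:`count_macs`.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "is_grad_enabled",
    "count_macs",
    "mac_scope",
    "concatenate",
    "stack",
    "matmul",
    "conv2d",
    "avg_pool2d",
    "max_pool2d",
    "upsample_bilinear",
    "pad2d",
    "softmax",
    "relu",
    "gelu",
    "sigmoid",
    "exp",
    "log",
    "sqrt",
    "erf",
    "take",
    "where_constant",
]


class _State:
    grad_enabled: bool = True
    counting: bool = False
    macs: dict | None = None
    scope: list = []


@contextmanager
def no_grad():
    """Disable graph construction inside the block."""
    prev = _State.grad_enabled
    _State.grad_enabled = False
    try:
        yield
    finally:
        _State.grad_enabled = prev


def is_grad_enabled() -> bool:
    return _State.grad_enabled


@contextmanager
def count_macs(out: dict):
    """Accumulate matmul/conv multiply-accumulate counts into ``out``.

    Keys are scope paths (see :func:`mac_scope`); the special key
    ``"total"`` always holds the grand total.
    """
    prev = _State.counting, _State.macs
    _State.counting, _State.macs = True, out
    out.setdefault("total", 0)
    try:
        yield out
    finally:
        _State.counting, _State.macs = prev


@contextmanager
def suspend_macs():
    """Exclude the enclosed ops from MAC counting (e.g. weight reparameterization)."""
    prev = _State.counting
    _State.counting = False
    try:
        yield
    finally:
        _State.counting = prev


@contextmanager
def mac_scope(name: str):
    """Attribute MACs recorded inside the block to ``name``."""
    _State.scope.append(name)
    try:
        yield
    finally:
        _State.scope.pop()


def _record_macs(n: int):
    if _State.counting and _State.macs is not None:
        _State.macs["total"] += int(n)
        key = "/".join(_State.scope) if _State.scope else "unscoped"
        _State.macs[key] = _State.macs.get(key, 0) + int(n)


def _as_array(x):
    if isinstance(x, np.ndarray):
        return x if x.dtype in (np.float32, np.float64) else x.astype(np.float32)
    if isinstance(x, np.floating):  # reductions yield numpy scalars
        return np.asarray(x)
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), name: str | None = None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _State.grad_enabled
        self._backward = None
        self._parents = _parents if self.requires_grad else ()
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
                # free intermediate buffers early
                if t is not self:
                    t._backward = None

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True) if g.dtype != self.data.dtype else g.copy()
        else:
            self.grad += g

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, pow_(other, -1.0))
        return mul(self, 1.0 / np.asarray(other))

    def __rtruediv__(self, other):
        return mul(pow_(self, -1.0), other)

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def tensor(data, requires_grad: bool = False, name: str | None = None) -> Tensor:
    if isinstance(data, Tensor):
        return data
    return Tensor(data, requires_grad=requires_grad, name=name)


def _make(data, parents, backward) -> Tensor:
    req = _State.grad_enabled and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req, _parents=tuple(p for p in parents if p.requires_grad))
    if req:
        out._backward = backward
    return out


# -- elementwise ---------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    if not isinstance(b, Tensor):
        b_arr = np.asarray(b, dtype=a.data.dtype if isinstance(a, Tensor) else np.float32)
        a = tensor(a)
        data = a.data * b_arr

        def backward_s(g):
            a._accum(_unbroadcast(g * b_arr, a.shape))

        return _make(data, (a,), backward_s)
    a = tensor(a)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def pow_(a: Tensor, p: float) -> Tensor:
    a = tensor(a)
    data = a.data ** p

    def backward(g):
        a._accum(_unbroadcast(g * p * a.data ** (p - 1), a.shape))

    return _make(data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    a = tensor(a)
    data = np.exp(a.data)

    def backward(g):
        a._accum(g * data)

    return _make(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    a = tensor(a)
    data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return _make(data, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    a = tensor(a)
    data = np.sqrt(a.data)

    def backward(g):
        a._accum(g * 0.5 / np.maximum(data, 1e-12))

    return _make(data, (a,), backward)


def erf(a: Tensor) -> Tensor:
    a = tensor(a)
    data = _erf(a.data).astype(a.data.dtype)

    def backward(g):
        a._accum(g * (2.0 / np.sqrt(np.pi)) * np.exp(-a.data ** 2))

    return _make(data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    a = tensor(a)
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        a._accum(g * mask)

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def gelu(a: Tensor) -> Tensor:
    """Exact (erf-form) Gaussian error linear unit."""
    a = tensor(a)
    cdf = 0.5 * (1.0 + _erf(a.data / np.sqrt(2.0)))
    data = (a.data * cdf).astype(a.data.dtype)

    def backward(g):
        pdf = np.exp(-0.5 * a.data ** 2) / np.sqrt(2.0 * np.pi)
        a._accum(g * (cdf + a.data * pdf))

    return _make(data, (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    a = tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accum(g * mask)

    return _make(data, (a,), backward)


def where_constant(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select between two tensors with a constant boolean mask."""
    a, b = tensor(a), tensor(b)
    data = np.where(cond, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.where(cond, g, 0.0), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.where(cond, 0.0, g), b.shape))

    return _make(data, (a, b), backward)


# -- reductions ----------------------------------------------------------------

def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.shape))

    return _make(data, (a,), backward)


def mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = tensor(a)
    n = a.size if axis is None else np.prod([a.shape[i] for i in np.atleast_1d(axis)])
    return mul(sum_(a, axis, keepdims), 1.0 / float(n))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    a = tensor(a)
    shifted = a - Tensor(a.data.max(axis=axis, keepdims=True))
    e = exp(shifted)
    return e / sum_(e, axis=axis, keepdims=True)


# -- shape ops -----------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    a = tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(a.shape))

    return _make(data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    a = tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _make(data, (a,), backward)


def getitem(a: Tensor, idx) -> Tensor:
    a = tensor(a)
    data = a.data[idx]

    def backward(g):
        buf = np.zeros_like(a.data)
        np.add.at(buf, idx, g)
        a._accum(buf)

    return _make(data, (a,), backward)


def take(table: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows of ``table`` by an integer index array (embedding lookup)."""
    return getitem(table, idx)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return _make(data, tuple(tensors), backward)


def pad2d_replicate(a: Tensor, pad: int) -> Tensor:
    """Edge-replicate padding of the last two axes by ``pad`` on each side.

    Expressed as a gather so the backward pass accumulates border
    gradients onto their source pixels.
    """
    a = tensor(a)
    H, W = a.shape[-2], a.shape[-1]
    iy = np.clip(np.arange(-pad, H + pad), 0, H - 1)
    ix = np.clip(np.arange(-pad, W + pad), 0, W - 1)
    return getitem(a, (Ellipsis, iy[:, None], ix[None, :]))


def pad2d(a: Tensor, pad: tuple) -> Tensor:
    """Zero-pad the last two axes by (top, bottom, left, right)."""
    a = tensor(a)
    t, b, l, r = pad
    width = [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)]
    data = np.pad(a.data, width)
    H, W = a.shape[-2], a.shape[-1]

    def backward(g):
        sl = (Ellipsis, slice(t, t + H), slice(l, l + W))
        a._accum(g[sl])

    return _make(data, (a,), backward)


# -- matmul --------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = tensor(a), tensor(b)
    data = np.matmul(a.data, b.data)
    _record_macs(data.size * a.shape[-1])

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


# -- convolution / pooling -----------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    # x: (N, C, H, W) -> (N, C, kh, kw, OH, OW)
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, :, :]
    return win.transpose(0, 1, 4, 5, 2, 3)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation over (N, C, H, W) input.

    ``w`` has shape (Cout, Cin/groups, KH, KW).
    """
    x, w = tensor(x), tensor(w)
    N, C, H, W = x.shape
    Cout, Cg, KH, KW = w.shape
    if C != Cg * groups or Cout % groups:
        raise ValueError(
            f"conv2d channel mismatch: input {C}, weight {w.shape}, groups {groups}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    OH = (xp.shape[2] - KH) // stride + 1
    OW = (xp.shape[3] - KW) // stride + 1
    cols = _im2col(xp, KH, KW, stride)  # (N, C, KH, KW, OH, OW)
    cols = cols.reshape(N, groups, (C // groups) * KH * KW, OH * OW)
    wmat = w.data.reshape(groups, Cout // groups, (C // groups) * KH * KW)
    out = np.einsum("gok,ngkp->ngop", wmat, cols, optimize=True)
    out = out.reshape(N, Cout, OH, OW)
    _record_macs(N * Cout * OH * OW * (C // groups) * KH * KW)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g4 = g.reshape(N, groups, Cout // groups, OH * OW)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("ngop,ngkp->gok", g4, cols, optimize=True)
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            gcols = np.einsum("gok,ngop->ngkp", wmat, g4, optimize=True)
            gcols = gcols.reshape(N, C, KH, KW, OH, OW)
            gx = np.zeros_like(xp)
            for i in range(KH):
                for j in range(KW):
                    gx[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride] += gcols[:, :, i, j]
            if padding:
                gx = gx[:, :, padding:padding + H, padding:padding + W]
            x._accum(gx)

    return _make(out, parents, backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Average pooling with kernel = stride = ``k`` (dims must divide)."""
    x = tensor(x)
    N, C, H, W = x.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: spatial dims ({H},{W}) not divisible by {k}")
    r = x.data.reshape(N, C, H // k, k, W // k, k)
    data = r.mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(gx)

    return _make(data, (x,), backward)


def max_pool2d(x: Tensor, k: int) -> Tensor:
    """Max pooling with kernel = stride = ``k`` (dims must divide)."""
    x = tensor(x)
    N, C, H, W = x.shape
    if H % k or W % k:
        raise ValueError(f"max_pool2d: spatial dims ({H},{W}) not divisible by {k}")
    r = x.data.reshape(N, C, H // k, k, W // k, k)
    data = r.max(axis=(3, 5))
    mask = r == data[:, :, :, None, :, None]
    # break ties: keep only the first max per window
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // k, W // k, k * k)
    first = np.zeros_like(flat)
    np.put_along_axis(first, flat.argmax(axis=-1)[..., None], True, axis=-1)
    first = first.reshape(N, C, H // k, W // k, k, k).transpose(0, 1, 2, 4, 3, 5)

    def backward(g):
        gx = first * g[:, :, :, None, :, None]
        x._accum(gx.reshape(N, C, H, W))

    return _make(data, (x,), backward)


def _interp_matrix(n_in: int, n_out: int, dtype=np.float32) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centers)."""
    M = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    M[np.arange(n_out), lo] += 1 - frac
    M[np.arange(n_out), hi] += frac
    return M


def upsample_bilinear(x: Tensor, size: tuple) -> Tensor:
    """Bilinearly resample (N, C, H, W) to spatial ``size`` (half-pixel grid).

    Interpolation is excluded from the MAC count: the analytic convention
    covers convolutions, linear layers and attention matmuls only.
    """
    x = tensor(x)
    N, C, H, W = x.shape
    H2, W2 = size
    if (H, W) == (H2, W2):
        return x
    Mh = Tensor(_interp_matrix(H, H2, x.dtype))
    Mw = Tensor(_interp_matrix(W, W2, x.dtype))
    prev = _State.counting
    _State.counting = False
    try:
        # out[n,c] = Mh @ x[n,c] @ Mw.T  — expressed with autodiff matmuls
        y = matmul(Mh, x.reshape(N * C, H, W))
        y = matmul(y, transpose(Mw, (1, 0)))
    finally:
        _State.counting = prev
    return y.reshape(N, C, H2, W2)
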