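"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operation that produced
it; :meth:`Tensor.backward` runs the reverse topological sweep and
accumulates gradients into every leaf with ``requires_grad``.  The operation
set is exactly what the 1D convolutional models in this package need:
broadcast arithmetic, matmul, same-padded 1D convolution, pooling, nearest
upsampling, concatenation, reductions (sum/mean/max), elementwise
nonlinearities and log/exp.  All primitives are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        # python scalars wrap as float32 so they never promote a float32
        # graph to float64 (0-d arrays take part in NEP-50 dtype promotion);
        # numpy scalars (np.float64 subclasses float!) keep their dtype
        if isinstance(data, (np.ndarray, np.generic)):
            self.data = np.asarray(data)
        elif isinstance(data, (int, float)):
            self.data = np.asarray(data, dtype=np.float32)
        else:
            self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: Tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), Tensor(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, Tensor(-1.0)))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, pow_(_wrap(other), -1.0))

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __pow__(self, p):
        return pow_(self, p)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def item(self) -> float:
        return float(self.data)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in ts)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs(*parents):
        out._prev = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- arithmetic ------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))
    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))
    return _make(a.data * b.data, (a, b), backward)


def pow_(a: Tensor, p: float) -> Tensor:
    def backward(g):
        a._accum(g * p * np.power(a.data, p - 1))
    return _make(np.power(a.data, p), (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        a._accum(g / a.data)
    return _make(np.log(a.data), (a,), backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        a._accum(g * out_data)
    return _make(out_data, (a,), backward)


def abs_(a: Tensor) -> Tensor:
    def backward(g):
        a._accum(g * np.sign(a.data))
    return _make(np.abs(a.data), (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accum(g @ b.data.T)
        b._accum(a.data.T @ g)
    return _make(a.data @ b.data, (a, b), backward)


# -- shape ops -------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def backward(g):
        a._accum(g.reshape(old))
    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


# -- reductions ------------------------------------------------------------

def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    shape = a.data.shape

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, shape).astype(a.data.dtype))
    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        scale = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        scale = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(sum_(a, axis, keepdims), Tensor(1.0 / scale))


def max_(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    out_data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out_data)
    mask = mask / mask.sum(axis=axis, keepdims=True)  # ties share gradient

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(g * mask)
    return _make(out_data if keepdims else out_data.squeeze(axis), (a,), backward)


# -- nonlinearities --------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accum(g * mask)
    return _make(a.data * mask, (a,), backward)


def leaky_relu(a: Tensor, negative_slope: float = 0.2) -> Tensor:
    pos = a.data > 0
    scale = np.where(pos, 1.0, negative_slope)

    def backward(g):
        a._accum(g * scale)
    return _make(a.data * scale, (a,), backward)


def prelu(a: Tensor, slope: Tensor) -> Tensor:
    """Parametric ReLU; ``slope`` broadcasts over ``a`` (per-channel)."""
    pos = a.data > 0
    neg_part = np.where(pos, 0.0, a.data)

    def backward(g):
        a._accum(g * np.where(pos, 1.0, slope.data))
        slope._accum(_unbroadcast(g * neg_part, slope.data.shape))
    return _make(np.where(pos, a.data, slope.data * a.data), (a, slope), backward)


def sqrt(a: Tensor) -> Tensor:
    return pow_(a, 0.5)


# -- 1D convolution and resampling ----------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Same-padded, stride-1 1D convolution (cross-correlation).

    ``x``: (B, C_in, L); ``w``: (C_out, C_in, K) with K odd; ``b``: (C_out,).
    """
    B, Cin, L = x.data.shape
    Cout, Cin_w, K = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    if K % 2 == 0:
        raise ValueError("kernel size must be odd for same padding")
    p = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    # im2col: (B, L, Cin*K) contiguous, then one BLAS matmul
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,Cin,L,K) view
    col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * L, Cin * K)
    w2d = w.data.reshape(Cout, Cin * K)
    out = (col @ w2d.T).reshape(B, L, Cout).transpose(0, 2, 1)
    if b is not None:
        out = out + b.data[None, :, None]

    def backward(g):
        g2d = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * L, Cout)
        w._accum((g2d.T @ col).reshape(Cout, Cin, K))
        if b is not None:
            b._accum(g.sum(axis=(0, 2)))
        gcol = (g2d @ w2d).reshape(B, L, Cin, K).transpose(0, 2, 1, 3)  # (B,Cin,L,K)
        gxp = np.zeros_like(xp)
        for k in range(K):
            gxp[:, :, k:k + L] += gcol[:, :, :, k]
        x._accum(gxp[:, :, p:p + L])

    parents = (x, w, b) if b is not None else (x, w)
    return _make(out, parents, backward)


def avg_pool1d(x: Tensor, k: int = 2) -> Tensor:
    B, C, L = x.data.shape
    if L % k:
        raise ValueError(f"length {L} not divisible by pool size {k}")
    out = x.data.reshape(B, C, L // k, k).mean(axis=3)

    def backward(g):
        x._accum(np.repeat(g / k, k, axis=2))
    return _make(out, (x,), backward)


def upsample_nearest1d(x: Tensor, k: int = 2) -> Tensor:
    B, C, L = x.data.shape

    def backward(g):
        x._accum(g.reshape(B, C, L, k).sum(axis=3))
    return _make(np.repeat(x.data, k, axis=2), (x,), backward)


def global_avg_pool1d(x: Tensor) -> Tensor:
    return mean(x, axis=2)


# -- composite helpers -----------------------------------------------------

def logsumexp(logits: Tensor, axis: int = 1) -> Tensor:
    m = Tensor(logits.data.max(axis=axis, keepdims=True))  # constant shift
    return log(sum_(exp(logits - m), axis=axis)) + reshape(m, (m.data.shape[0],))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
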