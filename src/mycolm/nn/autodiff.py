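"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations needed by the sequence models in this
package: broadcasting arithmetic, (batched) matmul, reductions, shape ops,
1-D window unfolding for convolutions, length-2 max pooling and nearest
neighbour upsampling, and the usual nonlinearities.  Gradients accumulate
into ``Tensor.grad`` after calling :meth:`Tensor.backward` on a scalar.

Computation defaults to float32 for speed; set ``DTYPE`` to float64 before
building tensors when exact gradients are needed (e.g. finite-difference
checks).
"""

from __future__ import annotations

import math

import numpy as np

DTYPE = np.float32


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_norm_stats")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # convenience operators (constants are promoted)
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _const(-1.0)))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, _const(-1.0)))

    def __neg__(self):
        return mul(self, _const(-1.0))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _const(v):
    return Tensor(np.asarray(v, dtype=DTYPE))


def _needs(*tensors):
    return any(t.requires_grad for t in tensors)


def _unbroadcast(g, shape):
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


def _make(data, parents, backward):
    req = _needs(*[p for p in parents if isinstance(p, Tensor)])
    return Tensor(data, requires_grad=req, parents=parents if req else (),
                  backward=backward if req else None)


# ---------------------------------------------------------------------------
# arithmetic

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), bwd)


def powc(a: Tensor, p: float) -> Tensor:
    out_data = a.data ** p

    def bwd(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), bwd)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).astype(DTYPE))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).astype(DTYPE))

    return _make(out_data, (a,), bwd)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), _const(1.0 / n))


# ---------------------------------------------------------------------------
# shape ops

def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def bwd(g):
        a._accumulate(g.reshape(a.shape))

    return _make(out_data, (a,), bwd)


def transpose(a: Tensor, axes) -> Tensor:
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bwd(g):
        a._accumulate(g.transpose(inv))

    return _make(out_data, (a,), bwd)


def slice_axis1(a: Tensor, start: int, stop: int) -> Tensor:
    """Crop positions [start, stop) along axis 1 of a (B, L, C) tensor."""
    out_data = a.data[:, start:stop]

    def bwd(g):
        full = np.zeros_like(a.data)
        full[:, start:stop] = g
        a._accumulate(full)

    return _make(out_data, (a,), bwd)


# ---------------------------------------------------------------------------
# nonlinearities

def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bwd(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), bwd)


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def bwd(g):
        a._accumulate(g / a.data)

    return _make(out_data, (a,), bwd)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def bwd(g):
        a._accumulate(g * mask)

    return _make(out_data, (a,), bwd)


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a: Tensor) -> Tensor:
    from scipy.special import erf

    phi = 0.5 * (1.0 + erf(a.data / _SQRT2))
    out_data = a.data * phi

    def bwd(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * a.data ** 2)
        a._accumulate(g * (phi + a.data * pdf))

    return _make(out_data, (a,), bwd)


def softplus(a: Tensor) -> Tensor:
    out_data = np.logaddexp(0.0, a.data)

    def bwd(g):
        a._accumulate(g / (1.0 + np.exp(-a.data)))

    return _make(out_data, (a,), bwd)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - dot))

    return _make(out_data, (a,), bwd)


def affine_norm(x: Tensor, gamma: Tensor, beta: Tensor, axes,
                eps: float = 1e-5, stats=None) -> Tensor:
    """Fused normalization: y = gamma * (x - mu) / sqrt(var + eps) + beta.

    With ``stats=None`` the statistics are computed over ``axes`` and
    differentiated through (batch-norm / layer-norm training path); with
    ``stats=(mean, var)`` they are treated as constants (inference path).
    ``gamma``/``beta`` are per-channel (last axis).
    """
    if stats is None:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        batch_stats = True
    else:
        mu, var = stats
        batch_stats = False
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data

    def bwd(g):
        red = tuple(range(out_data.ndim - 1))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=red))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=red))
        if x.requires_grad:
            gg = g * gamma.data
            if batch_stats:
                m1 = gg.mean(axis=axes, keepdims=True)
                m2 = (gg * xhat).mean(axis=axes, keepdims=True)
                x._accumulate((gg - m1 - xhat * m2) * inv)
            else:
                x._accumulate(gg * inv)

    out = _make(out_data, (x, gamma, beta), bwd)
    out._norm_stats = (mu, var)        # exposed for running-average updates
    return out


def dropout(a: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or rate <= 0.0:
        return a
    keep = 1.0 - rate
    mask = (rng.random(a.shape) < keep) / keep
    return mul(a, Tensor(mask))


# ---------------------------------------------------------------------------
# sequence ops (axis 1 = position, axis 2 = channels)

def unfold1d(a: Tensor, kernel: int) -> Tensor:
    """(B, L, C) -> (B, L, K, C) sliding windows with same zero padding."""
    B, L, C = a.shape
    left = (kernel - 1) // 2
    right = kernel - 1 - left
    padded = np.pad(a.data, ((0, 0), (left, right), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(padded, kernel, axis=1)
    # sliding_window_view yields (B, L, C, K); put K before C
    out_data = np.ascontiguousarray(windows.transpose(0, 1, 3, 2))

    def bwd(g):
        gx = np.zeros_like(padded)
        for k in range(kernel):
            gx[:, k:k + L] += g[:, :, k, :]
        a._accumulate(gx[:, left:left + L])

    return _make(out_data, (a,), bwd)


def maxpool2(a: Tensor) -> Tensor:
    B, L, C = a.shape
    if L % 2:
        raise ValueError("maxpool2 requires even length")
    pairs = a.data.reshape(B, L // 2, 2, C)
    idx = pairs.argmax(axis=2)
    out_data = np.take_along_axis(pairs, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def bwd(g):
        gp = np.zeros_like(pairs)
        np.put_along_axis(gp, idx[:, :, None, :], g[:, :, None, :], axis=2)
        a._accumulate(gp.reshape(B, L, C))

    return _make(out_data, (a,), bwd)


def upsample2(a: Tensor) -> Tensor:
    """Nearest-neighbour doubling of the position axis."""
    B, L, C = a.shape
    out_data = np.repeat(a.data, 2, axis=1)

    def bwd(g):
        a._accumulate(g.reshape(B, L, 2, C).sum(axis=2))

    return _make(out_data, (a,), bwd)


def stack_rows(tensors) -> Tensor:
    """Stack scalar tensors into a 1-D tensor (used for per-window losses)."""
    out_data = np.array([t.data.reshape(()) for t in tensors], dtype=DTYPE)

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.asarray(g[i]).reshape(t.shape))

    return _make(out_data, tuple(tensors), bwd)
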