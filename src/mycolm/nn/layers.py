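"""Neural network layers built on the autodiff engine.

Layers follow the channels-last convention: activations are (batch,
position, channels).  Each layer exposes ``params()`` returning its
trainable tensors; ``Module`` aggregates them for the optimizer.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: collects parameters from attributes recursively."""

    train_mode: bool = True

    def params(self):
        out = []
        seen = set()
        for attr in vars(self).values():
            for p in _collect(attr):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def set_train(self, mode: bool):
        self.train_mode = mode
        for attr in vars(self).values():
            for m in _collect_modules(attr):
                m.set_train(mode)

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))


def _collect(obj):
    if isinstance(obj, Tensor) and obj.requires_grad:
        yield obj
    elif isinstance(obj, Module):
        yield from obj.params()
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect(item)


def _collect_modules(obj):
    if isinstance(obj, Module):
        yield obj
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect_modules(item)


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int):
        self.w = _param(rng, (n_in, n_out), 1.0 / np.sqrt(n_in))
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.w), self.b)


class Conv1D(Module):
    """Same-padded 1-D convolution over (B, L, C_in) -> (B, L, C_out)."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int):
        self.kernel = kernel
        self.c_in = c_in
        self.w = _param(rng, (kernel * c_in, c_out), 1.0 / np.sqrt(kernel * c_in))
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        cols = ad.reshape(ad.unfold1d(x, self.kernel), (B, L, self.kernel * C))
        return ad.add(ad.matmul(cols, self.w), self.b)


class SeparableConv1D(Module):
    """Depthwise (per-channel) convolution followed by a pointwise mix."""

    def __init__(self, rng, channels: int, kernel: int):
        self.kernel = kernel
        self.dw = _param(rng, (kernel, channels), 1.0 / np.sqrt(kernel))
        self.pw = Dense(rng, channels, channels)

    def __call__(self, x: Tensor) -> Tensor:
        windows = ad.unfold1d(x, self.kernel)          # (B, L, K, C)
        depth = ad.tsum(ad.mul(windows, self.dw), axis=2)
        return self.pw(depth)


class BatchNorm1D(Module):
    """Normalizes over (batch, position); keeps running stats for eval."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.train_mode:
            out = ad.affine_norm(x, self.gamma, self.beta, axes=(0, 1),
                                 eps=self.eps)
            mu, var = out._norm_stats
            m = self.momentum
            self.run_mean = m * self.run_mean + (1 - m) * mu.ravel()
            self.run_var = m * self.run_var + (1 - m) * var.ravel()
            return out
        return ad.affine_norm(x, self.gamma, self.beta, axes=(0, 1),
                              eps=self.eps,
                              stats=(self.run_mean[None, None, :],
                                     self.run_var[None, None, :]))


class LayerNorm(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ad.affine_norm(x, self.gamma, self.beta, axes=-1, eps=self.eps)


class MultiHeadSelfAttention(Module):
    def __init__(self, rng, dim: int, n_heads: int, key_dim: int):
        self.n_heads = n_heads
        self.key_dim = key_dim
        inner = n_heads * key_dim
        self.wq = Dense(rng, dim, inner)
        self.wk = Dense(rng, dim, inner)
        self.wv = Dense(rng, dim, inner)
        self.wo = Dense(rng, inner, dim)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        x = ad.reshape(x, (B, L, self.n_heads, self.key_dim))
        return ad.transpose(x, (0, 2, 1, 3))           # (B, H, L, dk)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        q = self._split(self.wq(x), B, L)
        k = self._split(self.wk(x), B, L)
        v = self._split(self.wv(x), B, L)
        scores = ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))),
                        Tensor(1.0 / np.sqrt(self.key_dim)))
        att = ad.softmax(scores, axis=-1)
        out = ad.matmul(att, v)                        # (B, H, L, dk)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)),
                         (B, L, self.n_heads * self.key_dim))
        return self.wo(out)

    def attention_map(self, x: Tensor) -> np.ndarray:
        """Forward-only (L x L) attention weights averaged over heads."""
        B, L, _ = x.shape
        q = self._split(self.wq(x), B, L)
        k = self._split(self.wk(x), B, L)
        scores = ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))),
                        Tensor(1.0 / np.sqrt(self.key_dim)))
        return ad.softmax(scores, axis=-1).data.mean(axis=(0, 1))


class TransformerBlock(Module):
    """Pre-norm self-attention + position-wise feed-forward, both residual."""

    def __init__(self, rng, dim: int, n_heads: int, key_dim: int,
                 ffn_inner: int, dropout: float = 0.05):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(rng, dim, n_heads, key_dim)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Dense(rng, dim, ffn_inner)
        self.ff2 = Dense(rng, ffn_inner, dim)
        self.dropout = dropout

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        a = self.attn(self.ln1(x))
        x = ad.add(x, ad.dropout(a, self.dropout, rng, self.train_mode))
        h = self.ff2(ad.relu(self.ff1(self.ln2(x))))
        return ad.add(x, ad.dropout(h, self.dropout, rng, self.train_mode))
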