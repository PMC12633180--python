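"""Adam optimizer with global-norm gradient clipping and linear warmup."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.7,
                 beta2: float = 0.9, eps: float = 1e-8,
                 clipnorm: float = 0.1, warmup_steps: int = 0):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clipnorm = clipnorm
        self.warmup_steps = warmup_steps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def _effective_lr(self) -> float:
        if self.warmup_steps > 0 and self.t < self.warmup_steps:
            return self.lr * (self.t + 1) / self.warmup_steps
        return self.lr

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clipnorm is not None and self.clipnorm > 0:
            total = float(np.sqrt(sum(float((g ** 2).sum()) for g in grads)))
            if total > self.clipnorm:
                scale = self.clipnorm / (total + 1e-12)
                grads = [g * scale for g in grads]
        lr = self._effective_lr()
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
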