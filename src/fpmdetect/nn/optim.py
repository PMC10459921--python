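"""Optimizers for the Tensor engine."""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .tensor import Tensor

__all__ = ["SGD", "AdamW", "clip_grad_norm"]


def clip_grad_norm(params: Sequence[Tensor], max_norm: float) -> float:
    total = np.sqrt(
        sum(float((p.grad**2).sum()) for p in params if p.grad is not None)
    )
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


class SGD:
    def __init__(self, params: Sequence[Tensor], lr: float, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-4,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        lrs: Optional[List[float]] = None,
    ):
        self.params = list(params)
        self.lr = lr
        self.lrs = lrs  # optional per-parameter learning rates
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            lr = self.lrs[i] if self.lrs is not None else self.lr
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            if self.weight_decay:
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
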