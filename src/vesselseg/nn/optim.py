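"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["Adam", "MultiStepLR"]


class Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params: list[Parameter] = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = (p.data.astype(np.float64) - update).astype(p.data.dtype)


class MultiStepLR:
    """Multiply the optimiser's learning rate by ``factor`` at given epochs."""

    def __init__(self, optimizer: Adam, milestones, factor: float = 0.1):
        self.optimizer = optimizer
        self.milestones = set(int(m) for m in milestones)
        self.factor = float(factor)

    def step(self, epoch: int) -> None:
        """Call once at the START of ``epoch`` (0-based)."""
        if epoch in self.milestones:
            self.optimizer.lr *= self.factor
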