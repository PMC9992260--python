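"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .core import Tensor

__all__ = ["Adam", "StepLR"]


class Adam:
    """Adam with optional AMSGrad variant.

    Defaults mirror the common convention: betas (0.9, 0.999), eps 1e-8.
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, amsgrad: bool = False):
        self.params: list[Tensor] = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.amsgrad = amsgrad
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._vhat = ([np.zeros_like(p.data) for p in self.params]
                      if amsgrad else None)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / bc1
            if self.amsgrad:
                np.maximum(self._vhat[i], self._v[i], out=self._vhat[i])
                v_hat = self._vhat[i] / bc2
            else:
                v_hat = self._v[i] / bc2
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class StepLR:
    """Multiply the optimiser lr by `gamma` every `step_size` calls."""

    def __init__(self, optimizer: Adam, step_size: int, gamma: float):
        self.optimizer = optimizer
        self.step_size = int(step_size)
        self.gamma = float(gamma)
        self.base_lr = optimizer.lr
        self.count = 0

    def step(self) -> None:
        self.count += 1
        self.optimizer.lr = self.base_lr * self.gamma ** (self.count // self.step_size)

    @property
    def lr(self) -> float:
        return self.optimizer.lr
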