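"""Optimizers and schedulers for the NumPy autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` when the monitored loss has
    not improved for ``patience`` epochs; floor at ``min_lr``."""

    def __init__(
        self,
        optimizer: Adam,
        patience: int = 5,
        factor: float = 0.1,
        min_lr: float = 1e-6,
    ):
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> None:
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
            return
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
            self.bad_epochs = 0
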