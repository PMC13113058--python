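"""Optimizers and learning-rate scheduling for the autograd stack."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to grads."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Multiply the optimizer lr by `factor` after `patience` epochs without
    improvement of the monitored quantity (lower is better)."""

    def __init__(self, optimizer: Adam, factor: float = 0.35, patience: int = 10,
                 min_lr: float = 1e-7):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.num_bad = 0
        self.events: list[int] = []  # epochs at which lr was reduced
        self._epoch = 0

    def step(self, metric: float) -> None:
        self._epoch += 1
        if metric < self.best - 1e-12:
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad > self.patience:
                new_lr = max(self.optimizer.lr * self.factor, self.min_lr)
                if new_lr < self.optimizer.lr:
                    self.optimizer.lr = new_lr
                    self.events.append(self._epoch)
                self.num_bad = 0
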