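"""SGD with momentum plus the two learning-rate schedules the trainer offers."""

from __future__ import annotations

import math

import numpy as np


class SGD:
    """Stochastic gradient descent with classical momentum and decoupled
    L2 weight decay applied to the gradient (the convention of the
    detector family this package follows)."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.937,
                 weight_decay: float = 0.0005):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class CosineWarmRestarts:
    """Cosine annealing with warm restarts: within each cycle of length
    T, lr goes from lr0 to lr_min on a half cosine; cycles restart with
    period multiplied by t_mult."""

    def __init__(self, lr0: float, t0: int = 10, t_mult: int = 2,
                 lr_min: float = 1e-4):
        self.lr0, self.t0, self.t_mult, self.lr_min = lr0, t0, t_mult, lr_min

    def lr(self, epoch: int) -> float:
        t, period = epoch, self.t0
        while t >= period:
            t -= period
            period *= self.t_mult
        cos = 0.5 * (1.0 + math.cos(math.pi * t / period))
        return self.lr_min + (self.lr0 - self.lr_min) * cos


class ExponentialDecay:
    """lr(e) = lr0 * alpha**e."""

    def __init__(self, lr0: float, alpha: float = 0.95):
        self.lr0, self.alpha = lr0, alpha

    def lr(self, epoch: int) -> float:
        return self.lr0 * self.alpha ** epoch
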