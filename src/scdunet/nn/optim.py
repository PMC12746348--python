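"""Optimisation: Adam and the cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "cosine_annealing_lr"]


class Adam:
    """Adam with bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_annealing_lr(step: int, *, lr_max: float, lr_min: float, period: int) -> float:
    """Cosine decay from `lr_max` to `lr_min` over `period` steps, then flat.

    Matches a schedule that starts at the initial learning rate and is
    bounded below by the floor at every step.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    frac = min(step, period) / period
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + np.cos(np.pi * frac))
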