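"""Adam optimizer with a piecewise-constant learning-rate schedule."""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= F32(self.lr) * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def piecewise_lr(initial_lr: float, epoch: int, drop_every: int = 30,
                 factor: float = 0.1) -> float:
    """lr(e) = initial * factor^floor(e / drop_every), epochs counted from 0."""
    return initial_lr * factor ** (epoch // drop_every)
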