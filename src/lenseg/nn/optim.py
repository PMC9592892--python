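"""SGD with momentum and decoupled-from-nothing classic weight decay, plus
the learning-rate schedules used for training."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "poly_lr", "step_lr", "cosine_lr"]


class SGD:
    """Stochastic gradient descent with heavy-ball momentum.

    Weight decay is the classic L2 form: the decay term is added to the
    gradient before the momentum update.
    """

    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
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


def poly_lr(base_lr: float, step: int, total_steps: int, power: float = 0.9) -> float:
    """Polynomial decay, the DeepLab-family default."""
    frac = min(step, total_steps) / max(total_steps, 1)
    return base_lr * (1.0 - frac) ** power


def step_lr(base_lr: float, step: int, total_steps: int, drops: int = 3, factor: float = 0.1) -> float:
    stage = int(drops * min(step, total_steps - 1) / max(total_steps, 1))
    return base_lr * factor**stage


def cosine_lr(base_lr: float, step: int, total_steps: int) -> float:
    frac = min(step, total_steps) / max(total_steps, 1)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * frac))
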