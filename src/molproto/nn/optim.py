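"""Adam optimiser with L2 weight decay and a cosine-annealing schedule."""

from __future__ import annotations

import math

import numpy as np

from .layers import ParameterStore

__all__ = ["Adam", "cosine_annealing"]


class Adam:
    """Adam with the conventional coupled L2 weight decay (decay added to the
    gradient before the moment updates, as in the reference implementations).
    """

    def __init__(self, store: ParameterStore, lr: float = 8e-5,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.store = store
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in store.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in store.items()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.store.items():
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m = self._m[k] = b1 * self._m[k] + (1 - b1) * g
            v = self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            p.data = p.data - lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_annealing(lr0: float, epoch: int, total_epochs: int,
                     lr_min: float = 0.0) -> float:
    """Learning rate at ``epoch`` (0-based) under cosine annealing."""
    if total_epochs <= 1:
        return lr0
    frac = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * frac))
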