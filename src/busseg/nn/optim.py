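"""Optimizers operating in place on (param, grad) array pairs."""

from __future__ import annotations

import numpy as np

__all__ = ["RMSprop", "SGDMomentum", "make_optimizer"]


class RMSprop:
    """RMSprop: divide the step by a running RMS of recent gradients."""

    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._cache: dict[int, np.ndarray] = {}

    def step(self, params) -> None:
        for w, g in params:
            c = self._cache.get(id(w))
            if c is None:
                c = self._cache[id(w)] = np.zeros_like(w)
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            w -= self.lr * g / (np.sqrt(c) + self.eps)


class SGDMomentum:
    """Classical momentum SGD (velocity accumulation)."""

    def __init__(self, lr: float = 0.01, momentum: float = 0.99):
        self.lr, self.momentum = lr, momentum
        self._vel: dict[int, np.ndarray] = {}

    def step(self, params) -> None:
        for w, g in params:
            v = self._vel.get(id(w))
            if v is None:
                v = self._vel[id(w)] = np.zeros_like(w)
            v *= self.momentum
            v -= self.lr * g
            w += v


def make_optimizer(name: str, lr: float, momentum: float = 0.99):
    name = name.lower()
    if name == "rmsprop":
        return RMSprop(lr=lr)
    if name == "sgd":
        return SGDMomentum(lr=lr, momentum=momentum)
    raise ValueError(f"unknown optimizer {name!r}")
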