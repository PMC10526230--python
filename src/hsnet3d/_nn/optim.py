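"""Optimizers, the triangular cyclical learning rate, and weight averaging."""

from __future__ import annotations

import numpy as np


class Optimizer:
    """Updates a named-parameter dict in place from a matching gradient dict."""

    def __init__(self, params: dict):
        self.params = params

    def step(self, grads: dict, lr: float) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params: dict, momentum: float = 0.0):
        super().__init__(params)
        self.momentum = momentum
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()} if momentum else None

    def step(self, grads, lr):
        for k, p in self.params.items():
            g = grads[k]
            if self.velocity is not None:
                v = self.velocity[k]
                v *= self.momentum
                v -= lr * g
                p += v
            else:
                p -= lr * g


class Adam(Optimizer):
    def __init__(self, params: dict, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        super().__init__(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)


class RMSProp(Optimizer):
    def __init__(self, params: dict, rho: float = 0.9, eps: float = 1e-7):
        super().__init__(params)
        self.rho, self.eps = rho, eps
        self.sq = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads, lr):
        for k, p in self.params.items():
            g = grads[k]
            self.sq[k] = self.rho * self.sq[k] + (1 - self.rho) * g * g
            p -= lr * g / (np.sqrt(self.sq[k]) + self.eps)


OPTIMIZERS = {"sgd": SGD, "adam": Adam, "rmsprop": RMSProp}


def make_optimizer(name: str, params: dict, momentum: float = 0.9) -> Optimizer:
    name = name.lower()
    if name not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    if name == "sgd":
        return SGD(params, momentum=momentum)
    return OPTIMIZERS[name](params)


def clr_schedule(iteration: int, base_lr: float, max_lr: float,
                 step_size: int) -> float:
    """Triangular cyclical learning rate.

    Rises linearly from ``base_lr`` at iteration 0 to ``max_lr`` at
    ``step_size`` iterations, falls back linearly to ``base_lr`` at
    ``2 * step_size``, and repeats with that period (no amplitude decay).
    """
    if base_lr > max_lr:
        raise ValueError("base_lr must not exceed max_lr")
    if step_size < 1:
        raise ValueError("step_size must be >= 1")
    cycle_pos = iteration % (2 * step_size)
    frac = cycle_pos / step_size
    if frac > 1.0:
        frac = 2.0 - frac
    return base_lr + (max_lr - base_lr) * frac


def swa_update(w_swa: dict | None, n_models: int, w: dict) -> dict:
    """Fold one more weight snapshot into a running stochastic weight average.

    Every tensor becomes ``(w_swa * n_models + w) / (n_models + 1)``; with
    ``n_models == 0`` (or no average yet) the result is a copy of ``w``.
    """
    if n_models < 0:
        raise ValueError("n_models must be >= 0")
    if n_models == 0 or w_swa is None:
        return {k: v.copy() for k, v in w.items()}
    if set(w_swa) != set(w):
        raise KeyError("weight name sets differ between the average and the snapshot")
    return {k: (w_swa[k] * n_models + w[k]) / (n_models + 1) for k in w}
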