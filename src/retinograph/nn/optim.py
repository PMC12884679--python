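"""Gradient-descent optimisers for lists of Tensors."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "SGD", "make_optimizer"]


class Adam:
    """Adaptive moment estimation with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.vel = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.vel[i] = self.momentum * self.vel[i] - self.lr * p.grad
            p.data += self.vel[i]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def make_optimizer(tag: str, params: list[Tensor], lr: float):
    if tag == "adam":
        return Adam(params, lr=lr)
    if tag == "sgd":
        return SGD(params, lr=lr)
    raise ValueError(f"unknown optimiser {tag!r} (expected 'adam' or 'sgd')")
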