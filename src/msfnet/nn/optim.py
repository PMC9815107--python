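"""Optimizers. Adam is the default for all training in this package."""

from __future__ import annotations

from typing import Iterable, List

import numpy as np

from .modules import Parameter


class Adam:
    """Adam with the standard bias-corrected moment estimates.

    Defaults (beta1=0.9, beta2=0.999, eps=1e-8) follow common practice; the
    learning rate is the run-level knob.
    """

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params: List[Parameter] = list(params)
        if not self.params:
            raise ValueError("no parameters to optimize")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)


class SGD:
    """Plain SGD with optional momentum; used in a few tests as a baseline."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-2, momentum: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum = lr, momentum
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.buf[i] = self.momentum * self.buf[i] + p.grad
            p.data = p.data - self.lr * self.buf[i]
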