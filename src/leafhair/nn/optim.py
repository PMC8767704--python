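"""First-order optimizers over :class:`~leafhair.nn.layers.Parameter` lists."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["SGD", "Adam", "AdamW", "RMSProp", "make_optimizer", "OPTIMIZERS"]


class Optimizer:
    def __init__(self, params: list[Parameter], lr: float):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float, momentum: float = 0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self._vel = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if self.momentum:
                v *= self.momentum
                v += p.grad
                p.data -= self.lr * v
            else:
                p.data -= self.lr * p.grad


class Adam(Optimizer):
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def _update(self, p: Parameter, m: np.ndarray, v: np.ndarray) -> np.ndarray:
        m *= self.b1
        m += (1 - self.b1) * p.grad
        v *= self.b2
        v += (1 - self.b2) * p.grad**2
        mhat = m / (1 - self.b1**self.t)
        vhat = v / (1 - self.b2**self.t)
        return self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            p.data -= self._update(p, m, v)


class AdamW(Adam):
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        super().__init__(params, lr, betas, eps)
        self.weight_decay = weight_decay

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self._update(p, m, v)


class RMSProp(Optimizer):
    def __init__(self, params, lr: float, alpha: float = 0.99, eps: float = 1e-8):
        super().__init__(params, lr)
        self.alpha = alpha
        self.eps = eps
        self._sq = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, s in zip(self.params, self._sq):
            s *= self.alpha
            s += (1 - self.alpha) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)


OPTIMIZERS = {"SGD": SGD, "Adam": Adam, "AdamW": AdamW, "RMSProp": RMSProp}


def make_optimizer(name: str, params: list[Parameter], lr: float) -> Optimizer:
    if name not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    return OPTIMIZERS[name](params, lr)
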