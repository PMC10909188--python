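"""Momentum SGD with the Nesterov flag, matching the common DL convention:

    v <- mu * v + g            (g includes weight decay)
    step = g + mu * v          if nesterov else v
    w <- w - lr * step
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["SGD"]


class SGD:
    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9,
                 nesterov: bool = True, weight_decay: float = 0.0):
        if nesterov and momentum <= 0:
            raise ValueError("nesterov momentum requires momentum > 0")
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.nesterov = bool(nesterov)
        self.weight_decay = float(weight_decay)
        self._velocity: list[np.ndarray | None] = [None] * len(self.params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            if self.momentum:
                if self._velocity[i] is None:
                    self._velocity[i] = g.astype(p.data.dtype, copy=True)
                else:
                    self._velocity[i] *= self.momentum
                    self._velocity[i] += g
                step = g + self.momentum * self._velocity[i] if self.nesterov else self._velocity[i]
            else:
                step = g
            p.data -= self.lr * step
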