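"""Mini-batch SGD with momentum and decoupled-from-nothing L2 weight decay.

The update matches the classic segmentation-training recipe: the weight
decay term is added to the gradient, a momentum buffer accumulates it,
and the step is ``w -= lr * v``.  The learning rate is supplied per
step so a poly schedule can drive it.
"""

from __future__ import annotations

import numpy as np

from .core import Parameter

__all__ = ["SGD"]


class SGD:
    def __init__(self, params: list[Parameter], momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def state_dict(self) -> dict:
        return {f"velocity:{i}": v.copy() for i, v in enumerate(self.velocity)}

    def load_state_dict(self, state: dict) -> None:
        for i, v in enumerate(self.velocity):
            key = f"velocity:{i}"
            if key in state:
                v[...] = state[key]
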