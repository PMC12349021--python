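"""Adam optimizer for :class:`~mbmstfnet.nn.layers.Parameter` lists."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(self, parameters, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.parameters = list(parameters)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.parameters]
        self.v = [np.zeros_like(p.value) for p in self.parameters]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        # algebraically identical to the textbook update with both
        # bias corrections, but with scalar factors hoisted out
        alpha = self.lr * np.sqrt(bc2) / bc1
        eps_t = self.eps * np.sqrt(bc2)
        for p, m, v in zip(self.parameters, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            denom = np.sqrt(v)
            denom += eps_t
            np.divide(m, denom, out=denom)
            denom *= alpha
            p.value -= denom

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad[...] = 0.0
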