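"""Adam optimizer for the autograd tensors."""

from __future__ import annotations

from typing import Iterable, List

import numpy as np

from .tensor import Tensor


class Adam:
    """Adaptive-moment estimation with the standard bias correction.

    Parameters with ``requires_grad=False`` (frozen) or without a gradient
    are skipped.
    """

    def __init__(self, params: Iterable[Tensor], lr: float = 2e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params: List[Tensor] = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
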