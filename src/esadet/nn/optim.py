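"""AdamW optimizer (decoupled weight decay)."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class AdamW:
    """AdamW with per-group decoupled weight decay.

    `groups` is a list of dicts: {"params": [Tensor...], "weight_decay": float}.
    A plain list of tensors is treated as one group with the default decay.
    """

    def __init__(self, groups, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        if groups and isinstance(groups[0], Tensor):
            groups = [{"params": list(groups), "weight_decay": weight_decay}]
        self.groups = groups
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}
        for g in self.groups:
            for p in g["params"]:
                self._m[id(p)] = np.zeros_like(p.data)
                self._v[id(p)] = np.zeros_like(p.data)

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for g in self.groups:
            wd = g.get("weight_decay", 0.0)
            for p in g["params"]:
                if p.grad is None:
                    continue
                m = self._m[id(p)]
                v = self._v[id(p)]
                m *= self.b1
                m += (1.0 - self.b1) * p.grad
                v *= self.b2
                v += (1.0 - self.b2) * p.grad ** 2
                if wd:
                    p.data *= (1.0 - self.lr * wd)
                p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
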