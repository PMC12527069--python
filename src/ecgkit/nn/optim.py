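"""Adam and AdamW optimizers operating on named parameter dictionaries."""

from __future__ import annotations

import numpy as np

from .._exceptions import ValidationError


class Adam:
    """Adam with bias-corrected first/second moments."""

    def __init__(self, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValidationError(f"learning rate must be >= 0, got {lr}")
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def _update(self, key, p, g):
        m = self._m.setdefault(key, np.zeros_like(p))
        v = self._v.setdefault(key, np.zeros_like(p))
        m += (1 - self.b1) * (g - m)
        v += (1 - self.b2) * (g * g - v)
        mhat = m / (1 - self.b1 ** self.t)
        vhat = v / (1 - self.b2 ** self.t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for key, p in params.items():
            self._update(key, p, grads[key])


class AdamW(Adam):
    """Adam with decoupled weight decay (applied to weight matrices only)."""

    def __init__(self, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        super().__init__(lr, betas, eps)
        self.weight_decay = weight_decay

    def step(self, params, grads):
        self.t += 1
        for key, p in params.items():
            if self.weight_decay and not key.endswith(".b"):
                p -= self.lr * self.weight_decay * p
            self._update(key, p, grads[key])


def make_optimizer(name: str, lr: float, **kwargs) -> Adam:
    name = name.lower()
    if name == "adam":
        return Adam(lr=lr, **kwargs)
    if name == "adamw":
        return AdamW(lr=lr, **kwargs)
    raise ValidationError(f"unknown optimizer {name!r} (adam | adamw)")
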