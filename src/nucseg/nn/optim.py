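"""Adam optimizer with decoupled weight decay."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with decoupled (AdamW-style) weight decay.

    The decay coefficient multiplies the parameter directly each step,
    scaled by the current learning rate, rather than being folded into
    the gradient. Bias vectors are exempt from decay.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 3e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr: float | None = None) -> None:
        if lr is not None:
            self.lr = lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for key, p in self.params.items():
            g = grads[key]
            m = self.m[key]
            v = self.v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            if self.weight_decay and p.ndim > 1:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * update
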