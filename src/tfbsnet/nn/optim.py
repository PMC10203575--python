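"""Adam optimizer over (weight, gradient) pairs exposed by the network."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in self.pairs]
        self.v = [np.zeros_like(w) for w, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for i, (w, g) in enumerate(self.pairs):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            w -= (self.lr * (self.m[i] / corr1) / (np.sqrt(self.v[i] / corr2) + self.eps)).astype(
                w.dtype
            )
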