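"""Adam optimizer over a set of parameter-carrying layers."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.layers = list(layers)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1.0 - b1) * g
                v[k] = b2 * v[k] + (1.0 - b2) * g * g
                step = self.lr * (m[k] / bias1) / (np.sqrt(v[k] / bias2) + self.eps)
                if self.weight_decay and k not in ("b", "bx", "bh"):
                    # decoupled (AdamW-style) decay; biases exempt
                    step = step + self.lr * self.weight_decay * p
                p -= step.astype(p.dtype)
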