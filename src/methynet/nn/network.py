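"""Network containers and the binary cross-entropy objective."""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .layers import Layer


def sigmoid(z):
    return expit(np.asarray(z, dtype=np.float64))


def bce_with_logits(logits, y, sample_weight=None):
    """Mean binary cross-entropy on raw logits (numerically stable).

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the mean
    loss with respect to the logits.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    # log(1 + e^z) - y*z, computed without overflow
    per = np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-z))
    if sample_weight is None:
        loss = float(per.mean())
        dz = (p - y) / z.size
    else:
        w = np.asarray(sample_weight, dtype=np.float64)
        wsum = w.sum()
        loss = float((per * w).sum() / wsum)
        dz = (p - y) * w / wsum
    return loss, dz


def iter_param_layers(layers):
    """Yield every parameter-carrying layer, descending into wrappers."""
    for layer in layers:
        sub = getattr(layer, "sublayers", None)
        if sub is not None:
            yield from iter_param_layers(sub)
        elif layer.params:
            yield layer


class Sequential:
    """A plain layer stack mapping one input array to one output array."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def param_layers(self):
        return list(iter_param_layers(self.layers))

    def zero_grads(self):
        for layer in self.param_layers():
            layer.zero_grads()

    def reg_loss(self):
        return float(sum(layer.reg_loss() for layer in self.layers))

    @property
    def n_params(self) -> int:
        return int(sum(layer.n_params for layer in self.layers))

    def get_weights(self):
        return [{k: v.copy() for k, v in layer.params.items()}
                for layer in self.param_layers()]

    def set_weights(self, weights):
        for layer, w in zip(self.param_layers(), weights, strict=True):
            for k in layer.params:
                layer.params[k][...] = w[k]
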