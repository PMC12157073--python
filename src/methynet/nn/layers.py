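"""Layers with forward/backward passes.

Conventions
-----------
* Activations are ``(batch, ...)`` arrays; sequence layers use
  ``(batch, time, features)``.
* ``forward(x, train=...)`` caches whatever ``backward`` needs; ``backward(dy)``
  returns ``dx`` and accumulates parameter gradients into ``self.grads``.
* Parameters live in ``self.params`` (name -> ndarray); gradients in
  ``self.grads`` under the same names.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base class; stateless layers leave ``params`` empty."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def reg_loss(self) -> float:
        return 0.0

    def zero_grads(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))


class Dense(Layer):
    """Affine map on the last axis: ``y = x @ W + b``."""

    def __init__(self, n_in, n_out, rng, dtype=np.float32):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.params["W"] = _glorot(rng, n_in, n_out, (n_in, n_out), dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)
        self.zero_grads()

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x = self._x
        x2 = x.reshape(-1, self.n_in)
        dy2 = dy.reshape(-1, self.n_out)
        self.grads["W"] += x2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        return (dy2 @ self.params["W"].T).reshape(x.shape)


class TimeDistributedDense(Dense):
    """Alias of :class:`Dense`: the shared map is applied at every timestep.

    Dense already broadcasts over leading axes, so the subclass only marks
    intent in architecture listings.
    """


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = expit(x)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is false or rate is 0."""

    def __init__(self, rate, rng):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Conv1d(Layer):
    """'valid' 1-D convolution (cross-correlation), stride 1, via im2col.

    Input ``(B, L, C_in)`` -> output ``(B, L - k + 1, C_out)``.  The kernel is
    stored flat as ``(k * C_in, C_out)`` with the position axis outermost, so
    ``weights`` exposes it reshaped to ``(C_out, k, C_in)``.
    """

    def __init__(self, c_in, c_out, kernel_size, rng, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        fan_in = kernel_size * c_in
        self.params["W"] = _glorot(rng, fan_in, c_out, (fan_in, c_out), dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.zero_grads()

    @property
    def weights(self) -> np.ndarray:
        """Kernel tensor in ``(filter, position, channel)`` order."""
        return np.ascontiguousarray(
            self.params["W"].reshape(self.k, self.c_in, self.c_out).transpose(2, 0, 1)
        )

    def _im2col(self, x):
        # (B, L, C) -> (B, L-k+1, k*C); window axis lands last in
        # sliding_window_view, move it before the channel axis.
        v = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        v = np.ascontiguousarray(v.transpose(0, 1, 3, 2))
        return v.reshape(x.shape[0], -1, self.k * self.c_in)

    def forward(self, x, train=False):
        if x.shape[-1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[-1]}")
        self._xshape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        B, L, _ = self._xshape
        lout = L - self.k + 1
        cols2 = self._cols.reshape(-1, self.k * self.c_in)
        dy2 = dy.reshape(-1, self.c_out)
        self.grads["W"] += cols2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        dcols = (dy2 @ self.params["W"].T).reshape(B, lout, self.k, self.c_in)
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        for i in range(self.k):
            dx[:, i : i + lout, :] += dcols[:, :, i, :]
        return dx


class MaxPool1d(Layer):
    """Non-overlapping max pooling over time; trailing remainder is dropped."""

    def __init__(self, pool_size):
        super().__init__()
        self.p = pool_size

    def forward(self, x, train=False):
        B, L, C = x.shape
        self._in_len = L
        lout = L // self.p
        xr = x[:, : lout * self.p].reshape(B, lout, self.p, C)
        self._argmax = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        B, lout, C = dy.shape
        dxr = np.zeros((B, lout, self.p, C), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, self._in_len, C), dtype=dy.dtype)
        dx[:, : lout * self.p] = dxr.reshape(B, lout * self.p, C)
        return dx


def _sig(a):
    return expit(a)


class GRU(Layer):
    """Single-direction GRU ("reset-after" gating).

    Gate order in the packed kernels is ``[r, z, n]``::

        r_t = sigma(x W_r + b_ir + h U_r + b_hr)
        z_t = sigma(x W_z + b_iz + h U_z + b_hz)
        n_t = tanh (x W_n + b_in + r_t * (h U_n + b_hn))
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}

    ``l1``/``l2`` penalties apply to both kernels (input and recurrent), as is
    conventional for regularized recurrent layers.
    """

    def __init__(self, n_in, n_units, rng, return_sequences=False,
                 l1=0.0, l2=0.0, dtype=np.float32):
        super().__init__()
        self.n_in, self.h = n_in, n_units
        self.return_sequences = return_sequences
        self.l1, self.l2 = l1, l2
        self.params["Wx"] = _glorot(rng, n_in, n_units, (n_in, 3 * n_units), dtype)
        self.params["Wh"] = _glorot(rng, n_units, n_units, (n_units, 3 * n_units), dtype)
        self.params["bx"] = np.zeros(3 * n_units, dtype=dtype)
        self.params["bh"] = np.zeros(3 * n_units, dtype=dtype)
        self.zero_grads()

    def forward(self, x, train=False):
        B, T, _ = x.shape
        h = np.zeros((B, self.h), dtype=x.dtype)
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        bx, bh = self.params["bx"], self.params["bh"]
        gx = x @ Wx + bx  # (B, T, 3H)
        H = self.h
        self._cache = []
        ys = np.empty((B, T, H), dtype=x.dtype) if self.return_sequences else None
        for t in range(T):
            gh = h @ Wh + bh
            r = _sig(gx[:, t, :H] + gh[:, :H])
            z = _sig(gx[:, t, H:2 * H] + gh[:, H:2 * H])
            hh = gh[:, 2 * H:]
            n = np.tanh(gx[:, t, 2 * H:] + r * hh)
            h_new = (1.0 - z) * n + z * h
            self._cache.append((h, r, z, n, hh))
            h = h_new
            if self.return_sequences:
                ys[:, t] = h
        self._x = x
        self._h_last = h
        return ys if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        B, T, _ = x.shape
        H = self.h
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        dbx = np.zeros_like(self.params["bx"])
        dbh = np.zeros_like(self.params["bh"])
        dx = np.zeros_like(x)
        dh = np.zeros((B, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dy[:, t]
            elif t == T - 1:
                dh = dh + dy
            h_prev, r, z, n, hh = self._cache[t]
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            da_n = dn * (1.0 - n * n)
            dhh = da_n * r
            dr = da_n * hh
            da_r = dr * r * (1.0 - r)
            da_z = dz * z * (1.0 - z)
            dgx = np.concatenate([da_r, da_z, da_n], axis=1)   # (B, 3H)
            dgh = np.concatenate([da_r, da_z, dhh], axis=1)
            dWx += x[:, t].T @ dgx
            dbx += dgx.sum(axis=0)
            dWh += h_prev.T @ dgh
            dbh += dgh.sum(axis=0)
            dx[:, t] = dgx @ Wx.T
            dh = dh_prev + dgh @ Wh.T
        if self.l2:
            dWx += 2.0 * self.l2 * Wx
            dWh += 2.0 * self.l2 * Wh
        if self.l1:
            dWx += self.l1 * np.sign(Wx)
            dWh += self.l1 * np.sign(Wh)
        self.grads["Wx"] += dWx
        self.grads["Wh"] += dWh
        self.grads["bx"] += dbx
        self.grads["bh"] += dbh
        return dx

    def reg_loss(self) -> float:
        loss = 0.0
        for k in ("Wx", "Wh"):
            W = self.params[k]
            if self.l2:
                loss += self.l2 * float((W * W).sum())
            if self.l1:
                loss += self.l1 * float(np.abs(W).sum())
        return loss


class Bidirectional(Layer):
    """Runs a forward and a time-reversed copy of a GRU; concatenates features."""

    def __init__(self, make_gru):
        super().__init__()
        self.fwd: GRU = make_gru()
        self.bwd: GRU = make_gru()
        self.return_sequences = self.fwd.return_sequences

    @property
    def sublayers(self):
        return [self.fwd, self.bwd]

    def zero_grads(self):
        self.fwd.zero_grads()
        self.bwd.zero_grads()

    @property
    def n_params(self):
        return self.fwd.n_params + self.bwd.n_params

    def forward(self, x, train=False):
        yf = self.fwd.forward(x, train)
        yb = self.bwd.forward(x[:, ::-1], train)
        if self.return_sequences:
            return np.concatenate([yf, yb[:, ::-1]], axis=-1)
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dy):
        H = self.fwd.h
        if self.return_sequences:
            dyf, dyb = dy[..., :H], dy[..., H:][:, ::-1]
        else:
            dyf, dyb = dy[..., :H], dy[..., H:]
        dxf = self.fwd.backward(np.ascontiguousarray(dyf))
        dxb = self.bwd.backward(np.ascontiguousarray(dyb))
        return dxf + dxb[:, ::-1]

    def reg_loss(self):
        return self.fwd.reg_loss() + self.bwd.reg_loss()
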