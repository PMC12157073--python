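"""Mini-batch training loop with early stopping on validation loss."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import bce_with_logits
from .optim import Adam


def _take(X, idx):
    if isinstance(X, (tuple, list)):
        return tuple(x[idx] for x in X)
    return X[idx]


def _n_examples(X):
    if isinstance(X, (tuple, list)):
        return X[0].shape[0]
    return X.shape[0]


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)

    def append(self, **row):
        self.epochs.append(row)

    def __len__(self):
        return len(self.epochs)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.epochs)


class Trainer:
    """Adam + BCE training of a network object.

    The network must expose ``forward(X, train)`` returning 1-d logits,
    ``backward(dlogits)``, ``param_layers``, ``zero_grads``, ``reg_loss``,
    ``get_weights`` and ``set_weights``.  ``X`` may be a single array or a
    tuple of arrays batched along axis 0 in lockstep.
    """

    def __init__(self, net, lr=1e-3, batch_size=128, max_epochs=50,
                 patience=5, seed=0, weight_decay=0.0):
        self.net = net
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.rng = np.random.default_rng(seed)

    def predict_logits(self, X, batch_size=None):
        bs = batch_size or max(self.batch_size, 256)
        n = _n_examples(X)
        out = np.empty(n, dtype=np.float64)
        for s in range(0, n, bs):
            sl = slice(s, min(s + bs, n))
            out[sl] = np.asarray(self.net.forward(_take(X, sl), train=False)).ravel()
        return out

    def _eval_loss(self, X, y, sample_weight=None):
        z = self.predict_logits(X)
        loss, _ = bce_with_logits(z, y, sample_weight)
        return loss + self.net.reg_loss()

    def fit(self, X, y, X_val=None, y_val=None, sample_weight=None,
            verbose=False):
        y = np.asarray(y, dtype=np.float64)
        n = _n_examples(X)
        if n == 0:
            raise ValueError("empty training set")
        opt = Adam(self.net.param_layers(), lr=self.lr,
                   weight_decay=self.weight_decay)
        history = TrainingHistory()
        monitor_val = X_val is not None and _n_examples(X_val) > 0
        best_loss = np.inf
        best_weights = None
        bad_epochs = 0
        for epoch in range(self.max_epochs):
            order = self.rng.permutation(n)
            train_loss = 0.0
            for s in range(0, n, self.batch_size):
                idx = order[s : s + self.batch_size]
                xb, yb = _take(X, idx), y[idx]
                wb = None if sample_weight is None else sample_weight[idx]
                self.net.zero_grads()
                z = np.asarray(self.net.forward(xb, train=True)).ravel()
                loss, dz = bce_with_logits(z, yb, wb)
                self.net.backward(dz.astype(np.float32))
                opt.step()
                train_loss += loss * len(idx)
            train_loss = train_loss / n + self.net.reg_loss()
            row = {"epoch": epoch, "train_loss": train_loss}
            if monitor_val:
                val_loss = self._eval_loss(X_val, y_val)
                row["val_loss"] = val_loss
                if val_loss < best_loss - 1e-7:
                    best_loss = val_loss
                    best_weights = self.net.get_weights()
                    bad_epochs = 0
                else:
                    bad_epochs += 1
            history.append(**row)
            if verbose:
                print(", ".join(f"{k}={v:.4f}" if k != "epoch" else f"epoch {v}"
                                for k, v in row.items()))
            if monitor_val and bad_epochs > self.patience:
                break
        if monitor_val and best_weights is not None:
            self.net.set_weights(best_weights)
        return history
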