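"""The three classifiers: DNA CNN, neighbor BiGRU, and the joint model.

Architectures (defaults)
------------------------
DNA model — a CNN over the 1001x4 one-hot window:
``conv(128, k=11, s=1) + ReLU -> maxpool(4) -> conv(256, k=3, s=1) + ReLU ->
maxpool(2) -> flatten -> dense(256) + ReLU -> dropout -> sigmoid head``.
The post-dropout dense output is the model's 256-dimensional embedding.

Methylation model — two bidirectional GRU layers over the 50 neighbor
timesteps (state, distance): ``time-distributed dense(32) + ReLU ->
BiGRU(128, L1=L2=1e-4) -> BiGRU(256, last state) -> dropout`` giving a
512-dimensional embedding, then a sigmoid head.

Joint model — the concatenated 768-dimensional embedding (256 + 512) through
two dense layers of 512 units (ReLU) and a sigmoid head; trained end-to-end
from scratch by default, optionally warm-started from the single models.

All estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``); binarization of probabilities uses the
strict > 0.5 rule (probability exactly 0.5 rounds to unmethylated).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from . import nn
from .encode import EncodingSpec
from .nn.layers import Layer

__all__ = [
    "DnaModelSpec", "MethModelSpec", "JointModelSpec", "TrainConfig",
    "DnaCnnClassifier", "NeighborGruClassifier", "JointMethylationClassifier",
    "build_dna_model", "build_meth_model", "build_joint_model",
    "train", "predict", "binarize", "get_first_layer_filters",
    "save_model", "load_model",
]

DEFAULT_THRESHOLD = 0.5


# --------------------------------------------------------------------------
# Specs

@dataclass
class DnaModelSpec:
    conv1_filters: int = 128
    conv1_kernel: int = 11
    pool1: int = 4
    conv2_filters: int = 256
    conv2_kernel: int = 3
    pool2: int = 2
    fc_units: int = 256
    dropout_rate: float = 0.25

    def __post_init__(self):
        if self.conv1_kernel % 2 == 0 or self.conv2_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if self.fc_units <= 0:
            raise ValueError("fc_units must be positive")

    @property
    def embedding_dim(self) -> int:
        return self.fc_units


@dataclass
class MethModelSpec:
    k_neighbors: int = 25
    td_units: int = 32
    gru1_units: int = 128
    gru2_units: int = 256
    l1: float = 1e-4
    l2: float = 1e-4
    dropout_rate: float = 0.25

    @property
    def timesteps(self) -> int:
        return 2 * self.k_neighbors

    @property
    def step_features(self) -> int:
        return 2

    @property
    def embedding_dim(self) -> int:
        # bidirectional: forward and backward final states concatenated
        return 2 * self.gru2_units


@dataclass
class JointModelSpec:
    fc_units: int = 512
    n_fc_layers: int = 2

    def input_dim(self, dna: DnaModelSpec, meth: MethModelSpec) -> int:
        return dna.embedding_dim + meth.embedding_dim


@dataclass
class TrainConfig:
    """Optimization settings (none of these are architectural constants)."""

    loss: str = "bce"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 50
    patience: int = 5
    class_weight: str | None = None   # None or "balanced"
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


# --------------------------------------------------------------------------
# Network assembly

class _NeighborSplitStack(Layer):
    """(B, 4k) flat neighbor vector -> (B, 2k, 2) timestep sequence.

    Slot layout is states block then distances block; timestep t pairs
    state_t with distance_t.
    """

    def forward(self, x, train=False):
        b, d = x.shape
        half = d // 2
        return np.stack([x[:, :half], x[:, half:]], axis=-1)

    def backward(self, dy):
        return np.concatenate([dy[..., 0], dy[..., 1]], axis=1)


def _dna_body(spec: DnaModelSpec, seq_length: int, rng) -> list[Layer]:
    l1 = seq_length - spec.conv1_kernel + 1
    p1 = l1 // spec.pool1
    l2 = p1 - spec.conv2_kernel + 1
    p2 = l2 // spec.pool2
    if p2 <= 0:
        raise ValueError(f"sequence length {seq_length} too short for the spec")
    return [
        nn.Conv1d(4, spec.conv1_filters, spec.conv1_kernel, rng),
        nn.ReLU(),
        nn.MaxPool1d(spec.pool1),
        nn.Conv1d(spec.conv1_filters, spec.conv2_filters, spec.conv2_kernel, rng),
        nn.ReLU(),
        nn.MaxPool1d(spec.pool2),
        nn.Flatten(),
        nn.Dense(p2 * spec.conv2_filters, spec.fc_units, rng),
        nn.ReLU(),
        nn.Dropout(spec.dropout_rate, rng),
    ]


def _meth_body(spec: MethModelSpec, rng) -> list[Layer]:
    return [
        _NeighborSplitStack(),
        nn.TimeDistributedDense(spec.step_features, spec.td_units, rng),
        nn.ReLU(),
        nn.Bidirectional(lambda: nn.GRU(
            spec.td_units, spec.gru1_units, rng, return_sequences=True,
            l1=spec.l1, l2=spec.l2)),
        nn.Bidirectional(lambda: nn.GRU(
            2 * spec.gru1_units, spec.gru2_units, rng, return_sequences=False)),
        nn.Dropout(spec.dropout_rate, rng),
    ]


class _BranchNet:
    """Body (-> embedding) plus a 1-unit logit head."""

    def __init__(self, body: list[Layer], embedding_dim: int, rng):
        self.body = nn.Sequential(body)
        self.head = nn.Dense(embedding_dim, 1, rng)
        self.embedding_dim = embedding_dim

    def forward(self, x, train=False):
        e = self.body.forward(x, train=train)
        return self.head.forward(e, train=train).ravel()

    def backward(self, dz):
        de = self.head.backward(dz.reshape(-1, 1))
        return self.body.backward(de)

    def embed(self, x):
        return self.body.forward(x, train=False)

    def param_layers(self):
        return self.body.param_layers() + [self.head]

    def zero_grads(self):
        for l in self.param_layers():
            l.zero_grads()

    def reg_loss(self):
        return self.body.reg_loss()

    def get_weights(self):
        return [{k: v.copy() for k, v in l.params.items()} for l in self.param_layers()]

    def set_weights(self, weights):
        for l, w in zip(self.param_layers(), weights, strict=True):
            for k in l.params:
                l.params[k][...] = w[k]

    @property
    def n_params(self):
        return sum(l.n_params for l in self.param_layers())


class _JointNet:
    """Two embedding branches, concatenated, through a dense head."""

    def __init__(self, dna_body, meth_body, dna_dim, meth_dim,
                 joint: JointModelSpec, rng):
        self.dna = nn.Sequential(dna_body)
        self.meth = nn.Sequential(meth_body)
        self.dna_dim, self.meth_dim = dna_dim, meth_dim
        head: list[Layer] = []
        d = dna_dim + meth_dim
        for _ in range(joint.n_fc_layers):
            head += [nn.Dense(d, joint.fc_units, rng), nn.ReLU()]
            d = joint.fc_units
        head.append(nn.Dense(d, 1, rng))
        self.head = nn.Sequential(head)

    def forward(self, x, train=False):
        xs, xn = x
        e = np.concatenate([self.dna.forward(xs, train=train),
                            self.meth.forward(xn, train=train)], axis=1)
        return self.head.forward(e, train=train).ravel()

    def backward(self, dz):
        de = self.head.backward(dz.reshape(-1, 1))
        self.dna.backward(de[:, : self.dna_dim])
        self.meth.backward(np.ascontiguousarray(de[:, self.dna_dim :]))

    def embed(self, x):
        xs, xn = x
        return np.concatenate([self.dna.forward(xs, train=False),
                               self.meth.forward(xn, train=False)], axis=1)

    def param_layers(self):
        return (self.dna.param_layers() + self.meth.param_layers()
                + self.head.param_layers())

    def zero_grads(self):
        for l in self.param_layers():
            l.zero_grads()

    def reg_loss(self):
        return self.dna.reg_loss() + self.meth.reg_loss()

    def get_weights(self):
        return [{k: v.copy() for k, v in l.params.items()} for l in self.param_layers()]

    def set_weights(self, weights):
        for l, w in zip(self.param_layers(), weights, strict=True):
            for k in l.params:
                l.params[k][...] = w[k]

    @property
    def n_params(self):
        return sum(l.n_params for l in self.param_layers())


# --------------------------------------------------------------------------
# Estimators

def binarize(probs, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Probability -> state with the strict rule: > threshold is methylated."""
    return (np.asarray(probs) > threshold).astype(np.int64)


class _BaseNetClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery; subclasses build the network."""

    model_kind = "base"

    def _more_tags(self):  # pragma: no cover
        return {"binary_only": True}

    # -- subclass hooks ----------------------------------------------------
    def _make_net(self, rng):
        raise NotImplementedError

    def _check_X(self, X):
        raise NotImplementedError

    # ----------------------------------------------------------------------
    def initialize(self) -> "_BaseNetClassifier":
        """Build the (untrained) network so it can be inspected or run."""
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._make_net(rng)
        self.classes_ = np.array([0, 1])
        return self

    @property
    def n_parameters_(self) -> int:
        self._require_net()
        return self.net_.n_params

    def _require_net(self):
        if not hasattr(self, "net_"):
            raise NotFittedError(
                f"{type(self).__name__} is neither fitted nor initialized")

    def fit(self, X, y, validation_data=None, verbose=False):
        X = self._check_X(X)
        y = np.asarray(y, dtype=np.float64).ravel()
        if not np.isin(y, [0.0, 1.0]).all():
            raise ValueError("labels must be binary (0/1)")
        if len(np.unique(y)) < 2:
            warnings.warn("training set contains a single class; "
                          "AUC on validation data will be undefined")
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._make_net(rng)
        self.classes_ = np.array([0, 1])

        if validation_data is not None:
            X_val, y_val = validation_data
            X_val = self._check_X(X_val)
            y_val = np.asarray(y_val, dtype=np.float64).ravel()
        elif self.validation_fraction and self.validation_fraction > 0:
            n = y.shape[0]
            n_val = max(1, int(round(self.validation_fraction * n)))
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, y_val = _index_X(X, val_idx), y[val_idx]
            X, y = _index_X(X, tr_idx), y[tr_idx]
        else:
            X_val = y_val = None

        sample_weight = None
        if self.class_weight == "balanced":
            pos = max(y.sum(), 1.0)
            neg = max((1.0 - y).sum(), 1.0)
            w_pos, w_neg = len(y) / (2.0 * pos), len(y) / (2.0 * neg)
            sample_weight = np.where(y == 1.0, w_pos, w_neg)

        trainer = nn.Trainer(self.net_, lr=self.learning_rate,
                             batch_size=self.batch_size,
                             max_epochs=self.max_epochs,
                             patience=self.patience,
                             seed=self.random_state,
                             weight_decay=self.weight_decay)
        self.history_ = trainer.fit(X, y, X_val, y_val,
                                    sample_weight=sample_weight,
                                    verbose=verbose)
        self._trainer = trainer
        return self

    def predict_probability(self, X) -> np.ndarray:
        """Methylation probability per example (1-d, in [0, 1])."""
        self._require_net()
        X = self._check_X(X)
        trainer = getattr(self, "_trainer", None) or nn.Trainer(self.net_)
        return nn.sigmoid(trainer.predict_logits(X))

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_probability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return binarize(self.predict_probability(X))

    def embed(self, X) -> np.ndarray:
        """The learned embedding (evaluation mode, dropout off)."""
        self._require_net()
        X = self._check_X(X)
        n = X[0].shape[0] if isinstance(X, tuple) else X.shape[0]
        chunks = []
        for s in range(0, n, 512):
            xb = tuple(x[s:s + 512] for x in X) if isinstance(X, tuple) else X[s:s + 512]
            chunks.append(self.net_.embed(xb))
        return np.concatenate(chunks, axis=0)

    # encoding metadata travels with the model so that prediction-time
    # features are built identically to training-time ones
    def set_encoding(self, spec: EncodingSpec) -> "_BaseNetClassifier":
        self.encoding_spec_ = spec
        return self


def _index_X(X, idx):
    if isinstance(X, tuple):
        return tuple(x[idx] for x in X)
    return X[idx]


class DnaCnnClassifier(_BaseNetClassifier):
    """CNN over one-hot DNA windows centered on the target cytosine.

    ``X`` may be ``(n, L, 4)`` or flattened ``(n, 4L)``; ``L`` must equal
    ``2 * window_radius + 1``.
    """

    model_kind = "dna"

    def __init__(self, window_radius=500, conv1_filters=128, conv1_kernel=11,
                 pool1=4, conv2_filters=256, conv2_kernel=3, pool2=2,
                 fc_units=256, dropout_rate=0.25, learning_rate=1e-3,
                 batch_size=128, max_epochs=50, patience=5,
                 validation_fraction=0.1, class_weight=None, weight_decay=0.0,
                 random_state=0):
        self.window_radius = window_radius
        self.conv1_filters = conv1_filters
        self.conv1_kernel = conv1_kernel
        self.pool1 = pool1
        self.conv2_filters = conv2_filters
        self.conv2_kernel = conv2_kernel
        self.pool2 = pool2
        self.fc_units = fc_units
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.class_weight = class_weight
        self.weight_decay = weight_decay
        self.random_state = random_state

    @property
    def spec(self) -> DnaModelSpec:
        return DnaModelSpec(self.conv1_filters, self.conv1_kernel, self.pool1,
                            self.conv2_filters, self.conv2_kernel, self.pool2,
                            self.fc_units, self.dropout_rate)

    @property
    def seq_length(self) -> int:
        return 2 * self.window_radius + 1

    def _make_net(self, rng):
        spec = self.spec
        return _BranchNet(_dna_body(spec, self.seq_length, rng),
                          spec.embedding_dim, rng)

    def _check_X(self, X):
        X = np.asarray(X, dtype=np.float32)
        L = self.seq_length
        if X.ndim == 2 and X.shape[1] == 4 * L:
            X = X.reshape(-1, L, 4)
        if X.ndim != 3 or X.shape[1] != L or X.shape[2] != 4:
            raise ValueError(f"expected windows of shape (n, {L}, 4) "
                             f"or (n, {4 * L}), got {X.shape}")
        return X

    @property
    def first_layer_filters_(self) -> np.ndarray:
        """First-convolution kernels, shape (filters, positions, channels A/T/G/C)."""
        self._require_net()
        return self.net_.body.layers[0].weights


class NeighborGruClassifier(_BaseNetClassifier):
    """Bidirectional-GRU model over neighbor methylation states and distances.

    ``X`` is ``(n, 4k)``: 2k state slots then 2k distance slots.
    """

    model_kind = "meth"

    def __init__(self, k_neighbors=25, td_units=32, gru1_units=128,
                 gru2_units=256, l1=1e-4, l2=1e-4, dropout_rate=0.25,
                 learning_rate=1e-3, batch_size=128, max_epochs=50, patience=5,
                 validation_fraction=0.1, class_weight=None, weight_decay=0.0,
                 random_state=0):
        self.k_neighbors = k_neighbors
        self.td_units = td_units
        self.gru1_units = gru1_units
        self.gru2_units = gru2_units
        self.l1 = l1
        self.l2 = l2
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.class_weight = class_weight
        self.weight_decay = weight_decay
        self.random_state = random_state

    @property
    def spec(self) -> MethModelSpec:
        return MethModelSpec(self.k_neighbors, self.td_units, self.gru1_units,
                             self.gru2_units, self.l1, self.l2,
                             self.dropout_rate)

    def _make_net(self, rng):
        spec = self.spec
        return _BranchNet(_meth_body(spec, rng), spec.embedding_dim, rng)

    def _check_X(self, X):
        X = np.asarray(X, dtype=np.float32)
        d = 4 * self.k_neighbors
        if X.ndim != 2 or X.shape[1] != d:
            raise ValueError(f"expected neighbor vectors of shape (n, {d}), "
                             f"got {X.shape}")
        return X


class JointMethylationClassifier(_BaseNetClassifier):
    """End-to-end joint model over (DNA window, neighbor vector) pairs.

    ``X`` is either a tuple ``(seq, nbr)`` or a single 2-d array
    ``(n, 4L + 4k)`` with the flattened window first.
    """

    model_kind = "joint"

    def __init__(self, window_radius=500, conv1_filters=128, conv1_kernel=11,
                 pool1=4, conv2_filters=256, conv2_kernel=3, pool2=2,
                 fc_units=256, k_neighbors=25, td_units=32, gru1_units=128,
                 gru2_units=256, l1=1e-4, l2=1e-4, joint_units=512,
                 joint_layers=2, dropout_rate=0.25, learning_rate=1e-3,
                 batch_size=128, max_epochs=50, patience=5,
                 validation_fraction=0.1, class_weight=None, weight_decay=0.0,
                 random_state=0, warm_start_models=None):
        self.window_radius = window_radius
        self.conv1_filters = conv1_filters
        self.conv1_kernel = conv1_kernel
        self.pool1 = pool1
        self.conv2_filters = conv2_filters
        self.conv2_kernel = conv2_kernel
        self.pool2 = pool2
        self.fc_units = fc_units
        self.k_neighbors = k_neighbors
        self.td_units = td_units
        self.gru1_units = gru1_units
        self.gru2_units = gru2_units
        self.l1 = l1
        self.l2 = l2
        self.joint_units = joint_units
        self.joint_layers = joint_layers
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.class_weight = class_weight
        self.weight_decay = weight_decay
        self.random_state = random_state
        self.warm_start_models = warm_start_models

    @property
    def dna_spec(self) -> DnaModelSpec:
        return DnaModelSpec(self.conv1_filters, self.conv1_kernel, self.pool1,
                            self.conv2_filters, self.conv2_kernel, self.pool2,
                            self.fc_units, self.dropout_rate)

    @property
    def meth_spec(self) -> MethModelSpec:
        return MethModelSpec(self.k_neighbors, self.td_units, self.gru1_units,
                             self.gru2_units, self.l1, self.l2,
                             self.dropout_rate)

    @property
    def joint_spec(self) -> JointModelSpec:
        return JointModelSpec(self.joint_units, self.joint_layers)

    @property
    def seq_length(self) -> int:
        return 2 * self.window_radius + 1

    @property
    def input_dim(self) -> int:
        return self.dna_spec.embedding_dim + self.meth_spec.embedding_dim

    def _make_net(self, rng):
        dna, meth = self.dna_spec, self.meth_spec
        net = _JointNet(_dna_body(dna, self.seq_length, rng),
                        _meth_body(meth, rng),
                        dna.embedding_dim, meth.embedding_dim,
                        self.joint_spec, rng)
        if self.warm_start_models is not None:
            dna_est, meth_est = self.warm_start_models
            for seq, est in ((net.dna, dna_est), (net.meth, meth_est)):
                src = est.net_.body.param_layers()
                dst = seq.param_layers()
                for ls, ld in zip(src, dst, strict=True):
                    for k in ld.params:
                        if ld.params[k].shape != ls.params[k].shape:
                            raise ValueError(
                                "warm-start model architecture does not match")
                        ld.params[k][...] = ls.params[k]
        return net

    def _check_X(self, X):
        L, d = self.seq_length, 4 * self.k_neighbors
        if isinstance(X, (tuple, list)):
            seq, nbr = X
            seq = np.asarray(seq, dtype=np.float32)
            if seq.ndim == 2:
                seq = seq.reshape(-1, L, 4)
            nbr = np.asarray(nbr, dtype=np.float32)
        else:
            X = np.asarray(X, dtype=np.float32)
            if X.ndim != 2 or X.shape[1] != 4 * L + d:
                raise ValueError(f"expected (n, {4 * L + d}) combined input, "
                                 f"got {X.shape}")
            seq = X[:, : 4 * L].reshape(-1, L, 4)
            nbr = X[:, 4 * L :]
        if seq.shape[1:] != (L, 4):
            raise ValueError(f"window shape {seq.shape[1:]} != ({L}, 4)")
        if nbr.shape[1] != d:
            raise ValueError(f"neighbor dim {nbr.shape[1]} != {d}")
        if seq.shape[0] != nbr.shape[0]:
            raise ValueError("window and neighbor batches differ in length")
        return (seq, np.ascontiguousarray(nbr))

    @property
    def first_layer_filters_(self) -> np.ndarray:
        self._require_net()
        return self.net_.dna.layers[0].weights


# --------------------------------------------------------------------------
# Functional surface

def build_dna_model(spec: DnaModelSpec | None = None, window_radius: int = 500,
                    random_state: int = 0, **train_kwargs) -> DnaCnnClassifier:
    spec = spec or DnaModelSpec()
    est = DnaCnnClassifier(window_radius=window_radius, **asdict(spec),
                           random_state=random_state, **train_kwargs)
    return est.initialize()


def build_meth_model(spec: MethModelSpec | None = None, random_state: int = 0,
                     **train_kwargs) -> NeighborGruClassifier:
    spec = spec or MethModelSpec()
    est = NeighborGruClassifier(**asdict(spec), random_state=random_state,
                                **train_kwargs)
    return est.initialize()


def build_joint_model(dna_spec: DnaModelSpec | None = None,
                      meth_spec: MethModelSpec | None = None,
                      joint_spec: JointModelSpec | None = None,
                      window_radius: int = 500, random_state: int = 0,
                      **train_kwargs) -> JointMethylationClassifier:
    dna_spec = dna_spec or DnaModelSpec()
    meth_spec = meth_spec or MethModelSpec()
    joint_spec = joint_spec or JointModelSpec()
    est = JointMethylationClassifier(
        window_radius=window_radius,
        conv1_filters=dna_spec.conv1_filters, conv1_kernel=dna_spec.conv1_kernel,
        pool1=dna_spec.pool1, conv2_filters=dna_spec.conv2_filters,
        conv2_kernel=dna_spec.conv2_kernel, pool2=dna_spec.pool2,
        fc_units=dna_spec.fc_units, k_neighbors=meth_spec.k_neighbors,
        td_units=meth_spec.td_units, gru1_units=meth_spec.gru1_units,
        gru2_units=meth_spec.gru2_units, l1=meth_spec.l1, l2=meth_spec.l2,
        joint_units=joint_spec.fc_units, joint_layers=joint_spec.n_fc_layers,
        dropout_rate=dna_spec.dropout_rate, random_state=random_state,
        **train_kwargs)
    return est.initialize()


def train(model: _BaseNetClassifier, train_set, val_set=None,
          config: TrainConfig | None = None, verbose=False) -> _BaseNetClassifier:
    """Fit ``model`` on ``(X, y)`` tuples under a :class:`TrainConfig`."""
    config = config or TrainConfig()
    model.set_params(learning_rate=config.learning_rate,
                     batch_size=config.batch_size,
                     max_epochs=config.max_epochs, patience=config.patience,
                     class_weight=config.class_weight,
                     weight_decay=config.weight_decay,
                     random_state=config.seed)
    X, y = train_set
    return model.fit(X, y, validation_data=val_set, verbose=verbose)


def predict(model: _BaseNetClassifier, X) -> np.ndarray:
    """Methylation probabilities in [0, 1], one per example."""
    return model.predict_probability(X)


def get_first_layer_filters(model) -> np.ndarray:
    """First-convolution kernels of a DNA or joint model, (filters, 11, 4)."""
    if getattr(model, "model_kind", None) not in ("dna", "joint"):
        raise ValueError("first-layer filters exist only for DNA/joint models")
    return model.first_layer_filters_


# --------------------------------------------------------------------------
# Serialization: flat npz of weights + JSON sidecar of hyperparameters

_KIND_TO_CLASS = {}


def _register():
    for cls in (DnaCnnClassifier, NeighborGruClassifier,
                JointMethylationClassifier):
        _KIND_TO_CLASS[cls.model_kind] = cls


_register()


def save_model(model: _BaseNetClassifier, path) -> None:
    model._require_net()
    arrays = {}
    for i, layer in enumerate(model.net_.param_layers()):
        for k, v in layer.params.items():
            arrays[f"layer{i:03d}__{k}"] = v
    params = {k: v for k, v in model.get_params().items()
              if k != "warm_start_models"}
    meta = {
        "model_kind": model.model_kind,
        "params": params,
        "encoding_spec": (model.encoding_spec_.to_dict()
                          if hasattr(model, "encoding_spec_") else None),
    }
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> _BaseNetClassifier:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cls = _KIND_TO_CLASS[meta["model_kind"]]
    model = cls(**meta["params"]).initialize()
    layers = model.net_.param_layers()
    for i, layer in enumerate(layers):
        for k in layer.params:
            layer.params[k][...] = data[f"layer{i:03d}__{k}"]
    if meta["encoding_spec"] is not None:
        model.set_encoding(EncodingSpec.from_dict(meta["encoding_spec"]))
    return model
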