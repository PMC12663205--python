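"""Classifiers: the dual-branch CNN-BiLSTM hybrid and KNN/SVM/CNN baselines.

The hybrid network takes the pair of per-window feature matrices:

* functional branch (CNN): input (pairs x F_f x 1) -> conv 8 filters 3x3 ->
  batch-norm -> ReLU -> conv 16 filters 3x3 -> batch-norm -> ReLU -> flatten;
* temporal branch (BiLSTM): channels as the sequence axis (31 steps of
  F_t-dimensional vectors) -> bidirectional LSTM 100 units -> batch-norm ->
  ReLU -> bidirectional LSTM 50 units (final states);

branch outputs are concatenated, passed through a 64-unit fully connected
ReLU layer and a 2-way softmax.  Training uses Adam (lr 1e-3, halved every
20 epochs), mini-batches of 32, up to 70 epochs with early stopping on a
10% held-out validation split (patience 10).

Baselines follow the same hyperparameter sheet: KNN with k=25, city-block
distance, brute-force search, no standardization; SVM with an RBF kernel,
automatic kernel scale, standardization and a 0.05 outlier fraction
(nu-SVM); a plain CNN with three conv blocks (8/16/32 filters, 3x3),
batch-norm, ReLU, dropout 0.3, Adam 1e-3, batch 128, up to 64 epochs.

The positive class is schizophrenia (label 1) throughout.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import NuSVC

from .nn import (Adam, BatchNorm, BiLSTM, Conv2D, Dense, Dropout, Flatten,
                 ReLU, Sequential, softmax, softmax_cross_entropy)

__all__ = ["ModelSpec", "TrainedModel", "fit", "predict_scores"]

KINDS = ("knn", "svm", "cnn", "hybrid")


@dataclass(frozen=True)
class ModelSpec:
    """Classifier kind plus its hyperparameters.

    ``input_mode`` tells the evaluation layer what to feed the model:
    ``"pair"`` (the hybrid's (functional, temporal) matrix pair),
    ``"functional"`` / ``"temporal"`` (one whole matrix, for the CNN),
    ``"single:<feature>"`` (one feature's flat vector, for KNN/SVM), or
    ``"flat"`` (both matrices flattened and concatenated).
    """

    kind: str = "hybrid"
    seed: int = 0
    input_mode: str = "pair"
    # knn
    knn_k: int = 25
    knn_metric: str = "cityblock"
    # svm
    svm_nu: float = 0.05
    # cnn baseline
    cnn_filters: tuple[int, ...] = (8, 16, 32)
    cnn_dropout: float = 0.3
    cnn_batch: int = 32
    cnn_epochs: int = 64
    # hybrid
    hybrid_filters: tuple[int, ...] = (8, 16)
    hybrid_lstm_units: tuple[int, int] = (100, 50)
    hybrid_fc: int = 64
    hybrid_batch: int = 32
    hybrid_epochs: int = 70
    # shared training knobs
    lr: float = 1e-3
    lr_decay_every: int = 20
    lr_decay_factor: float = 0.5
    patience: int = 10
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "knn" and self.knn_k < 1:
            raise ValueError(f"knn_k must be >= 1, got {self.knn_k}")
        if self.kind == "svm" and not 0 < self.svm_nu < 1:
            raise ValueError(f"svm_nu must be in (0, 1), got {self.svm_nu}")
        if self.kind == "hybrid" and len(self.hybrid_filters) != 2:
            raise ValueError("hybrid needs exactly two conv filter counts")


@dataclass
class TrainedModel:
    spec: ModelSpec
    state: Any
    input_shapes: tuple[tuple[int, ...], ...]
    history: dict[str, list[float]] = field(default_factory=dict)

    def predict_scores(self, x) -> np.ndarray:
        return predict_scores(self, x)


class _HybridNet:
    """Two input branches, concatenation, fully connected head."""

    def __init__(self, func_shape: tuple[int, int], temp_shape: tuple[int, int],
                 spec: ModelSpec, rng: np.random.Generator):
        pairs, n_f = func_shape
        n_steps, n_t = temp_shape
        f1, f2 = spec.hybrid_filters
        u1, u2 = spec.hybrid_lstm_units
        self.func_branch = Sequential([
            Conv2D(1, f1, rng), BatchNorm(f1), ReLU(),
            Conv2D(f1, f2, rng), BatchNorm(f2), ReLU(), Flatten(),
        ])
        self.temp_branch = Sequential([
            BiLSTM(n_t, u1, rng, return_sequences=True),
            BatchNorm(2 * u1), ReLU(),
            BiLSTM(2 * u1, u2, rng, return_sequences=False),
        ])
        self.head = Sequential([
            Dense(pairs * n_f * f2 + 2 * u2, spec.hybrid_fc, rng), ReLU(),
            Dense(spec.hybrid_fc, 2, rng),
        ])
        self._split = pairs * n_f * f2

    def params(self):
        return (self.func_branch.params() + self.temp_branch.params()
                + self.head.params())

    def grads(self):
        return (self.func_branch.grads() + self.temp_branch.grads()
                + self.head.grads())

    def forward(self, inputs, training=False):
        x_func, x_temp = inputs
        f = self.func_branch.forward(x_func[..., None], training)
        t = self.temp_branch.forward(x_temp, training)
        return self.head.forward(np.concatenate([f, t], axis=1), training)

    def backward(self, dlogits):
        dcat = self.head.backward(dlogits)
        self.func_branch.backward(dcat[:, : self._split])
        self.temp_branch.backward(dcat[:, self._split:])


class _CNNNet:
    """Conv blocks + dropout + flatten + softmax head on one matrix input."""

    def __init__(self, shape: tuple[int, int], spec: ModelSpec,
                 rng: np.random.Generator):
        h, w = shape
        layers: list = []
        c_in = 1
        for f in spec.cnn_filters:
            layers += [Conv2D(c_in, f, rng), BatchNorm(f), ReLU()]
            c_in = f
        layers += [Dropout(spec.cnn_dropout, rng), Flatten(),
                   Dense(h * w * c_in, 2, rng)]
        self.net = Sequential(layers)

    def params(self):
        return self.net.params()

    def grads(self):
        return self.net.grads()

    def forward(self, inputs, training=False):
        (x,) = inputs
        return self.net.forward(x[..., None], training)

    def backward(self, dlogits):
        self.net.backward(dlogits)


def _stratified_holdout(y: np.ndarray, fraction: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split into (train_idx, val_idx); val gets >= 1 per class."""
    train, val = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        n_val = max(1, int(round(fraction * idx.size)))
        val.append(idx[:n_val])
        train.append(idx[n_val:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(val))


def _train_network(net, inputs: tuple[np.ndarray, ...], y: np.ndarray,
                   spec: ModelSpec, batch: int, max_epochs: int,
                   rng: np.random.Generator) -> dict[str, list[float]]:
    train_idx, val_idx = _stratified_holdout(y, spec.val_fraction, rng)
    x_tr = tuple(a[train_idx] for a in inputs)
    x_va = tuple(a[val_idx] for a in inputs)
    y_tr, y_va = y[train_idx], y[val_idx]

    opt = Adam(net.params(), lr=spec.lr)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = [p.copy() for p in net.params()]
    stall = 0
    n = y_tr.size
    for epoch in range(max_epochs):
        opt.lr = spec.lr * spec.lr_decay_factor ** (epoch // spec.lr_decay_every)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            sel = order[start:start + batch]
            logits = net.forward(tuple(a[sel] for a in x_tr), training=True)
            loss, dlogits = softmax_cross_entropy(logits, y_tr[sel])
            net.backward(dlogits)
            opt.step(net.grads())
            epoch_loss += loss * sel.size
        val_logits = net.forward(x_va, training=False)
        val_loss, _ = softmax_cross_entropy(val_logits, y_va)
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = [p.copy() for p in net.params()]
            stall = 0
        else:
            stall += 1
            if stall >= spec.patience:
                break
    for p, best in zip(net.params(), best_params):
        p[...] = best
    return history


def _as_inputs(spec: ModelSpec, x) -> tuple[np.ndarray, ...]:
    if spec.kind == "hybrid":
        if not (isinstance(x, tuple) and len(x) == 2):
            raise ValueError(
                "hybrid input must be a (functional, temporal) array pair")
        xf, xt = (np.asarray(a, float) for a in x)
        if xf.ndim != 3 or xt.ndim != 3:
            raise ValueError(
                f"hybrid inputs must be 3-D (items x rows x cols); got "
                f"{xf.shape} and {xt.shape}")
        if xf.shape[0] != xt.shape[0]:
            raise ValueError("functional/temporal item counts differ")
        return xf, xt
    x = np.asarray(x, float)
    if spec.kind == "cnn":
        if x.ndim != 3:
            raise ValueError(f"cnn input must be 3-D, got shape {x.shape}")
        return (x,)
    if x.ndim != 2:
        raise ValueError(f"{spec.kind} input must be 2-D, got shape {x.shape}")
    return (x,)


def fit(spec: ModelSpec, x, y) -> TrainedModel:
    """Train a classifier of the given kind.

    ``y`` is a binary label array (1 = schizophrenia).  ``x`` is a flat
    (n, d) array for knn/svm, an (n, H, W) matrix stack for cnn, or a
    ``(functional, temporal)`` pair of 3-D stacks for the hybrid.
    """
    inputs = _as_inputs(spec, x)
    y = np.asarray(y, int).ravel()
    if y.size != inputs[0].shape[0]:
        raise ValueError(f"{y.size} labels for {inputs[0].shape[0]} items")
    if y.size == 0:
        raise ValueError("empty training set")
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    shapes = tuple(a.shape[1:] for a in inputs)
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "knn":
        est = KNeighborsClassifier(n_neighbors=spec.knn_k,
                                   metric=spec.knn_metric, algorithm="brute")
        est.fit(inputs[0], y)
        return TrainedModel(spec, est, shapes)
    if spec.kind == "svm":
        scaler = StandardScaler().fit(inputs[0])
        est = NuSVC(nu=spec.svm_nu, kernel="rbf", gamma="scale")
        est.fit(scaler.transform(inputs[0]), y)
        return TrainedModel(spec, (scaler, est), shapes)
    if spec.kind == "cnn":
        net = _CNNNet(shapes[0], spec, rng)
        history = _train_network(net, inputs, y, spec, spec.cnn_batch,
                                 spec.cnn_epochs, rng)
        return TrainedModel(spec, net, shapes, history)
    net = _HybridNet(shapes[0], shapes[1], spec, rng)
    history = _train_network(net, inputs, y, spec, spec.hybrid_batch,
                             spec.hybrid_epochs, rng)
    return TrainedModel(spec, net, shapes, history)


def predict_scores(model: TrainedModel, x) -> np.ndarray:
    """Per-item (p_control, p_schizophrenia) score pairs.

    Softmax kinds return class probabilities; KNN returns the neighbor
    vote fraction; SVM returns a logistic map of its decision margin.
    Thresholding column 1 at 0.5 yields hard labels.
    """
    spec = model.spec
    inputs = _as_inputs(spec, x)
    for a, contract in zip(inputs, model.input_shapes):
        if a.shape[1:] != contract:
            raise ValueError(
                f"input shape {a.shape[1:]} does not match training "
                f"contract {contract}")
    if spec.kind == "knn":
        return model.state.predict_proba(inputs[0])
    if spec.kind == "svm":
        scaler, est = model.state
        margin = est.decision_function(scaler.transform(inputs[0]))
        p1 = 1.0 / (1.0 + np.exp(-margin))
        return np.column_stack([1.0 - p1, p1])
    logits = model.state.forward(inputs, training=False)
    return softmax(logits)
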