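"""The learning stage: splitting, SMOTE balancing, and a feed-forward
softmax classifier over voxel feature tables.

The network is the tabular architecture used for voxel-wise histology
classification: ten fully connected hidden layers, each followed by
batch normalization and an exponential-linear (ELU) activation, ending
in a fully connected softmax layer over the six classes. Training
minimizes cross-entropy with mini-batch Adam (β₁ = 0.9, β₂ = 0.999,
batch 200) and early-stops on validation loss, restoring the
best-validation weights. Features are additionally z-scored with
training-set statistics before the first layer, since the metric units
differ by orders of magnitude.

Class balancing uses SMOTE: each synthetic minority row is
x + u·(x_nn − x) with u ~ Uniform(0, 1) and x_nn one of the k nearest
same-class neighbors. Balancing is only ever applied to training data.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from dhikit.dbsi_fit import METRICS

logger = logging.getLogger(__name__)

__all__ = [
    "LABEL_COLUMN",
    "TrainConfig",
    "DNNModel",
    "split_dataset",
    "smote_balance",
    "train",
    "predict",
    "table_checksum",
]

LABEL_COLUMN = "histology_class"
_NON_FEATURE_COLUMNS = (LABEL_COLUMN, "voxel_id", "patient_id", "specimen_id")


@dataclass(frozen=True)
class TrainConfig:
    """Architecture and optimization hyper-parameters."""

    features: tuple[str, ...] = METRICS
    hidden_layers: int = 10
    hidden_width: int = 128
    batch_size: int = 200
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    n_classes: int = 6

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        for b in (self.beta1, self.beta2):
            if not 0.0 < b < 1.0:
                raise ValueError("Adam betas must lie in (0, 1)")


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        # He-style init suits ELU-family activations
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def grads(self):
        return [self.gw, self.gb]


class _BatchNorm:
    eps = 1e-5
    momentum = 0.9

    def __init__(self, n: int):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        return self.gamma * self._xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self.ggamma = (grad * xhat).sum(axis=0)
        self.gbeta = grad.sum(axis=0)
        m = grad.shape[0]
        return (self.gamma * self._istd) * (
            grad - grad.mean(axis=0) - xhat * (grad * xhat).mean(axis=0)
        ) if m > 1 else grad * self.gamma * self._istd

    def grads(self):
        return [self.ggamma, self.gbeta]


class _ELU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._out = _elu(x)
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * np.where(self._out > 0, 1.0, self._out + 1.0)

    def params(self):
        return []

    def grads(self):
        return []


@dataclass
class DNNModel:
    """Trained network: layers, feature normalization and class order."""

    config: TrainConfig
    layers: list
    feature_mean: np.ndarray
    feature_std: np.ndarray
    class_order: tuple[int, ...]
    history: dict[str, list[float]] = field(default_factory=dict)

    @property
    def n_hidden_layers(self) -> int:
        return sum(isinstance(l, _Dense) for l in self.layers) - 1

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = (x - self.feature_mean) / self.feature_std
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                h = layer.forward(h, training)
            else:
                h = layer.forward(h)
        return _softmax(h)


def _feature_columns(table: pd.DataFrame, features: tuple[str, ...] | None) -> list[str]:
    if features is not None:
        missing = [f for f in features if f not in table.columns]
        if missing:
            raise ValueError(f"feature columns missing from table: {missing}")
        return list(features)
    return [c for c in table.columns if c not in _NON_FEATURE_COLUMNS]


def table_checksum(table: pd.DataFrame) -> str:
    """Content hash used to assert no-leakage invariants."""
    return hashlib.sha256(
        pd.util.hash_pandas_object(table, index=True).to_numpy().tobytes()
    ).hexdigest()


def split_dataset(
    table: pd.DataFrame,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    stratified: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Random train/validation/test split.

    Test and validation sizes are ``round(ratio · N)`` (of the
    normalized ratios); train takes the remainder. Partitions are
    disjoint and exhaustive, and reproducible per seed. With
    ``stratified`` the rounding is applied class-wise, so global
    partition sizes can differ from the unstratified ones by at most
    one row per class.
    """
    r = np.asarray(ratios, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    r = r / r.sum()
    rng = np.random.default_rng(seed)

    def allocate(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = len(idx)
        n_test = int(round(r[2] * n))
        n_val = int(round(r[1] * n))
        perm = rng.permutation(idx)
        return perm[n_test + n_val:], perm[n_test:n_test + n_val], perm[:n_test]

    if stratified:
        if LABEL_COLUMN not in table.columns:
            raise ValueError("stratified split requires a label column")
        counts = table[LABEL_COLUMN].value_counts()
        if (counts < 3).any():
            small = counts[counts < 3].index.tolist()
            raise ValueError(f"classes with <3 rows cannot be stratified: {small}")
        parts: list[list[np.ndarray]] = [[], [], []]
        for cls in sorted(counts.index):
            idx = table.index[table[LABEL_COLUMN] == cls].to_numpy()
            for part, chunk in zip(parts, allocate(idx)):
                part.append(chunk)
        tr, va, te = (np.concatenate(p) for p in parts)
    else:
        tr, va, te = allocate(table.index.to_numpy())
    return table.loc[tr], table.loc[va], table.loc[te]


def smote_balance(
    table: pd.DataFrame,
    k_neighbors: int = 5,
    seed: int = 0,
    features: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Oversample every minority class up to the majority count.

    Synthetic rows interpolate a random class member toward one of its
    k nearest same-class neighbors; original rows are kept unchanged
    (synthetic rows get ``voxel_id`` −1 when that column exists).
    Classes with a single row fall back to duplication with a warning;
    k is clamped to class size − 1 with a warning.
    """
    if LABEL_COLUMN not in table.columns:
        raise ValueError("table has no label column")
    counts = table[LABEL_COLUMN].value_counts()
    if counts.empty:
        raise ValueError("empty table")
    cols = _feature_columns(table, features)
    target = int(counts.max())
    rng = np.random.default_rng(seed)
    synth_frames = [table]
    for cls in sorted(counts.index):
        n = int(counts[cls])
        deficit = target - n
        if deficit == 0:
            continue
        rows = table[table[LABEL_COLUMN] == cls]
        x = rows[cols].to_numpy(float)
        if n == 1:
            warnings.warn(
                f"class {cls} has a single row; duplicating instead of SMOTE")
            new = np.repeat(x, deficit, axis=0)
        else:
            k = k_neighbors
            if k > n - 1:
                warnings.warn(
                    f"class {cls}: k={k_neighbors} clamped to {n - 1}")
                k = n - 1
            nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
            _, nbrs = nn.kneighbors(x)  # column 0 is the point itself
            base = rng.integers(0, n, deficit)
            pick = nbrs[base, rng.integers(1, k + 1, deficit)]
            u = rng.uniform(0.0, 1.0, deficit)[:, None]
            new = x[base] + u * (x[pick] - x[base])
        frame = pd.DataFrame(new, columns=cols)
        frame[LABEL_COLUMN] = cls
        if "voxel_id" in table.columns:
            frame["voxel_id"] = -1
        synth_frames.append(frame[[c for c in table.columns if c in frame.columns]])
    out = pd.concat(synth_frames, ignore_index=True)
    return out


def _one_hot(labels: np.ndarray, order: tuple[int, ...]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(order)}
    y = np.zeros((len(labels), len(order)))
    y[np.arange(len(labels)), [lut[int(l)] for l in labels]] = 1.0
    return y


def _build_layers(rng: np.random.Generator, n_in: int, config: TrainConfig) -> list:
    layers: list = []
    width = config.hidden_width
    for i in range(config.hidden_layers):
        layers.append(_Dense(rng, n_in if i == 0 else width, width))
        layers.append(_BatchNorm(width))
        layers.append(_ELU())
    layers.append(_Dense(rng, width if config.hidden_layers else n_in,
                         config.n_classes))
    return layers


def train(
    train_table: pd.DataFrame,
    val_table: pd.DataFrame,
    config: TrainConfig | None = None,
) -> DNNModel:
    """Mini-batch Adam training with early stopping on validation loss.

    Deterministic given the seed (single-threaded numpy); the returned
    model carries the weights of the best validation epoch and the full
    loss history.
    """
    config = config or TrainConfig()
    if len(val_table) == 0:
        raise ValueError("empty validation table")
    cols = _feature_columns(train_table, config.features)
    x_tr = train_table[cols].to_numpy(float)
    x_va = val_table[cols].to_numpy(float)
    if not (np.all(np.isfinite(x_tr)) and np.all(np.isfinite(x_va))):
        raise ValueError("non-finite feature values")
    class_order = tuple(int(c) for c in sorted(
        set(train_table[LABEL_COLUMN]) | set(val_table[LABEL_COLUMN])))
    if len(class_order) > config.n_classes:
        raise ValueError("more classes in data than network outputs")
    order = class_order + tuple(
        c for c in range(config.n_classes) if c not in class_order)[: config.n_classes - len(class_order)]
    y_tr = _one_hot(train_table[LABEL_COLUMN].to_numpy(), order)
    y_va = _one_hot(val_table[LABEL_COLUMN].to_numpy(), order)

    mean = x_tr.mean(axis=0)
    std = x_tr.std(axis=0)
    std[std < 1e-12] = 1.0

    rng = np.random.default_rng(config.seed)
    layers = _build_layers(rng, len(cols), config)
    model = DNNModel(config=config, layers=layers, feature_mean=mean,
                     feature_std=std, class_order=order,
                     history={"train_loss": [], "val_loss": [], "val_error": []})

    params = [p for l in layers for p in l.params()]
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    t_step = 0

    def val_metrics() -> tuple[float, float]:
        p = model.forward(x_va, training=False)
        loss = -float(np.mean(np.log(np.clip(p[y_va.astype(bool)], 1e-12, None))))
        err = float(np.mean(p.argmax(1) != y_va.argmax(1)))
        return loss, err

    best_loss = np.inf
    best_state: list[np.ndarray] | None = None
    patience_left = config.patience
    n = len(x_tr)

    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb = (x_tr[idx] - mean) / std
            yb = y_tr[idx]
            h = xb
            for layer in layers:
                h = layer.forward(h, True) if isinstance(layer, _BatchNorm) else layer.forward(h)
            p = _softmax(h)
            batch_loss = -np.mean(np.log(np.clip(p[yb.astype(bool)], 1e-12, None)))
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"training diverged (NaN loss); lower the learning rate "
                    f"(currently {config.learning_rate})")
            epoch_loss += batch_loss * len(idx)
            grad = (p - yb) / len(idx)
            for layer in reversed(layers):
                grad = layer.backward(grad)
            t_step += 1
            grads = [g for l in layers for g in l.grads()]
            lr_t = config.learning_rate * (
                np.sqrt(1 - config.beta2**t_step) / (1 - config.beta1**t_step))
            for p_arr, g, m_a, v_a in zip(params, grads, m_adam, v_adam):
                m_a *= config.beta1
                m_a += (1 - config.beta1) * g
                v_a *= config.beta2
                v_a += (1 - config.beta2) * g * g
                p_arr -= lr_t * m_a / (np.sqrt(v_a) + 1e-8)
        vloss, verr = val_metrics()
        model.history["train_loss"].append(epoch_loss / n)
        model.history["val_loss"].append(vloss)
        model.history["val_error"].append(verr)
        if vloss < best_loss - 1e-6:
            best_loss = vloss
            best_state = [p.copy() for p in params] + [
                np.concatenate([l.run_mean, l.run_var])
                for l in layers if isinstance(l, _BatchNorm)]
            patience_left = config.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                logger.info("early stop at epoch %d (best val loss %.4f)",
                            epoch, best_loss)
                break

    if best_state is not None:  # restore best-validation weights
        for p_arr, saved in zip(params, best_state):
            p_arr[...] = saved
        bn_layers = [l for l in layers if isinstance(l, _BatchNorm)]
        for l, saved in zip(bn_layers, best_state[len(params):]):
            half = saved.shape[0] // 2
            l.run_mean = saved[:half].copy()
            l.run_var = saved[half:].copy()
    return model


def predict(
    model: DNNModel,
    features: pd.DataFrame | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels for a feature table.

    Probability rows sum to 1; the label is the argmax with the
    lowest-class-index tie-break. Columns of the probability matrix
    follow ``model.class_order``.
    """
    if isinstance(features, pd.DataFrame):
        x = features[list(_feature_columns(features, model.config.features))].to_numpy(float)
    else:
        x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.feature_mean.shape[0]:
        raise ValueError(
            f"expected {model.feature_mean.shape[0]} features, got {x.shape}")
    proba = model.forward(x, training=False)
    labels = np.asarray(model.class_order)[proba.argmax(axis=1)]
    return proba, labels
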