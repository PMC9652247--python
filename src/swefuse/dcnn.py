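"""The breast-lesion DCNN: architecture, shape arithmetic and training.

The default architecture is a four-convolution discriminative CNN for
224x224x3 inputs: an 11x11 stride-4 stem, three 3x3-pool downsamplings
with batch normalization, a 1024-unit fully connected layer and a single
sigmoid classification unit.  Training uses Adam (lr 1e-4), binary
cross-entropy, batch size 32 and up to 100 epochs by default; the input
shape, learning rate and epoch budget are configurable so the same stack
runs at reduced scale (e.g. 64x64) on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn

__all__ = ["DCNNConfig", "TrainedModel", "build_dcnn", "output_shape_trace",
           "train_model", "fit_network"]


@dataclass(frozen=True)
class DCNNConfig:
    """Architecture and training hyperparameters of the lesion classifier.

    The layer stack itself is fixed (it is the model under study); the
    fields here are the knobs the stack exposes.  ``checkpoint`` selects
    which epoch's weights the trained model keeps: ``"best_val_loss"``
    (default) or ``"last"``.
    """

    input_shape: tuple[int, int, int] = (224, 224, 3)
    dropout_rate: float = 0.5
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    dense_units: int = 1024
    bn_momentum: float = 0.99
    checkpoint: str = "best_val_loss"
    class_weight: dict[int, float] | None = None

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.input_shape) != 3:
            raise ValueError("input_shape must be (height, width, channels)")
        if self.checkpoint not in ("best_val_loss", "last"):
            raise ValueError("checkpoint must be 'best_val_loss' or 'last'")

    def with_(self, **kw) -> "DCNNConfig":
        return replace(self, **kw)


# (kind, arg-dict) rows of the fixed layer table
_LAYER_TABLE = [
    ("conv", dict(filters=64, kernel=11, stride=4)),
    ("pool", dict(pool=3, stride=2)),
    ("batchnorm", {}),
    ("conv", dict(filters=128, kernel=5, stride=1)),
    ("pool", dict(pool=3, stride=2)),
    ("batchnorm", {}),
    ("conv", dict(filters=256, kernel=3, stride=1)),
    ("conv", dict(filters=256, kernel=3, stride=1)),
    ("pool", dict(pool=3, stride=2)),
    ("dropout", {}),
    ("flatten", {}),
    ("dense", dict(units=None, activation="relu")),      # units = config.dense_units
    ("dense", dict(units=1, activation="sigmoid")),      # classification layer
]


def output_shape_trace(config: DCNNConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Pure shape arithmetic for the layer stack, no framework involved.

    Same-padded stride-``s`` convolutions map ``n -> ceil(n/s)``; valid
    pools map ``n -> floor((n-k)/s) + 1``.  Raises ``ValueError`` if a
    valid-padded pool window exceeds the running spatial size.
    """
    h, w, c = config.input_shape
    trace: list[tuple[str, tuple[int, ...]]] = [("input", (h, w, c))]
    for i, (kind, args) in enumerate(_LAYER_TABLE):
        if kind == "conv":
            s = args["stride"]
            h, w, c = math.ceil(h / s), math.ceil(w / s), args["filters"]
            trace.append((f"conv{args['filters']}_{i}", (h, w, c)))
        elif kind == "pool":
            k, s = args["pool"], args["stride"]
            if h < k or w < k:
                raise ValueError(
                    f"pool window {k} exceeds spatial size {h}x{w} at layer {i}"
                )
            h, w = (h - k) // s + 1, (w - k) // s + 1
            trace.append((f"maxpool_{i}", (h, w, c)))
        elif kind == "batchnorm":
            trace.append((f"batchnorm_{i}", (h, w, c)))
        elif kind == "dropout":
            trace.append((f"dropout_{i}", (h, w, c)))
        elif kind == "flatten":
            trace.append((f"flatten_{i}", (h * w * c,)))
        elif kind == "dense":
            units = args["units"] or config.dense_units
            trace.append((f"dense{units}_{i}", (units,)))
    return trace


def _make_layers(config: DCNNConfig, headless: bool) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    for kind, args in _LAYER_TABLE:
        if kind == "conv":
            layers.append(nn.Conv2D(args["filters"], args["kernel"], args["stride"], "relu"))
        elif kind == "pool":
            layers.append(nn.MaxPool2D(args["pool"], args["stride"]))
        elif kind == "batchnorm":
            layers.append(nn.BatchNorm(momentum=config.bn_momentum))
        elif kind == "dropout":
            layers.append(nn.Dropout(config.dropout_rate))
        elif kind == "flatten":
            layers.append(nn.Flatten())
        elif kind == "dense":
            units = args["units"] or config.dense_units
            layers.append(nn.Dense(units, args["activation"]))
    if headless:
        layers = layers[:-1]  # drop only the final Dense(1, sigmoid)
    return layers


@dataclass
class TrainedModel:
    """A (possibly untrained) classifier plus its config and history."""

    network: nn.Sequential
    config: DCNNConfig
    headless: bool = False
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict(self, x: np.ndarray) -> np.ndarray:
        out = self.network.predict(np.asarray(x, dtype=np.float32))
        return out if self.headless else out[:, 0]


def build_dcnn(config: DCNNConfig, headless: bool = False, seed: int = 0) -> TrainedModel:
    """Instantiate the layer stack with seeded weight initialization.

    ``headless=True`` removes only the final single-unit sigmoid layer,
    exposing the ``dense_units``-dimensional representation for
    feature-level fusion.
    """
    output_shape_trace(config)  # validates spatial feasibility up front
    net = nn.Sequential(_make_layers(config, headless), config.input_shape, seed)
    return TrainedModel(network=net, config=config, headless=headless)


# ---------------------------------------------------------------------------
# training


def _take(x, idx):
    if isinstance(x, tuple):
        return tuple(a[idx] for a in x)
    return x[idx]


def _n_rows(x) -> int:
    return len(x[0]) if isinstance(x, tuple) else len(x)


def _auc_or_nan(y: np.ndarray, p: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, p))


def fit_network(network, x_train, y_train, x_val, y_val, config: DCNNConfig,
                seed: int, epochs: int | None = None) -> pd.DataFrame:
    """Generic Adam/BCE training loop shared by plain and two-stream nets.

    ``x_*`` may be a single array stack or a tuple of two aligned stacks
    (for the two-input parallel network).  Shuffling, dropout and weight
    restoration are all driven by ``seed``; two runs with the same seed in
    a single-threaded process produce identical histories and weights.
    """
    y_train = np.asarray(y_train, dtype=np.float32)
    y_val = np.asarray(y_val, dtype=np.float32)
    if _n_rows(x_train) == 0:
        raise ValueError("empty training set")
    for y in (y_train, y_val):
        if y.size and not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("labels must be binary 0/1")
    n_epochs = config.epochs if epochs is None else epochs
    rng = np.random.default_rng(seed)
    opt = nn.Adam(network, learning_rate=config.learning_rate)
    n = _n_rows(x_train)

    sample_w = None
    if config.class_weight:
        sample_w = np.where(y_train == 1,
                            config.class_weight.get(1, 1.0),
                            config.class_weight.get(0, 1.0)).astype(np.float32)

    records = []
    best = (np.inf, None)
    for epoch in range(n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = _take(x_train, idx), y_train[idx]
            p = network.forward(xb, training=True, rng=rng)[:, 0]
            delta = (p - yb) / len(yb)
            if sample_w is not None:
                delta = delta * sample_w[idx]
            network.backward_from_logits(delta[:, None])
            opt.step()

        p_tr = network.predict(x_train)[:, 0]
        p_va = network.predict(x_val)[:, 0] if _n_rows(x_val) else np.empty(0, np.float32)
        rec = {
            "epoch": epoch,
            "loss": nn.binary_cross_entropy(y_train, p_tr),
            "accuracy": float(np.mean((p_tr >= 0.5) == y_train)),
            "auc": _auc_or_nan(y_train, p_tr),
            "val_loss": nn.binary_cross_entropy(y_val, p_va) if y_val.size else float("nan"),
            "val_accuracy": float(np.mean((p_va >= 0.5) == y_val)) if y_val.size else float("nan"),
            "val_auc": _auc_or_nan(y_val, p_va) if y_val.size else float("nan"),
        }
        records.append(rec)
        if y_val.size and rec["val_loss"] < best[0]:
            best = (rec["val_loss"], network.get_weights())

    if config.checkpoint == "best_val_loss" and best[1] is not None:
        network.set_weights(best[1])
    return pd.DataFrame.from_records(records)


def train_model(model: TrainedModel, train_set, val_set, seed: int,
                epochs: int | None = None) -> TrainedModel:
    """Train a single-input classifier on ``(images, labels)`` stacks."""
    if model.headless:
        raise ValueError("cannot train a headless model directly; it has no classifier")
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    model.history = fit_network(model.network, x_tr, y_tr, x_va, y_va,
                                model.config, seed, epochs=epochs)
    return model
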