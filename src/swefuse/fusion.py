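"""The three US + SWE combination topologies.

* **Generalized** — one classifier trained on the pooled US and SWE
  stacks (so its training set is twice the paired size); at prediction
  time both modality images are fed through it and the two output
  probabilities are averaged.
* **Ensembled** — two independently trained classifiers with identical
  architecture, one per modality; their output probabilities are
  averaged.
* **Parallel** — two identical headless trunks (the classifier minus its
  final sigmoid unit), one per modality, whose 1024-dimensional features
  are concatenated into a 2048-vector feeding a single shared sigmoid
  unit; trained end-to-end and requiring both modalities at prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .dcnn import DCNNConfig, TrainedModel, build_dcnn, fit_network, train_model

__all__ = ["FusionMethod", "generalized_pool", "train_generalized",
           "predict_generalized", "train_ensembled", "predict_ensembled",
           "build_and_train_parallel", "predict_parallel", "predict_fused"]

METHOD_NAMES = ("GENERALIZED", "ENSEMBLED", "PARALLEL")


@dataclass
class FusionMethod:
    name: str
    config: DCNNConfig
    models: list[TrainedModel] = field(default_factory=list)  # GENERALIZED/ENSEMBLED
    network: nn.TwoStreamNetwork | None = None                # PARALLEL
    history: pd.DataFrame | None = None

    def __post_init__(self):
        if self.name not in METHOD_NAMES:
            raise ValueError(f"unknown fusion method {self.name!r}")


def _check_paired(us: np.ndarray, swe: np.ndarray,
                  y_us: np.ndarray | None = None,
                  y_swe: np.ndarray | None = None) -> None:
    if us is None or swe is None:
        raise ValueError("this method needs both US and SWE stacks simultaneously")
    if len(us) != len(swe):
        raise ValueError("US and SWE stacks must be index-aligned pairs")
    if y_us is not None and y_swe is not None and not np.array_equal(y_us, y_swe):
        raise ValueError("US and SWE stacks disagree on labels; pairing is broken")


# ---------------------------------------------------------------------------
# generalized: one model, pooled training, averaged prediction


def generalized_pool(us: np.ndarray, y_us: np.ndarray,
                     swe: np.ndarray, y_swe: np.ndarray,
                     seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Stack US rows then SWE rows (labels duplicated), optional seeded shuffle.

    The pooled stack has exactly twice the paired size — the bookkeeping
    the protocol's split table reports for this method.
    """
    _check_paired(us, swe, y_us, y_swe)
    x = np.concatenate([us, swe], axis=0)
    y = np.concatenate([y_us, y_swe], axis=0)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(x))
        x, y = x[order], y[order]
    return x, y


def train_generalized(us_train, y_train, swe_train, val_us, y_val, val_swe,
                      config: DCNNConfig, seed: int,
                      epochs: int | None = None) -> FusionMethod:
    x_tr, y_tr = generalized_pool(us_train, y_train, swe_train, y_train, seed=seed)
    x_va, y_va = generalized_pool(val_us, y_val, val_swe, y_val, seed=None)
    model = build_dcnn(config, headless=False, seed=seed)
    train_model(model, (x_tr, y_tr), (x_va, y_va), seed=seed, epochs=epochs)
    return FusionMethod(name="GENERALIZED", config=config, models=[model],
                        history=model.history)


def predict_generalized(method: FusionMethod, us: np.ndarray,
                        swe: np.ndarray) -> np.ndarray:
    if method.name != "GENERALIZED":
        raise ValueError(f"predict_generalized got a {method.name} method")
    _check_paired(us, swe)
    model = method.models[0]
    return 0.5 * (model.predict(us) + model.predict(swe))


# ---------------------------------------------------------------------------
# ensembled: two models, averaged prediction


def train_ensembled(us_train, y_train, swe_train, val_us, y_val, val_swe,
                    config: DCNNConfig, seed: int,
                    epochs: int | None = None) -> FusionMethod:
    """Train one classifier per modality (seeds ``seed`` and ``seed + 1``)."""
    _check_paired(us_train, swe_train)
    us_model = build_dcnn(config, headless=False, seed=seed)
    train_model(us_model, (us_train, y_train), (val_us, y_val),
                seed=seed, epochs=epochs)
    swe_model = build_dcnn(config, headless=False, seed=seed + 1)
    train_model(swe_model, (swe_train, y_train), (val_swe, y_val),
                seed=seed + 1, epochs=epochs)
    return FusionMethod(name="ENSEMBLED", config=config,
                        models=[us_model, swe_model])


def predict_ensembled(method: FusionMethod, us: np.ndarray,
                      swe: np.ndarray) -> np.ndarray:
    if method.name != "ENSEMBLED":
        raise ValueError(f"predict_ensembled got a {method.name} method")
    _check_paired(us, swe)
    us_model, swe_model = method.models
    return 0.5 * (us_model.predict(us) + swe_model.predict(swe))


# ---------------------------------------------------------------------------
# parallel: two headless trunks, concatenated features, one sigmoid unit


def build_and_train_parallel(us_train, y_train, swe_train, val_us, y_val, val_swe,
                             config: DCNNConfig, seed: int,
                             epochs: int | None = None,
                             combiner: str = "concat") -> FusionMethod:
    """End-to-end training of the two-input feature-fusion network.

    The default combiner concatenates the two 1024-feature vectors into
    2048 inputs for the sigmoid unit; ``combiner="average"`` averages
    them instead.
    """
    _check_paired(us_train, swe_train)
    _check_paired(val_us, val_swe)
    trunk_us = build_dcnn(config, headless=True, seed=seed).network
    trunk_swe = build_dcnn(config, headless=True, seed=seed + 1).network
    head = nn.Dense(1, activation="sigmoid")
    net = nn.TwoStreamNetwork(trunk_us, trunk_swe, head, seed=seed + 2,
                              combiner=combiner)
    history = fit_network(net, (us_train, swe_train), y_train,
                          (val_us, val_swe), y_val, config, seed, epochs=epochs)
    return FusionMethod(name="PARALLEL", config=config, network=net,
                        history=history)


def predict_parallel(method: FusionMethod, us: np.ndarray,
                     swe: np.ndarray) -> np.ndarray:
    if method.name != "PARALLEL":
        raise ValueError(f"predict_parallel got a {method.name} method")
    _check_paired(us, swe)
    return method.network.predict((np.asarray(us, np.float32),
                                   np.asarray(swe, np.float32)))[:, 0]


def predict_fused(method: FusionMethod, us: np.ndarray,
                  swe: np.ndarray) -> np.ndarray:
    """Dispatch prediction for any of the three fusion topologies."""
    if method.name == "GENERALIZED":
        return predict_generalized(method, us, swe)
    if method.name == "ENSEMBLED":
        return predict_ensembled(method, us, swe)
    return predict_parallel(method, us, swe)
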