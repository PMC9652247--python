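"""Repeated-split evaluation protocol and classification metrics.

The study protocol splits the cohort 70/15/15 into train/validation/test,
builds the model, measures accuracy, sensitivity, specificity and AUC on
the held-out test part, and repeats the whole procedure 20 times with
fresh splits and fresh initialization; results are summarized as the mean
and sample standard deviation over runs.  Malignant is the positive
class; the decision threshold is 0.5 on the predicted probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = ["SplitAssignment", "RunMetrics", "MetricsSummary",
           "split_dataset", "compute_metrics", "repeated_evaluation",
           "largest_remainder"]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "auc")


@dataclass(frozen=True)
class SplitAssignment:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratios: tuple[float, float, float]
    seed: int
    grouping: str  # "image_level" | "patient_level"

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train_ids), len(self.val_ids), len(self.test_ids))


@dataclass(frozen=True)
class RunMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}

    def as_percent(self) -> dict[str, float]:
        return {m: 100.0 * getattr(self, m) for m in METRIC_NAMES}


@dataclass(frozen=True)
class MetricsSummary:
    """Mean and sample SD (ddof=1) of each metric over repeated runs."""

    mu: dict[str, float]
    sigma: dict[str, float]
    n_runs: int
    n_failed: int = 0
    metadata: dict = field(default_factory=dict)


def largest_remainder(n: int, ratios: tuple[float, ...]) -> tuple[int, ...]:
    """Apportion ``n`` items to parts with the largest-remainder rule."""
    raw = np.asarray(ratios, dtype=np.float64) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return tuple(int(c) for c in counts)


def split_dataset(manifest: pd.DataFrame,
                  ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 0,
                  grouping: str = "image_level",
                  stratified: bool = True) -> SplitAssignment:
    """Partition the manifest into disjoint train/validation/test id sets.

    Image-level splits apportion sizes with the largest-remainder rule
    (within each class when stratified) after a seeded shuffle, so 746
    samples at 70/15/15 give exactly (522, 112, 112).  Patient-level
    splits assign whole patients greedily toward the same targets, so
    sizes are approximate but no patient straddles partitions.
    """
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    n = len(manifest)
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if grouping not in ("image_level", "patient_level"):
        raise ValueError("grouping must be 'image_level' or 'patient_level'")
    rng = np.random.default_rng(seed)
    ids = manifest["sample_id"].astype(str).to_numpy()
    labels = manifest["label"].to_numpy()

    parts: list[list[str]] = [[], [], []]
    if grouping == "image_level":
        groups = ([np.where(labels == lab)[0] for lab in np.unique(labels)]
                  if stratified else [np.arange(n)])
        targets = largest_remainder(n, ratios)
        sizes_per_group = [list(largest_remainder(len(idx), ratios))
                           for idx in groups]
        # reconcile per-class rounding so the overall sizes hit the
        # largest-remainder targets exactly
        totals = [sum(s[p] for s in sizes_per_group) for p in range(3)]
        while totals != list(targets):
            over = next(p for p in range(3) if totals[p] > targets[p])
            under = next(p for p in range(3) if totals[p] < targets[p])
            donor = max(range(len(groups)), key=lambda g: sizes_per_group[g][over])
            sizes_per_group[donor][over] -= 1
            sizes_per_group[donor][under] += 1
            totals[over] -= 1
            totals[under] += 1
        for idx, sizes in zip(groups, sizes_per_group):
            idx = idx.copy()
            rng.shuffle(idx)
            offsets = np.cumsum((0, *sizes))
            for p in range(3):
                parts[p].extend(ids[idx[offsets[p]:offsets[p + 1]]])
    else:
        patients = manifest["patient_id"].astype(str).to_numpy()
        uniq = pd.unique(patients)
        order = rng.permutation(len(uniq))
        targets = largest_remainder(n, ratios)
        filled = [0, 0, 0]
        for u in uniq[order]:
            members = ids[patients == u]
            # put the whole patient where the deficit is largest
            deficits = [targets[p] - filled[p] for p in range(3)]
            p = int(np.argmax(deficits))
            parts[p].extend(members)
            filled[p] += len(members)

    assignment = SplitAssignment(train_ids=tuple(parts[0]), val_ids=tuple(parts[1]),
                                 test_ids=tuple(parts[2]), ratios=tuple(ratios),
                                 seed=seed, grouping=grouping)
    assert sum(assignment.sizes) == n
    return assignment


def compute_metrics(labels: np.ndarray, probabilities: np.ndarray,
                    threshold: float = 0.5) -> RunMetrics:
    """Accuracy, sensitivity, specificity at ``threshold`` plus rank AUC.

    Malignant (label 1) is positive; predictions are ``p >= threshold``.
    AUC uses the rank statistic (ties count one half), equivalent to
    exhaustive positive-negative pair counting.  Raises if a class is
    absent, naming the undefined metric.
    """
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if labels.shape != probabilities.shape:
        raise ValueError("labels and probabilities must be aligned")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pos = labels == 1
    neg = ~pos
    if not pos.any():
        raise ValueError("sensitivity and AUC undefined: no malignant (positive) samples")
    if not neg.any():
        raise ValueError("specificity and AUC undefined: no benign (negative) samples")
    pred = probabilities >= threshold
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & neg))
    return RunMetrics(
        accuracy=(tp + tn) / labels.size,
        sensitivity=tp / pos.sum(),
        specificity=tn / neg.sum(),
        auc=float(roc_auc_score(labels, probabilities)),
    )


def repeated_evaluation(method_builder, manifest: pd.DataFrame,
                        samples: list, n_runs: int = 20, master_seed: int = 0,
                        ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
                        grouping: str = "image_level",
                        stratified: bool = True,
                        resplit_each_run: bool = True
                        ) -> tuple[MetricsSummary, pd.DataFrame]:
    """Build and evaluate a model ``n_runs`` times; summarize mean and SD.

    Run ``r`` uses seed ``master_seed + r`` for its split and its model
    initialization (set ``resplit_each_run=False`` to freeze the split at
    ``master_seed`` and vary only the initialization).  ``method_builder``
    is called as ``(train_samples, val_samples, seed) -> predict_fn`` with
    ``predict_fn(test_samples) -> probabilities``.  Failed runs are
    recorded and excluded from the summary, which reports both counts.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    by_id = {s.sample_id: s for s in samples}
    rows, failures = [], []
    for r in range(n_runs):
        seed = master_seed + r
        split_seed = seed if resplit_each_run else master_seed
        split = split_dataset(manifest, ratios=ratios, seed=split_seed,
                              grouping=grouping, stratified=stratified)
        train = [by_id[i] for i in split.train_ids]
        val = [by_id[i] for i in split.val_ids]
        test = [by_id[i] for i in split.test_ids]
        try:
            predict = method_builder(train, val, seed)
            probs = np.asarray(predict(test), dtype=np.float64)
            m = compute_metrics(np.array([s.label for s in test]), probs)
        except Exception as exc:  # noqa: BLE001 - per-run failures are data
            failures.append({"run": r, "seed": seed, "error": str(exc)})
            continue
        rows.append({"run": r, "seed": seed, **m.as_dict()})
    per_run = pd.DataFrame(rows, columns=["run", "seed", *METRIC_NAMES])
    if len(per_run) == 0:
        raise RuntimeError(f"all {n_runs} runs failed; first error: {failures[0]['error']}")
    mu = {m: float(per_run[m].mean()) for m in METRIC_NAMES}
    sigma = {m: float(per_run[m].std(ddof=1)) for m in METRIC_NAMES}
    summary = MetricsSummary(mu=mu, sigma=sigma, n_runs=len(per_run),
                             n_failed=len(failures),
                             metadata={"master_seed": master_seed,
                                       "resplit_each_run": resplit_each_run,
                                       "grouping": grouping,
                                       "failures": failures})
    return summary, per_run
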