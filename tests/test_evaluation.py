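"""Split apportionment, metric definitions and the repeated-run protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swefuse.evaluation import (compute_metrics, largest_remainder,
                                repeated_evaluation, split_dataset)


def _manifest(n, n_malignant=None, n_patients=None, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    if n_malignant is None:
        n_malignant = n // 2
    labels[:n_malignant] = 1
    rng.shuffle(labels)
    patients = (rng.integers(0, n_patients, n) if n_patients
                else np.arange(n))
    return pd.DataFrame({"sample_id": [f"S{i:05d}" for i in range(n)],
                         "patient_id": [f"P{p:04d}" for p in patients],
                         "label": labels})


def brute_force_auc(labels, probs):
    """Exhaustive positive-negative pair counting with ties at one half."""
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestSplit:
    def test_clinical_cohort_sizes(self):
        """746 samples at 70/15/15 -> (522, 112, 112), the protocol's table."""
        split = split_dataset(_manifest(746, 486), seed=0)
        assert split.sizes == (522, 112, 112)

    def test_largest_remainder_small_n(self):
        assert largest_remainder(20, (0.70, 0.15, 0.15)) == (14, 3, 3)
        split = split_dataset(_manifest(20), seed=1)
        assert split.sizes == (14, 3, 3)

    def test_partitions_disjoint_and_exhaustive(self):
        man = _manifest(101, 37)
        split = split_dataset(man, seed=5)
        all_ids = set(split.train_ids) | set(split.val_ids) | set(split.test_ids)
        assert len(all_ids) == 101
        assert not set(split.train_ids) & set(split.test_ids)
        assert not set(split.train_ids) & set(split.val_ids)
        assert not set(split.val_ids) & set(split.test_ids)

    def test_determinism_and_size_invariance(self):
        man = _manifest(746, 486)
        a = split_dataset(man, seed=3)
        b = split_dataset(man, seed=3)
        c = split_dataset(man, seed=4)
        assert a == b
        assert c.sizes == a.sizes
        assert set(c.train_ids) != set(a.train_ids)

    def test_stratification_preserves_class_ratio(self):
        man = _manifest(746, 486)
        split = split_dataset(man, seed=2, stratified=True)
        by_id = man.set_index("sample_id")["label"]
        test_labels = by_id.loc[list(split.test_ids)]
        assert int(test_labels.sum()) == round(486 * 0.15)

    def test_patient_level_split_keeps_patients_together(self):
        man = _manifest(100, 40, n_patients=20, seed=7)
        split = split_dataset(man, seed=0, grouping="patient_level")
        by_patient = man.set_index("sample_id")["patient_id"]
        parts = [set(by_patient.loc[list(ids)])
                 for ids in (split.train_ids, split.val_ids, split.test_ids)]
        assert not parts[0] & parts[1]
        assert not parts[0] & parts[2]
        assert not parts[1] & parts[2]
        assert sum(split.sizes) == 100

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(_manifest(10), ratios=(0.5, 0.2, 0.2))


class TestMetrics:
    def test_perfect_separation(self):
        m = compute_metrics(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.1, 0.2]))
        assert (m.accuracy, m.sensitivity, m.specificity, m.auc) == (1, 1, 1, 1)

    def test_mixed_case_frozen_confusion_counts(self):
        # TP=2, FP=1, TN=1, FN=0; AUC by pair enumeration = 3/4
        m = compute_metrics(np.array([1, 0, 1, 0]), np.array([0.6, 0.7, 0.8, 0.2]))
        assert m.accuracy == 0.75
        assert m.sensitivity == 1.0
        assert m.specificity == 0.5
        assert m.auc == 0.75

    def test_complete_ties_auc_half(self):
        m = compute_metrics(np.array([1, 0]), np.array([0.5, 0.5]))
        assert m.auc == 0.5

    def test_single_class_raises_naming_metric(self):
        with pytest.raises(ValueError, match="specificity"):
            compute_metrics(np.ones(4), np.full(4, 0.7))
        with pytest.raises(ValueError, match="sensitivity"):
            compute_metrics(np.zeros(4), np.full(4, 0.3))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(4, 50), st.integers(0, 2 ** 31 - 1))
    def test_rank_auc_equals_pair_counting(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, int)
        labels[:rng.integers(1, n)] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            return
        probs = np.round(rng.random(n), 2)  # rounding forces ties
        m = compute_metrics(labels, probs)
        assert m.auc == pytest.approx(brute_force_auc(labels, probs), abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(4, 60), st.integers(0, 2 ** 31 - 1))
    def test_accuracy_recoverable_from_sens_spec(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = (rng.random(n) < 0.5).astype(int)
        if labels.sum() in (0, n):
            return
        probs = rng.random(n)
        m = compute_metrics(labels, probs)
        p, q = labels.sum(), n - labels.sum()
        assert m.accuracy == pytest.approx(
            (m.sensitivity * p + m.specificity * q) / n, abs=1e-12)


class TestRepeatedEvaluation:
    class _Sample:
        def __init__(self, sid, label):
            self.sample_id, self.patient_id, self.label = sid, "P0", label

    def _cohort(self, n=40):
        man = _manifest(n, n // 2, seed=1)
        samples = [self._Sample(r.sample_id, r.label) for r in man.itertuples()]
        return man, samples

    def test_oracle_predictor_gives_mu_one_sigma_zero(self):
        man, samples = self._cohort()
        builder = lambda train, val, seed: (
            lambda test: np.array([s.label for s in test], float))
        summary, per_run = repeated_evaluation(builder, man, samples,
                                              n_runs=5, master_seed=0)
        assert len(per_run) == 5
        assert summary.mu["accuracy"] == 1.0
        assert summary.sigma["accuracy"] == 0.0

    def test_reproducible_per_run_table(self):
        man, samples = self._cohort()
        rng_builder = lambda train, val, seed: (
            lambda test: np.random.default_rng(seed).random(len(test)))
        _, a = repeated_evaluation(rng_builder, man, samples, n_runs=4, master_seed=9)
        _, b = repeated_evaluation(rng_builder, man, samples, n_runs=4, master_seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_runs_use_distinct_seeds_and_splits(self):
        man, samples = self._cohort()
        seen = []
        builder = lambda train, val, seed: (
            seen.append((seed, tuple(s.sample_id for s in train)))
            or (lambda test: np.random.default_rng(seed).random(len(test))))
        repeated_evaluation(builder, man, samples, n_runs=3, master_seed=100)
        seeds = [s for s, _ in seen]
        trains = [t for _, t in seen]
        assert seeds == [100, 101, 102]
        assert len(set(trains)) == 3

    def test_failed_runs_reported_not_fatal(self):
        man, samples = self._cohort()
        def builder(train, val, seed):
            if seed % 2 == 0:
                raise RuntimeError("boom")
            return lambda test: np.random.default_rng(seed).random(len(test))
        summary, per_run = repeated_evaluation(builder, man, samples,
                                              n_runs=4, master_seed=0)
        assert summary.n_runs == 2
        assert summary.n_failed == 2

    def test_minimum_two_runs(self):
        man, samples = self._cohort()
        with pytest.raises(ValueError):
            repeated_evaluation(lambda *a: None, man, samples, n_runs=1)
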