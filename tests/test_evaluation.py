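"""Fold construction, confusion metrics, ROC/AUC and CV bookkeeping."""

import numpy as np
import pytest

import dualeeg as dg
from dualeeg.evaluation import (ConfusionCounts, confusion_and_metrics,
                                cross_validate, roc_auc, stratified_kfold)
from dualeeg.models import ModelSpec


def brute_auc(truth, scores):
    """Mann-Whitney U / (n1 * n0): pairwise comparisons with tie = 1/2."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestStratifiedKFold:
    def test_exact_divisibility_balances_folds(self):
        y = np.array([0, 1] * 5)
        folds = stratified_kfold(y, 5, seed=0)
        for f in range(5):
            sel = folds == f
            assert sel.sum() == 2
            assert y[sel].sum() == 1

    def test_class_balance_within_one(self):
        rng = np.random.default_rng(0)
        y = (rng.random(83) < 0.45).astype(int)
        folds = stratified_kfold(y, 5, seed=1)
        for cls in (0, 1):
            per_fold = [((folds == f) & (y == cls)).sum() for f in range(5)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_subject_level_keeps_groups_whole(self):
        y = np.repeat([0, 1, 0, 1, 0, 1, 0, 1], 6)
        groups = np.repeat(np.arange(8), 6)
        folds = stratified_kfold(y, 4, seed=0, group_ids=groups)
        for g in np.unique(groups):
            assert np.unique(folds[groups == g]).size == 1

    def test_deterministic_given_seed(self):
        y = np.array([0, 1] * 20)
        a = stratified_kfold(y, 5, seed=3)
        b = stratified_kfold(y, 5, seed=3)
        assert np.array_equal(a, b)

    def test_k_larger_than_class_rejected(self):
        y = np.array([0, 0, 0, 1, 1, 1, 0, 0])
        with pytest.raises(ValueError, match="class size"):
            stratified_kfold(y, 4, seed=0)


class TestConfusionMetrics:
    def test_printed_worked_example(self):
        """FN=4, FP=3 over 409 schizophrenia / 394 healthy windows."""
        truth = np.concatenate([np.ones(409, int), np.zeros(394, int)])
        scores = truth.astype(float).copy()
        scores[:4] = 0.0          # 4 missed positives
        scores[409:412] = 1.0     # 3 false alarms
        counts, metrics = confusion_and_metrics(truth, scores)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (405, 4, 391, 3)
        assert round(100 * metrics["specificity"], 2) == 99.24
        assert metrics["sensitivity"] == pytest.approx(405 / 409)
        assert metrics["accuracy"] == pytest.approx(796 / 803)

    def test_all_correct(self):
        truth = np.array([0, 1, 0, 1])
        counts, metrics = confusion_and_metrics(truth, truth.astype(float))
        assert metrics == {"accuracy": 1.0, "sensitivity": 1.0,
                           "specificity": 1.0}
        assert counts.n == 4

    def test_single_class_truth_gives_undefined_metric(self):
        truth = np.ones(5, int)
        _, metrics = confusion_and_metrics(truth, np.ones(5))
        assert metrics["specificity"] is None
        assert metrics["sensitivity"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_and_metrics(np.array([]), np.array([]))

    def test_counts_partition_items(self, rng):
        truth = (rng.random(50) < 0.5).astype(int)
        scores = rng.random(50)
        counts, _ = confusion_and_metrics(truth, scores)
        assert counts.n == 50


class TestROC:
    def test_perfect_separation_auc_one(self):
        truth = np.array([0, 0, 1, 1])
        points, auc = roc_auc(truth, np.array([0.1, 0.2, 0.8, 0.9]))
        assert auc == 1.0
        assert tuple(points[0]) == (0.0, 0.0)
        assert tuple(points[-1]) == (1.0, 1.0)

    def test_constant_scores_auc_half(self):
        truth = np.array([0, 1, 0, 1])
        _, auc = roc_auc(truth, np.full(4, 0.5))
        assert auc == 0.5

    def test_roc_monotone(self, rng):
        truth = (rng.random(40) < 0.5).astype(int)
        points, _ = roc_auc(truth, rng.random(40))
        assert (np.diff(points[:, 0]) >= 0).all()
        assert (np.diff(points[:, 1]) >= 0).all()

    def test_auc_equals_mann_whitney_u(self, rng):
        """Trapezoidal AUC = normalized U statistic, ties included."""
        for _ in range(100):
            n = int(rng.integers(6, 50))
            truth = np.zeros(n, int)
            truth[rng.choice(n, size=int(rng.integers(2, n - 1)),
                             replace=False)] = 1
            if truth.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # rounding induces ties
            _, auc = roc_auc(truth, scores)
            assert auc == pytest.approx(brute_auc(truth, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.ones(4, int), np.ones(4))


@pytest.fixture(scope="module")
def knn_report(small_dataset):
    spec = ModelSpec(kind="knn", knn_k=3, input_mode="single:plv")
    return cross_validate(spec, small_dataset, k=3, seed=0), small_dataset


class TestCrossValidate:
    def test_pooled_counts_sum_to_dataset_size(self, knn_report):
        report, ds = knn_report
        assert report.pooled_counts.n == len(ds)

    def test_metric_identities_hold_per_fold(self, knn_report):
        report, _ = knn_report
        for f in report.folds:
            c = f.counts
            if f.metrics["accuracy"] is not None:
                assert f.metrics["accuracy"] == pytest.approx(
                    (c.tp + c.tn) / c.n)
            if f.metrics["sensitivity"] is not None:
                assert f.metrics["sensitivity"] == pytest.approx(
                    c.tp / (c.tp + c.fn))

    def test_fold_assignment_is_a_partition(self, knn_report):
        report, ds = knn_report
        seen = np.concatenate([f.test_indices for f in report.folds])
        assert sorted(seen) == list(range(len(ds)))

    def test_subject_level_mode_keeps_subjects_whole(self, small_dataset):
        spec = ModelSpec(kind="knn", knn_k=3, input_mode="single:plv")
        report = cross_validate(spec, small_dataset, k=3, seed=0,
                                subject_level=True)
        subjects = small_dataset.subject_ids()
        for f in report.folds:
            test_subj = set(subjects[f.test_indices])
            train_subj = set(subjects) - test_subj
            assert not (test_subj & train_subj)

    def test_deterministic_given_seed(self, small_dataset):
        spec = ModelSpec(kind="knn", knn_k=3, input_mode="single:pearson")
        a = cross_validate(spec, small_dataset, k=3, seed=4)
        b = cross_validate(spec, small_dataset, k=3, seed=4)
        assert a.summary() == b.summary()
        assert np.array_equal(a.fold_assignment, b.fold_assignment)

    def test_label_shuffle_gives_chance_auc(self, small_dataset):
        """Permuting labels should destroy the signal (AUC near 1/2)."""
        rng = np.random.default_rng(0)
        aucs = []
        for rep in range(5):
            items = list(small_dataset.items)
            labels = [it.label for it in items]
            rng.shuffle(labels)
            import copy
            shuffled = [copy.copy(it) for it in items]
            for it, lab in zip(shuffled, labels):
                it.label = lab
            ds = dg.FeatureDataset(shuffled, small_dataset.temporal_cfg,
                                   small_dataset.functional_cfg)
            if ds.labels().sum() in (0, len(ds)):
                continue
            spec = ModelSpec(kind="knn", knn_k=3, input_mode="single:plv")
            aucs.append(cross_validate(spec, ds, k=2, seed=rep).pooled_auc)
        assert abs(np.mean(aucs) - 0.5) < 0.25


def test_confusion_counts_addition():
    a = ConfusionCounts(1, 2, 3, 4)
    b = ConfusionCounts(10, 20, 30, 40)
    s = a + b
    assert (s.tp, s.fp, s.tn, s.fn) == (11, 22, 33, 44)
    assert s.n == 110
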