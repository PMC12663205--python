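"""Cross-validated evaluation: confusion counts, metrics, ROC/AUC, reports.

Schizophrenia is the positive class throughout: sensitivity = TP/(TP+FN)
is the schizophrenia detection rate, specificity = TN/(TN+FP) the healthy
recognition rate.  Metrics with an empty denominator are reported as None
(undefined), never as 0.  The default protocol is stratified 5-fold
cross-validation at the window level; subject-level grouping (all windows
of one subject in one fold) is available because window-level splits let
the model see other windows of a test subject during training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .models import ModelSpec, fit
from .pipeline import FeatureDataset

__all__ = [
    "ConfusionCounts", "CVReport", "stratified_kfold",
    "confusion_and_metrics", "roc_auc", "cross_validate",
]


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN with schizophrenia as the positive class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    def metrics(self) -> dict[str, float | None]:
        """accuracy, sensitivity, specificity; None where undefined."""
        acc = (self.tp + self.tn) / self.n if self.n else None
        sens = self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None
        spec = self.tn / (self.tn + self.fp) if (self.tn + self.fp) else None
        return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


def stratified_kfold(labels: np.ndarray, k: int, seed: int = 0,
                     group_ids: np.ndarray | None = None) -> np.ndarray:
    """Fold index (0..k-1) per item; class-balanced within +-1 item.

    With ``group_ids`` (subject-level mode) every group lands in exactly
    one fold.  Deterministic given ``seed``.
    """
    labels = np.asarray(labels).ravel()
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"k={k} exceeds the smallest class size {counts.min()}")
    assignment = np.empty(labels.size, dtype=int)
    if group_ids is None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (_, test) in enumerate(splitter.split(labels[:, None], labels)):
            assignment[test] = fold
    else:
        group_ids = np.asarray(group_ids).ravel()
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed)
        for fold, (_, test) in enumerate(
                splitter.split(labels[:, None], labels, groups=group_ids)):
            assignment[test] = fold
    return assignment


def confusion_and_metrics(truth: np.ndarray, scores: np.ndarray,
                          threshold: float = 0.5,
                          ) -> tuple[ConfusionCounts, dict[str, float | None]]:
    """Threshold positive-class scores and count the confusion cells."""
    truth = np.asarray(truth, int).ravel()
    scores = np.asarray(scores, float).ravel()
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.size != scores.size:
        raise ValueError(f"{truth.size} labels vs {scores.size} scores")
    pred = (scores >= threshold).astype(int)
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
    )
    return counts, counts.metrics()


def roc_auc(truth: np.ndarray, scores: np.ndarray,
            ) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all distinct score thresholds, and the
    trapezoidal AUC.  Equal scores are grouped into one step."""
    truth = np.asarray(truth, int).ravel()
    scores = np.asarray(scores, float).ravel()
    if np.unique(truth).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(truth, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


@dataclass
class FoldResult:
    fold: int
    counts: ConfusionCounts
    metrics: dict[str, float | None]
    auc: float
    roc_points: np.ndarray
    test_indices: np.ndarray


@dataclass
class CVReport:
    """Per-fold and pooled cross-validation results."""

    folds: list[FoldResult]
    fold_assignment: np.ndarray
    pooled_counts: ConfusionCounts
    pooled_auc: float
    pooled_roc: np.ndarray

    @property
    def pooled_metrics(self) -> dict[str, float | None]:
        return self.pooled_counts.metrics()

    def mean_metrics(self) -> dict[str, float]:
        """Fold-mean of each defined metric, plus mean AUC."""
        out = {}
        for key in ("accuracy", "sensitivity", "specificity"):
            vals = [f.metrics[key] for f in self.folds
                    if f.metrics[key] is not None]
            out[key] = float(np.mean(vals)) if vals else float("nan")
        out["auc"] = float(np.mean([f.auc for f in self.folds]))
        return out

    def sd_metrics(self) -> dict[str, float]:
        out = {}
        for key in ("accuracy", "sensitivity", "specificity"):
            vals = [f.metrics[key] for f in self.folds
                    if f.metrics[key] is not None]
            out[key] = float(np.std(vals)) if vals else float("nan")
        out["auc"] = float(np.std([f.auc for f in self.folds]))
        return out

    def summary(self) -> dict[str, float]:
        """Mean metrics in one flat dict (the Table-4-style quadruple)."""
        return self.mean_metrics()

    def to_frame(self):
        import pandas as pd

        rows = []
        for f in self.folds:
            rows.append({"fold": f.fold, **{k: v for k, v in f.metrics.items()},
                         "auc": f.auc, "tp": f.counts.tp, "fp": f.counts.fp,
                         "tn": f.counts.tn, "fn": f.counts.fn})
        pooled = self.pooled_metrics
        rows.append({"fold": "pooled", **pooled, "auc": self.pooled_auc,
                     "tp": self.pooled_counts.tp, "fp": self.pooled_counts.fp,
                     "tn": self.pooled_counts.tn, "fn": self.pooled_counts.fn})
        return pd.DataFrame(rows)

    def to_delimited(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _model_inputs(spec: ModelSpec, dataset: FeatureDataset, idx: np.ndarray):
    mode = spec.input_mode
    if mode == "pair":
        return (dataset.functional_array()[idx], dataset.temporal_array()[idx])
    if mode == "functional":
        return dataset.functional_array()[idx]
    if mode == "temporal":
        return dataset.temporal_array()[idx]
    if mode == "flat":
        xf = dataset.functional_array()
        xt = dataset.temporal_array()
        flat = np.concatenate([xf.reshape(len(xf), -1),
                               xt.reshape(len(xt), -1)], axis=1)
        return flat[idx]
    if mode.startswith("single:"):
        return dataset.single_feature_vectors(mode.split(":", 1)[1])[idx]
    raise ValueError(f"unknown input_mode {mode!r}")


def cross_validate(spec: ModelSpec, dataset: FeatureDataset, k: int = 5,
                   seed: int = 0, subject_level: bool = False) -> CVReport:
    """Stratified k-fold CV of one model spec on a feature dataset.

    Fits on k-1 folds, scores the held-out fold, and aggregates both
    per-fold and pooled.  All randomness (fold assignment, network
    initialization, shuffling) derives from ``seed`` and ``spec.seed``.
    """
    y = dataset.labels()
    groups = dataset.subject_ids() if subject_level else None
    assignment = stratified_kfold(y, k, seed=seed, group_ids=groups)

    folds: list[FoldResult] = []
    pooled_truth = np.empty(y.size, dtype=int)
    pooled_scores = np.empty(y.size, dtype=float)
    for fold in range(k):
        test_idx = np.nonzero(assignment == fold)[0]
        train_idx = np.nonzero(assignment != fold)[0]
        try:
            fold_spec = replace(spec, seed=spec.seed + fold)
            model = fit(fold_spec, _model_inputs(spec, dataset, train_idx),
                        y[train_idx])
            scores = model.predict_scores(
                _model_inputs(spec, dataset, test_idx))[:, 1]
        except Exception as exc:
            raise RuntimeError(f"fold {fold} failed: {exc}") from exc
        counts, metrics = confusion_and_metrics(y[test_idx], scores)
        roc_points, fold_auc = roc_auc(y[test_idx], scores)
        folds.append(FoldResult(fold, counts, metrics, fold_auc, roc_points,
                                test_idx))
        pooled_truth[test_idx] = y[test_idx]
        pooled_scores[test_idx] = scores

    pooled_counts = ConfusionCounts()
    for f in folds:
        pooled_counts = pooled_counts + f.counts
    pooled_roc, pooled_auc = roc_auc(pooled_truth, pooled_scores)
    return CVReport(folds=folds, fold_assignment=assignment,
                    pooled_counts=pooled_counts, pooled_auc=pooled_auc,
                    pooled_roc=pooled_roc)


def plot_roc(report: CVReport, path) -> None:
    """Pooled ROC curve to an image file (optional reporting aid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.pooled_roc[:, 0], report.pooled_roc[:, 1],
            label=f"AUC = {report.pooled_auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
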