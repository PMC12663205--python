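"""Dataset assembly and the greedy feature-combination search.

``build_dataset`` runs filter -> segment -> reject -> normalize on every
recording and computes the pair of per-window feature matrices, keeping
subject/window provenance.  ``greedy_feature_search`` implements the
wrapper selection procedure over the 4 functional x 5 temporal feature
pools: score each single functional feature against all temporal features,
greedily grow the functional subset from the best performer, then greedily
grow temporal subsets under the chosen functional set.  An exhaustive mode
enumerates all (2^4 - 1)(2^5 - 1) = 465 nonempty subset pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .functional import (FunctionalFeatureConfig, FunctionalFeatureMatrix,
                         functional_feature_matrix)
from .preprocessing import PreprocessingConfig, preprocess_recording
from .recording import SCHIZOPHRENIA, EEGRecording
from .temporal import (TemporalFeatureConfig, TemporalFeatureMatrix,
                       temporal_feature_matrix)

__all__ = ["FeatureItem", "FeatureDataset", "build_dataset",
           "greedy_feature_search", "SearchTrace", "save_dataset",
           "load_dataset"]


@dataclass
class FeatureItem:
    """One window's dual feature matrices with provenance."""

    temporal: TemporalFeatureMatrix
    functional: FunctionalFeatureMatrix
    label: str
    subject_id: str
    window_index: int


@dataclass
class FeatureDataset:
    """Labeled dual-matrix dataset: one item per kept window."""

    items: list[FeatureItem]
    temporal_cfg: TemporalFeatureConfig
    functional_cfg: FunctionalFeatureConfig

    def __post_init__(self) -> None:
        if self.items:
            t0 = self.items[0].temporal.values.shape
            f0 = self.items[0].functional.values.shape
            for it in self.items:
                if (it.temporal.values.shape != t0
                        or it.functional.values.shape != f0):
                    raise ValueError(
                        f"inconsistent matrix shapes for subject {it.subject_id}")

    def __len__(self) -> int:
        return len(self.items)

    def labels(self) -> np.ndarray:
        """Binary labels, 1 = schizophrenia (the positive class)."""
        return np.array([1 if it.label == SCHIZOPHRENIA else 0
                         for it in self.items], dtype=int)

    def subject_ids(self) -> np.ndarray:
        return np.array([it.subject_id for it in self.items])

    def temporal_array(self) -> np.ndarray:
        """(n_items, channels, F_t) stack."""
        return np.stack([it.temporal.values for it in self.items])

    def functional_array(self) -> np.ndarray:
        """(n_items, pairs, F_f) stack."""
        return np.stack([it.functional.values for it in self.items])

    def single_feature_vectors(self, feature: str) -> np.ndarray:
        """Flat per-window vector of one named feature (31- or 465-dim)."""
        if feature in self.temporal_cfg.features:
            j = self.temporal_cfg.features.index(feature)
            return np.stack([it.temporal.values[:, j] for it in self.items])
        if feature in self.functional_cfg.features:
            j = self.functional_cfg.features.index(feature)
            return np.stack([it.functional.values[:, j] for it in self.items])
        raise KeyError(f"feature {feature!r} not in this dataset")

    def subset(self, functional: tuple[str, ...] | None = None,
               temporal: tuple[str, ...] | None = None) -> "FeatureDataset":
        """Restrict both matrices to the named feature columns."""
        functional = tuple(functional or self.functional_cfg.features)
        temporal = tuple(temporal or self.temporal_cfg.features)
        fj = [self.functional_cfg.features.index(f) for f in functional]
        tj = [self.temporal_cfg.features.index(f) for f in temporal]
        items = [
            FeatureItem(
                temporal=TemporalFeatureMatrix(
                    it.temporal.values[:, tj], it.temporal.channel_labels,
                    temporal),
                functional=FunctionalFeatureMatrix(
                    it.functional.values[:, fj], it.functional.pair_labels,
                    functional),
                label=it.label, subject_id=it.subject_id,
                window_index=it.window_index)
            for it in self.items
        ]
        return FeatureDataset(
            items,
            replace(self.temporal_cfg, features=temporal),
            replace(self.functional_cfg, features=functional))


def build_dataset(recordings: list[EEGRecording],
                  pre_cfg: PreprocessingConfig | None = None,
                  temporal_cfg: TemporalFeatureConfig | None = None,
                  functional_cfg: FunctionalFeatureConfig | None = None,
                  ) -> FeatureDataset:
    """Preprocess every recording and extract both feature matrices per window."""
    if not recordings:
        raise ValueError("no recordings given")
    pre_cfg = pre_cfg or PreprocessingConfig()
    temporal_cfg = temporal_cfg or TemporalFeatureConfig()
    functional_cfg = functional_cfg or FunctionalFeatureConfig()

    fs0 = recordings[0].fs
    ch0 = recordings[0].channel_labels
    bad = [r.subject_id for r in recordings
           if r.fs != fs0 or r.channel_labels != ch0]
    if bad:
        raise ValueError(
            f"inconsistent sampling rate or channel set for subjects: {bad}")

    items: list[FeatureItem] = []
    for rec in recordings:
        windows, _rejected = preprocess_recording(rec, pre_cfg)
        for w in windows:
            items.append(FeatureItem(
                temporal=temporal_feature_matrix(w, temporal_cfg),
                functional=functional_feature_matrix(w, functional_cfg),
                label=w.label, subject_id=w.subject_id,
                window_index=w.window_index))
    return FeatureDataset(items, temporal_cfg, functional_cfg)


def save_dataset(dataset: FeatureDataset, outdir) -> None:
    """Write a dataset as one TSV pair per window plus a YAML manifest."""
    import yaml
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, it in enumerate(dataset.items):
        stem = f"{it.subject_id}_w{it.window_index:03d}"
        it.temporal.to_delimited(outdir / f"{stem}.temporal.tsv")
        it.functional.to_delimited(outdir / f"{stem}.functional.tsv")
        entries.append({"stem": stem, "label": it.label,
                        "subject_id": it.subject_id,
                        "window_index": int(it.window_index)})
    meta = {
        "temporal_cfg": {
            "features": list(dataset.temporal_cfg.features),
            "ar_order": dataset.temporal_cfg.ar_order,
            "entropy_bins": dataset.temporal_cfg.entropy_bins,
        },
        "functional_cfg": {
            "features": list(dataset.functional_cfg.features),
            "band": list(dataset.functional_cfg.band),
            "welch_seconds": dataset.functional_cfg.welch_seconds,
            "welch_overlap": dataset.functional_cfg.welch_overlap,
            "pli_variant": dataset.functional_cfg.pli_variant,
        },
        "items": entries,
    }
    with open(outdir / "dataset.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_dataset(path) -> FeatureDataset:
    """Load a dataset written by :func:`save_dataset`."""
    import yaml
    from pathlib import Path

    path = Path(path)
    manifest = path / "dataset.yaml" if path.is_dir() else path
    with open(manifest) as fh:
        meta = yaml.safe_load(fh)
    root = manifest.parent
    t_cfg = TemporalFeatureConfig(
        features=tuple(meta["temporal_cfg"]["features"]),
        ar_order=meta["temporal_cfg"]["ar_order"],
        entropy_bins=meta["temporal_cfg"]["entropy_bins"])
    f_cfg = FunctionalFeatureConfig(
        features=tuple(meta["functional_cfg"]["features"]),
        band=tuple(meta["functional_cfg"]["band"]),
        welch_seconds=meta["functional_cfg"]["welch_seconds"],
        welch_overlap=meta["functional_cfg"]["welch_overlap"],
        pli_variant=meta["functional_cfg"]["pli_variant"])
    items = []
    for entry in meta["items"]:
        t_frame = pd.read_csv(root / f"{entry['stem']}.temporal.tsv",
                              sep="\t", index_col=0)
        f_frame = pd.read_csv(root / f"{entry['stem']}.functional.tsv",
                              sep="\t", index_col=0)
        pair_labels = [tuple(s.split("-", 1)) for s in f_frame.index]
        items.append(FeatureItem(
            temporal=TemporalFeatureMatrix(
                t_frame.to_numpy(), tuple(t_frame.index),
                tuple(t_frame.columns)),
            functional=FunctionalFeatureMatrix(
                f_frame.to_numpy(), pair_labels, tuple(f_frame.columns)),
            label=entry["label"], subject_id=entry["subject_id"],
            window_index=entry["window_index"]))
    return FeatureDataset(items, t_cfg, f_cfg)


@dataclass
class SearchTrace:
    """Every evaluated combination, in evaluation order, plus the winner.

    ``chosen_functional`` is the functional subset the greedy growth stage
    settled on (the set the temporal stage then works under).
    """

    entries: list[dict] = field(default_factory=list)
    chosen_functional: tuple[str, ...] | None = None

    def record(self, functional: tuple[str, ...], temporal: tuple[str, ...],
               metrics: dict | None, error: str | None = None) -> None:
        self.entries.append({
            "order": len(self.entries),
            "functional": tuple(functional),
            "temporal": tuple(temporal),
            "metrics": metrics,
            "error": error,
        })

    def seen(self, functional: tuple[str, ...], temporal: tuple[str, ...]) -> bool:
        key = (tuple(functional), tuple(temporal))
        return any((e["functional"], e["temporal"]) == key for e in self.entries)

    def lookup(self, functional, temporal) -> dict | None:
        key = (tuple(functional), tuple(temporal))
        for e in self.entries:
            if (e["functional"], e["temporal"]) == key:
                return e["metrics"]
        return None

    @property
    def best(self) -> dict:
        """Highest accuracy; ties broken by AUC, then smaller subset."""
        scored = [e for e in self.entries if e["metrics"] is not None]
        if not scored:
            raise ValueError("no combination evaluated successfully")
        return max(scored, key=lambda e: (
            e["metrics"]["accuracy"],
            e["metrics"].get("auc", 0.0),
            -(len(e["functional"]) + len(e["temporal"])),
        ))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            m = e["metrics"] or {}
            rows.append({
                "functional": " ".join(e["functional"]),
                "temporal": " ".join(e["temporal"]),
                "accuracy": m.get("accuracy"),
                "sensitivity": m.get("sensitivity"),
                "specificity": m.get("specificity"),
                "auc": m.get("auc"),
                "error": e["error"] or "",
            })
        return pd.DataFrame(rows)

    def to_delimited(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _nonempty_subsets(pool: tuple[str, ...]) -> list[tuple[str, ...]]:
    out = []
    n = len(pool)
    for mask in range(1, 2**n):
        out.append(tuple(pool[i] for i in range(n) if mask >> i & 1))
    return out


def greedy_feature_search(
    evaluator: Callable[[tuple[str, ...], tuple[str, ...]], dict],
    functional_pool: tuple[str, ...] = ("pearson", "coherence", "plv", "pli"),
    temporal_pool: tuple[str, ...] = ("variance", "absolute_energy",
                                      "auto_regression", "shannon_entropy",
                                      "hjorth_mobility"),
    exhaustive: bool = False,
) -> SearchTrace:
    """Wrapper feature selection over the two pools.

    ``evaluator(functional_subset, temporal_subset)`` must return a metric
    dict with at least ``accuracy`` (the primary metric) and ideally
    ``auc`` (tie break).  Evaluator failures are recorded in the trace and
    the search continues.  In ``exhaustive`` mode every nonempty subset
    pair is scored instead.
    """
    if not functional_pool or not temporal_pool:
        raise ValueError("feature pools must be non-empty")
    trace = SearchTrace()

    def evaluate(f_sub, t_sub) -> dict | None:
        # canonicalize by pool order so a subset is evaluated at most once
        # regardless of the order the greedy growth discovered it in
        f_sub = tuple(f for f in functional_pool if f in f_sub)
        t_sub = tuple(t for t in temporal_pool if t in t_sub)
        cached = trace.lookup(f_sub, t_sub)
        if cached is not None or trace.seen(f_sub, t_sub):
            return cached
        try:
            metrics = evaluator(f_sub, t_sub)
        except Exception as exc:  # noqa: BLE001 — evaluator is user code
            trace.record(f_sub, t_sub, None, error=str(exc))
            return None
        trace.record(f_sub, t_sub, metrics)
        return metrics

    def primary(m: dict | None) -> tuple:
        if m is None:
            return (-np.inf, -np.inf)
        return (m["accuracy"], m.get("auc", 0.0))

    if exhaustive:
        for f_sub in _nonempty_subsets(functional_pool):
            for t_sub in _nonempty_subsets(temporal_pool):
                evaluate(f_sub, t_sub)
        trace.chosen_functional = trace.best["functional"]
        return trace

    all_t = tuple(temporal_pool)

    # Stage 1: each single functional feature with all temporal features.
    singles = {(f,): evaluate((f,), all_t) for f in functional_pool}
    best_f = max(singles, key=lambda k: primary(singles[k]))
    best_f_metrics = singles[best_f]

    # Stage 2: greedy growth of the functional subset.
    current, current_m = best_f, best_f_metrics
    remaining = [f for f in functional_pool if f not in current]
    while remaining:
        candidates = {f: evaluate(current + (f,), all_t) for f in remaining}
        cand = max(candidates, key=lambda f: primary(candidates[f]))
        if primary(candidates[cand]) >= primary(current_m):
            current = current + (cand,)
            current_m = candidates[cand]
            remaining.remove(cand)
        else:
            break
    chosen_f = tuple(f for f in functional_pool if f in current)
    trace.chosen_functional = chosen_f

    # Stage 3: greedy temporal growth from each single temporal start.
    for t0 in temporal_pool:
        t_cur = (t0,)
        t_m = evaluate(chosen_f, t_cur)
        t_rem = [t for t in temporal_pool if t != t0]
        while t_rem:
            cands = {t: evaluate(chosen_f, t_cur + (t,)) for t in t_rem}
            cand = max(cands, key=lambda t: primary(cands[t]))
            if primary(cands[cand]) >= primary(t_m):
                t_cur = t_cur + (cand,)
                t_m = cands[cand]
                t_rem.remove(cand)
            else:
                break
    return trace
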