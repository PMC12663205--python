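"""Per-channel temporal features and the channels x features matrix.

Five scalar features per channel: variance (1/N), absolute energy,
a first autoregressive coefficient (Yule-Walker fit), Shannon entropy of
the binned amplitude distribution, and Hjorth mobility.  Stacking the
configured subset over all channels gives the temporal feature matrix —
31 x 4 for the default montage and feature set (variance, absolute
energy, auto-regression, Hjorth mobility).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.regression.linear_model import yule_walker

from .recording import EEGWindow

__all__ = [
    "TemporalFeatureConfig", "TemporalFeatureMatrix", "ARFit",
    "variance", "absolute_energy", "ar_feature", "ar_fit",
    "shannon_entropy", "hjorth_mobility", "temporal_feature_matrix",
    "TEMPORAL_FEATURES",
]

#: Canonical feature names, in the order used by the default 31x4 matrix
#: plus Shannon entropy.
TEMPORAL_FEATURES = (
    "variance", "absolute_energy", "auto_regression", "hjorth_mobility",
    "shannon_entropy",
)


@dataclass(frozen=True)
class TemporalFeatureConfig:
    """Which temporal features to compute, and their knobs.

    ar_order : AR lag window p (default 2); the scalar feature is phi_1.
    entropy_bins : number K of equal-width amplitude bins (default 64).
    """

    features: tuple[str, ...] = (
        "variance", "absolute_energy", "auto_regression", "hjorth_mobility")
    ar_order: int = 2
    entropy_bins: int = 64

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("features must be non-empty")
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"duplicate features in {self.features}")
        unknown = set(self.features) - set(TEMPORAL_FEATURES)
        if unknown:
            raise ValueError(f"unknown temporal features {sorted(unknown)}")
        if self.ar_order < 1:
            raise ValueError(f"ar_order must be >= 1, got {self.ar_order}")
        if self.entropy_bins < 2:
            raise ValueError(f"entropy_bins must be >= 2, got {self.entropy_bins}")


@dataclass
class ARFit:
    """Autoregressive model fit x(t) = c + sum_i phi_i x(t-i) + eps_t."""

    c: float
    phi: np.ndarray
    residual_variance: float


@dataclass
class TemporalFeatureMatrix:
    """channels x features grid with row/column labels."""

    values: np.ndarray
    channel_labels: tuple[str, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.channel_labels), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.channel_labels)} channels x "
                f"{len(self.feature_names)} features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("temporal feature matrix contains non-finite entries")

    def to_delimited(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=list(self.channel_labels),
                     columns=list(self.feature_names)).to_csv(path, sep="\t")


def _check_series(x: np.ndarray, min_len: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise ValueError(f"series of length {x.size} (need >= {min_len})")
    return x


def variance(x: np.ndarray) -> float:
    """Population variance: (1/N) * sum (x_t - mean)^2."""
    x = _check_series(x)
    return float(np.var(x))


def absolute_energy(x: np.ndarray) -> float:
    """Sum of squared amplitudes, sum |x_t|^2."""
    x = _check_series(x)
    return float(np.sum(np.abs(x) ** 2))


def ar_fit(x: np.ndarray, p: int = 2) -> ARFit:
    """Fit AR(p) by Yule-Walker on the centered series."""
    x = _check_series(x, min_len=p + 2)
    if np.ptp(x) == 0:
        raise ValueError("constant series: autocovariance matrix is singular")
    mean = x.mean()
    phi, sigma = yule_walker(x - mean, order=p, method="mle", demean=False)
    return ARFit(c=float(mean * (1.0 - phi.sum())), phi=np.asarray(phi),
                 residual_variance=float(sigma**2))


def ar_feature(x: np.ndarray, p: int = 2) -> float:
    """Scalar AR summary: the first Yule-Walker coefficient phi_1."""
    return float(ar_fit(x, p).phi[0])


def shannon_entropy(x: np.ndarray, k: int = 64) -> float:
    """Shannon entropy (bits) of the K-bin amplitude histogram.

    Amplitudes are binned into ``k`` equal-width bins spanning [min, max];
    p_i are the bin relative frequencies and empty bins contribute zero.
    The result lies in [0, log2 k]; a constant series occupies a single
    bin and has entropy 0.
    """
    x = _check_series(x)
    if k < 2:
        raise ValueError(f"need k >= 2 bins, got {k}")
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=k)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def hjorth_mobility(x: np.ndarray) -> float:
    """Hjorth mobility sqrt(Var(diff x) / Var(x)).

    The first difference is the length-(N-1) forward difference.  For a
    sampled sinusoid at frequency f the closed form is 2|sin(pi f / fs)|;
    for iid noise it converges to sqrt(2).  A zero-variance series maps to
    0 with a warning (same degenerate-case policy as z-scoring).
    """
    x = _check_series(x, min_len=2)
    v = np.var(x)
    if v == 0:
        warnings.warn("zero-variance series in hjorth_mobility; returning 0")
        return 0.0
    return float(np.sqrt(np.var(np.diff(x)) / v))


def _compute_one(name: str, x: np.ndarray, cfg: TemporalFeatureConfig) -> float:
    if name == "variance":
        return variance(x)
    if name == "absolute_energy":
        return absolute_energy(x)
    if name == "auto_regression":
        return ar_feature(x, cfg.ar_order)
    if name == "shannon_entropy":
        return shannon_entropy(x, cfg.entropy_bins)
    if name == "hjorth_mobility":
        return hjorth_mobility(x)
    raise ValueError(f"unknown temporal feature {name!r}")


def temporal_feature_matrix(window: EEGWindow,
                            cfg: TemporalFeatureConfig | None = None,
                            ) -> TemporalFeatureMatrix:
    """One row per channel, one column per configured feature.

    Note: on z-scored windows variance is ~1 and absolute energy ~T_w for
    every channel by construction; they are still computed (and reported)
    as configured.  Pass a pre-normalization window to retain amplitude
    information in these columns.
    """
    cfg = cfg or TemporalFeatureConfig()
    values = np.empty((window.n_channels, len(cfg.features)))
    for i in range(window.n_channels):
        for j, name in enumerate(cfg.features):
            try:
                values[i, j] = _compute_one(name, window.data[i], cfg)
            except ValueError as exc:
                raise ValueError(
                    f"feature {name!r} failed on channel "
                    f"{window.channel_labels[i]}: {exc}") from exc
    return TemporalFeatureMatrix(values=values,
                                 channel_labels=window.channel_labels,
                                 feature_names=tuple(cfg.features))
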