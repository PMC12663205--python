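"""Pairwise functional-connectivity features and the pairs x features matrix.

Four features per unordered channel pair: Pearson correlation, band-mean
magnitude-squared coherence (Welch), phase locking value (PLV) and phase
lag index (PLI).  Phase is taken from the analytic signal (Hilbert
transform) of each full window.  Over the 31-channel montage the default
feature set {pli, plv, pearson} yields the 465 x 3 functional matrix.

PLI variants
------------
``printed``   |mean sign(sin d)| / mean |sin d|   (the ratio form; exceeds 1
              for constant small nonzero lags — kept as the default for
              fidelity to the formula it implements)
``standard``  |mean sign(sin d)|                  (the literature PLI, in [0,1])
``wpli``      |mean sin d| / mean |sin d|         (weighted PLI, in [0,1])

where d is the inter-channel instantaneous phase difference.  When the
shared denominator is below 1e-12 (zero-lag locking), ``printed`` and
``wpli`` return 0 by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import EEGWindow, channel_pairs

__all__ = [
    "FunctionalFeatureConfig", "FunctionalFeatureMatrix", "PhaseSeries",
    "instantaneous_phase", "pearson_pair", "coherence_pair", "plv_pair",
    "pli_pair", "functional_feature_matrix", "FUNCTIONAL_FEATURES",
]

FUNCTIONAL_FEATURES = ("pearson", "coherence", "plv", "pli")

_DENOM_EPS = 1e-12


@dataclass
class PhaseSeries:
    """Instantaneous phase angles (radians, wrapped to (-pi, pi])."""

    phi: np.ndarray
    channel_labels: tuple[str, ...]


@dataclass(frozen=True)
class FunctionalFeatureConfig:
    """Which pairwise features to compute and how to scalarize coherence.

    band : (low, high) Hz range the coherence spectrum is averaged over.
    welch_seconds / welch_overlap : Welch segment length (s) and fractional
        overlap (2-s Hann segments, 50% overlap by default).
    pli_variant : 'printed', 'standard' or 'wpli'.
    """

    features: tuple[str, ...] = ("pli", "plv", "pearson")
    band: tuple[float, float] = (1.0, 30.0)
    welch_seconds: float = 2.0
    welch_overlap: float = 0.5
    pli_variant: str = "printed"

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("features must be non-empty")
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"duplicate features in {self.features}")
        unknown = set(self.features) - set(FUNCTIONAL_FEATURES)
        if unknown:
            raise ValueError(f"unknown functional features {sorted(unknown)}")
        if self.pli_variant not in ("printed", "standard", "wpli"):
            raise ValueError(f"unknown pli variant {self.pli_variant!r}")
        if not self.band[0] < self.band[1]:
            raise ValueError(f"band must be (low, high), got {self.band}")


@dataclass
class FunctionalFeatureMatrix:
    """pairs x features grid; pairs in canonical lexicographic order."""

    values: np.ndarray
    pair_labels: list[tuple[str, str]]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pair_labels), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.pair_labels)} pairs x {len(self.feature_names)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("functional feature matrix contains non-finite entries")

    def to_delimited(self, path) -> None:
        import pandas as pd

        idx = [f"{a}-{b}" for a, b in self.pair_labels]
        pd.DataFrame(self.values, index=idx,
                     columns=list(self.feature_names)).to_csv(path, sep="\t")


def instantaneous_phase(window: EEGWindow) -> PhaseSeries:
    """Phase of the analytic signal, per channel, on the full window."""
    analytic = sps.hilbert(window.data, axis=1)
    return PhaseSeries(phi=np.angle(analytic),
                       channel_labels=window.channel_labels)


def pearson_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient r in [-1, 1].

    Constant inputs (undefined r) map to 0 with a warning.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom < _DENOM_EPS:
        warnings.warn("constant input in pearson_pair; returning 0")
        return 0.0
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def _welch_params(n: int, fs: float, cfg: FunctionalFeatureConfig) -> tuple[int, int]:
    nperseg = min(int(round(cfg.welch_seconds * fs)), n)
    noverlap = int(round(cfg.welch_overlap * nperseg))
    step = nperseg - noverlap
    n_segments = 1 + (n - nperseg) // step if n >= nperseg else 0
    if n_segments < 2:
        raise ValueError(
            f"coherence needs >= 2 Welch segments, got {n_segments} "
            f"(n={n}, nperseg={nperseg})")
    return nperseg, noverlap


def coherence_pair(x: np.ndarray, y: np.ndarray, fs: float,
                   band: tuple[float, float] = (1.0, 30.0),
                   welch_seconds: float = 2.0,
                   welch_overlap: float = 0.5) -> float:
    """Band-mean magnitude-squared coherence |S_xy|^2 / (S_xx S_yy).

    Spectra are Welch-averaged (Hann segments); the per-frequency coherence
    is then averaged over ``band`` to a scalar in [0, 1].
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    cfg = FunctionalFeatureConfig(band=band, welch_seconds=welch_seconds,
                                  welch_overlap=welch_overlap)
    nperseg, noverlap = _welch_params(x.size, fs, cfg)
    freqs, cxy = sps.coherence(x, y, fs=fs, window="hann", nperseg=nperseg,
                               noverlap=noverlap)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} contains no Welch frequency bins")
    return float(cxy[sel].mean())


def plv_pair(phi_i: np.ndarray, phi_j: np.ndarray) -> float:
    """Phase locking value: modulus of the mean unit phasor of phi_i - phi_j."""
    phi_i = np.asarray(phi_i, float).ravel()
    phi_j = np.asarray(phi_j, float).ravel()
    if phi_i.size != phi_j.size:
        raise ValueError(f"length mismatch: {phi_i.size} vs {phi_j.size}")
    return float(np.abs(np.mean(np.exp(1j * (phi_i - phi_j)))))


def pli_pair(phi_i: np.ndarray, phi_j: np.ndarray,
             variant: str = "printed") -> float:
    """Phase lag index of the phase difference d = phi_i - phi_j.

    See the module docstring for the three variants.  All are symmetric in
    (i, j) because the sign flip of d sits inside an absolute value.
    """
    phi_i = np.asarray(phi_i, float).ravel()
    phi_j = np.asarray(phi_j, float).ravel()
    if phi_i.size != phi_j.size:
        raise ValueError(f"length mismatch: {phi_i.size} vs {phi_j.size}")
    sin_d = np.sin(phi_i - phi_j)
    num_standard = np.abs(np.mean(np.sign(sin_d)))
    if variant == "standard":
        return float(num_standard)
    denom = np.mean(np.abs(sin_d))
    if denom < _DENOM_EPS:
        return 0.0
    if variant == "printed":
        return float(num_standard / denom)
    if variant == "wpli":
        return float(np.abs(np.mean(sin_d)) / denom)
    raise ValueError(f"unknown pli variant {variant!r}")


def _coherence_matrix(data: np.ndarray, fs: float,
                      cfg: FunctionalFeatureConfig) -> np.ndarray:
    """Band-mean coherence for every channel pair via broadcast Welch/CSD."""
    n_ch, n = data.shape
    nperseg, noverlap = _welch_params(n, fs, cfg)
    freqs, pxx = sps.welch(data, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=noverlap)
    _, pxy = sps.csd(data[:, None, :], data[None, :, :], fs=fs, window="hann",
                     nperseg=nperseg, noverlap=noverlap)
    cxy = np.abs(pxy) ** 2 / (pxx[:, None, :] * pxx[None, :, :])
    sel = (freqs >= cfg.band[0]) & (freqs <= cfg.band[1])
    if not sel.any():
        raise ValueError(f"band {cfg.band} contains no Welch frequency bins")
    return cxy[..., sel].mean(axis=-1)


def functional_feature_matrix(window: EEGWindow,
                              cfg: FunctionalFeatureConfig | None = None,
                              ) -> FunctionalFeatureMatrix:
    """One row per unordered channel pair (canonical order), one column per
    configured feature.

    Vectorized over pairs; each entry equals the corresponding per-pair
    function applied to the two channels.
    """
    cfg = cfg or FunctionalFeatureConfig()
    data = window.data
    n_ch = window.n_channels
    iu = np.triu_indices(n_ch, k=1)
    pairs = channel_pairs(window.channel_labels)

    columns: dict[str, np.ndarray] = {}
    if "pearson" in cfg.features:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = np.corrcoef(data)
        flat = data.std(axis=1) < _DENOM_EPS
        if flat.any():
            warnings.warn("constant channel(s); Pearson set to 0 for their pairs")
            r[flat, :] = 0.0
            r[:, flat] = 0.0
        columns["pearson"] = np.clip(r[iu], -1.0, 1.0)
    if "coherence" in cfg.features:
        columns["coherence"] = _coherence_matrix(data, window.fs, cfg)[iu]
    if {"plv", "pli"} & set(cfg.features):
        phi = instantaneous_phase(window).phi
        if "plv" in cfg.features:
            e = np.exp(1j * phi)
            g = (e @ e.conj().T) / phi.shape[1]
            columns["plv"] = np.abs(g)[iu]
        if "pli" in cfg.features:
            sin_d = np.sin(phi[iu[0]] - phi[iu[1]])  # (n_pairs, T)
            num_std = np.abs(np.mean(np.sign(sin_d), axis=1))
            if cfg.pli_variant == "standard":
                columns["pli"] = num_std
            else:
                denom = np.mean(np.abs(sin_d), axis=1)
                num = (np.abs(np.mean(sin_d, axis=1))
                       if cfg.pli_variant == "wpli" else num_std)
                with np.errstate(divide="ignore", invalid="ignore"):
                    vals = np.where(denom < _DENOM_EPS, 0.0, num / denom)
                columns["pli"] = vals

    values = np.column_stack([columns[name] for name in cfg.features])
    return FunctionalFeatureMatrix(values=values, pair_labels=pairs,
                                   feature_names=tuple(cfg.features))
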