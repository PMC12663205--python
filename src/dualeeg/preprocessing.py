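"""Filtering, windowing, artifact rejection and per-window normalization.

The pipeline order is: zero-phase band-pass (optionally with a power-line
notch) on the continuous recording, segmentation into non-overlapping
25-s windows, amplitude-threshold rejection of contaminated windows, then
per-channel within-window z-scoring.  Normalization uses the population
(1/N) standard deviation, consistent with the 1/T_w variance definition
used by the temporal features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .recording import EEGRecording, EEGWindow

__all__ = [
    "PreprocessingConfig", "bandpass_notch_filter", "segment_windows",
    "reject_windows", "zscore_normalize", "preprocess_recording",
]

#: Default analysis band (Hz).  The emulated acquisition chain band-passes
#: at 0.16-30 Hz and notches line noise around 50 Hz; 0.5-45 Hz is a safe
#: cleaning band for a 500 Hz signal and every edge is configurable.
DEFAULT_LOW_HZ = 0.5
DEFAULT_HIGH_HZ = 45.0


@dataclass(frozen=True)
class PreprocessingConfig:
    """Settings for the filter -> segment -> reject -> normalize chain."""

    low_hz: float = DEFAULT_LOW_HZ
    high_hz: float = DEFAULT_HIGH_HZ
    notch_hz: float | None = None
    window_seconds: float = 25.0
    amplitude_threshold_sd: float = 8.0
    reject: bool = True


def bandpass_notch_filter(rec: EEGRecording, low_hz: float = DEFAULT_LOW_HZ,
                          high_hz: float = DEFAULT_HIGH_HZ,
                          notch_hz: float | None = None,
                          notch_q: float = 30.0) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass, plus optional notch.

    Both stages run forward-backward (``sosfiltfilt`` / ``filtfilt``) so the
    pass band keeps zero phase; output length equals input length.
    """
    if not (0 < low_hz < high_hz < rec.fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2 = {rec.fs / 2}; "
            f"got low={low_hz}, high={high_hz}")
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=rec.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
    if notch_hz is not None:
        if not (0 < notch_hz < rec.fs / 2):
            raise ValueError(f"notch_hz must be in (0, fs/2), got {notch_hz}")
        b, a = sps.iirnotch(notch_hz, notch_q, fs=rec.fs)
        filtered = sps.filtfilt(b, a, filtered, axis=1)
    return replace(rec, signal=filtered)


def segment_windows(rec: EEGRecording,
                    window_seconds: float = 25.0) -> list[EEGWindow]:
    """Cut the recording into non-overlapping windows of ``window_seconds``.

    Window k covers the half-open sample range [k*T_w, (k+1)*T_w); the
    trailing remainder is discarded, so a recording of duration D yields
    floor(D / window_seconds) windows (24 for 600 s / 25 s).
    """
    t_w = int(round(rec.fs * window_seconds))
    if t_w < 1:
        raise ValueError(f"window_seconds too small: {window_seconds}")
    n_windows = rec.n_samples // t_w
    if n_windows == 0:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{t_w}-sample window")
    return [
        EEGWindow(
            data=rec.signal[:, k * t_w:(k + 1) * t_w].copy(),
            fs=rec.fs,
            channel_labels=rec.channel_labels,
            subject_id=rec.subject_id,
            window_index=k,
            label=rec.group_label,
        )
        for k in range(n_windows)
    ]


def reject_windows(windows: list[EEGWindow], amplitude_threshold_sd: float = 8.0,
                   ) -> tuple[list[EEGWindow], list[tuple[EEGWindow, str]]]:
    """Partition windows into (kept, rejected-with-reason).

    A window is rejected iff any channel's pre-normalization absolute
    amplitude exceeds ``amplitude_threshold_sd`` times that channel's
    recording-level standard deviation (estimated per subject over all of
    the subject's windows).  An automatic stand-in for manual/ICA artifact
    screening: extreme excursions are what it catches.
    """
    if not amplitude_threshold_sd > 0:
        raise ValueError("amplitude_threshold_sd must be positive")
    # recording-level per-channel SD, per subject
    sd_by_subject: dict[str, np.ndarray] = {}
    for subject in {w.subject_id for w in windows}:
        data = np.concatenate(
            [w.data for w in windows if w.subject_id == subject], axis=1)
        sd = data.std(axis=1)
        sd[sd == 0] = np.inf  # flat channel can never trip the threshold
        sd_by_subject[subject] = sd

    kept: list[EEGWindow] = []
    rejected: list[tuple[EEGWindow, str]] = []
    for w in windows:
        limit = amplitude_threshold_sd * sd_by_subject[w.subject_id]
        peaks = np.abs(w.data).max(axis=1)
        over = np.nonzero(peaks > limit)[0]
        if over.size:
            ch = w.channel_labels[over[0]]
            rejected.append((
                w,
                f"channel {ch} peak {peaks[over[0]]:.3g} exceeds "
                f"{amplitude_threshold_sd} SD ({limit[over[0]]:.3g})"))
        else:
            kept.append(w)
    return kept, rejected


def zscore_normalize(window: EEGWindow) -> EEGWindow:
    """Per-channel within-window z-scoring with the population (1/N) SD.

    Zero-variance channels are mapped to all-zeros with a warning rather
    than raising, so window shapes stay fixed for the network inputs.
    Idempotent: normalizing an already-normalized window is a no-op up to
    floating point.
    """
    mu = window.data.mean(axis=1, keepdims=True)
    sd = window.data.std(axis=1, keepdims=True)  # population (ddof=0)
    flat = (sd == 0).ravel()
    if flat.any():
        names = [window.channel_labels[i] for i in np.nonzero(flat)[0]]
        warnings.warn(
            f"zero-variance channel(s) {names} in window "
            f"{window.subject_id}/{window.window_index}; set to zeros")
    sd = np.where(sd == 0, 1.0, sd)
    data = (window.data - mu) / sd
    data[flat, :] = 0.0
    return replace(window, data=data, normalized=True)


def preprocess_recording(rec: EEGRecording, cfg: PreprocessingConfig,
                         ) -> tuple[list[EEGWindow], list[tuple[EEGWindow, str]]]:
    """Full chain: filter -> segment -> reject -> normalize.

    Returns (normalized kept windows, rejected windows with reasons).
    """
    filtered = bandpass_notch_filter(rec, cfg.low_hz, cfg.high_hz, cfg.notch_hz)
    windows = segment_windows(filtered, cfg.window_seconds)
    if cfg.reject:
        kept, rejected = reject_windows(windows, cfg.amplitude_threshold_sd)
    else:
        kept, rejected = windows, []
    return [zscore_normalize(w) for w in kept], rejected
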