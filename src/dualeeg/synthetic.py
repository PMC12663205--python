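"""Two-group synthetic EEG cohorts with controllable coupling and amplitude.

The generator produces multichannel recordings built from a small set of
shared narrow-band oscillatory sources mixed into every channel with a
group-dependent coupling weight and a channel-dependent lag, on top of
independent 1/f ("pink") background noise plus white noise.  Stronger
coupling raises inter-channel phase synchrony (PLV/PLI/coherence/Pearson);
the amplitude multiplier moves variance/energy without touching phase
relations.  The construction is purely an artifact of this package — it
emulates the *kind* of group differences a clinical schizophrenia-vs-control
EEG study measures, not any particular study's signals.

Determinism contract: identical ``(params, cfg, subject_seed)`` give
bit-identical signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import CONTROL, MONTAGE_31, SCHIZOPHRENIA, EEGRecording


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters of one group.

    coupling_strength : mixing weight of the shared sources into each
        channel, in [0, 1].  0 means channels carry independent noise only.
    lag_seconds : base inter-channel lag of the shared sources (s); channel
        ``c`` receives the source delayed by ``c * lag_seconds``, which makes
        phase differences consistent and nonzero (PLI is blind to zero lag).
    amplitude_scale : overall multiplier on the channel signal (> 0).
    osc_freqs : center frequencies (Hz) of the shared narrow-band sources.
    pink_exponent : spectral slope beta of the 1/f^beta background.
    snr : ratio of full-strength oscillatory power to total noise power.
    """

    coupling_strength: float = 0.5
    lag_seconds: float = 0.005
    amplitude_scale: float = 1.0
    osc_freqs: tuple[float, ...] = (6.0, 10.0, 20.0)
    pink_exponent: float = 1.0
    snr: float = 1.0

    def validate(self, fs: float) -> None:
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError(
                f"coupling_strength must be in [0, 1], got {self.coupling_strength}"
            )
        if not self.amplitude_scale > 0:
            raise ValueError(
                f"amplitude_scale must be positive, got {self.amplitude_scale}"
            )
        for f in self.osc_freqs:
            if not 0 < f < fs / 2:
                raise ValueError(
                    f"osc_freqs must lie in (0, fs/2) = (0, {fs / 2}); got {f}"
                )
        if not self.snr > 0:
            raise ValueError(f"snr must be positive, got {self.snr}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level layout: sizes, montage, sampling, master seed.

    ``n_subjects_per_group`` is either one count used for both groups or an
    ``(n_sz, n_hc)`` pair (the emulated clinical cohort is 26/25).
    """

    n_subjects_per_group: int | tuple[int, int] = (26, 25)
    n_channels: int = 31
    fs: float = 500.0
    duration_seconds: float = 600.0
    seed: int = 0

    def counts(self) -> tuple[int, int]:
        n = self.n_subjects_per_group
        if isinstance(n, tuple):
            n_sz, n_hc = n
        else:
            n_sz = n_hc = int(n)
        return int(n_sz), int(n_hc)

    def validate(self, min_duration: float = 0.0) -> None:
        n_sz, n_hc = self.counts()
        if n_sz < 1 or n_hc < 1:
            raise ValueError(
                f"n_subjects_per_group counts must be >= 1, got {self.n_subjects_per_group}"
            )
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration_seconds < max(min_duration, 1.0 / self.fs):
            raise ValueError(
                f"duration_seconds too short: {self.duration_seconds}"
            )

    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels <= len(MONTAGE_31):
            return MONTAGE_31[: self.n_channels]
        extra = tuple(f"CH{i}" for i in range(len(MONTAGE_31), self.n_channels))
        return MONTAGE_31 + extra


def strong_effect() -> tuple[GroupParams, GroupParams]:
    """Default separable study condition: coupling 0.7 (SZ) vs 0.3 (HC),
    amplitude 1.2 vs 1.0."""
    sz = GroupParams(coupling_strength=0.7, amplitude_scale=1.2)
    hc = GroupParams(coupling_strength=0.3, amplitude_scale=1.0)
    return sz, hc


def null_effect() -> tuple[GroupParams, GroupParams]:
    """Chance-level condition: identical parameters for both groups."""
    p = GroupParams(coupling_strength=0.5, amplitude_scale=1.0)
    return p, p


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                beta: float) -> np.ndarray:
    """1/f^beta noise via frequency-domain shaping of white noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-beta / 2.0)
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _narrowband_source(rng: np.random.Generator, n_samples: int, fs: float,
                       f0: float, rel_bandwidth: float = 0.15) -> np.ndarray:
    """Unit-variance narrow-band noise centred at f0 (band-passed white noise).

    Narrow-band noise rather than a pure sinusoid so the instantaneous phase
    drifts realistically while remaining shared across channels.
    """
    half_bw = max(0.25, rel_bandwidth * f0 / 2.0)
    lo = max(f0 - half_bw, 1e-3)
    hi = min(f0 + half_bw, 0.999 * fs / 2.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
    sd = x.std()
    return x / (sd if sd > 0 else 1.0)


def generate_recording(params: GroupParams, cfg: CohortConfig,
                       subject_seed: int, subject_id: str = "",
                       group_label: str = "unknown") -> EEGRecording:
    """Simulate one subject's recording.

    Channel ``c`` is built as::

        amplitude_scale * ( coupling * sum_k shift(s_k, c * lag) + noise_c )

    where the ``s_k`` are shared unit-variance narrow-band sources, the shift
    is circular by ``round(c * lag_seconds * fs)`` samples, and ``noise_c``
    is independent pink + white noise scaled so that the full-strength
    (coupling = 1) oscillatory power over noise power equals ``snr``.
    """
    cfg.validate()
    params.validate(cfg.fs)
    n_samples = int(round(cfg.fs * cfg.duration_seconds))
    rng = np.random.default_rng(subject_seed)

    sources = np.stack([
        _narrowband_source(rng, n_samples, cfg.fs, f0) for f0 in params.osc_freqs
    ])  # (K, T), each unit variance

    # Full-strength oscillatory power per channel (sources are independent).
    osc_power_full = float(len(params.osc_freqs))
    noise_power = osc_power_full / params.snr
    # Split noise power: 80% pink, 20% white.
    pink = _pink_noise(rng, cfg.n_channels, n_samples, params.pink_exponent)
    white = rng.standard_normal((cfg.n_channels, n_samples))
    noise = (np.sqrt(0.8 * noise_power) * pink
             + np.sqrt(0.2 * noise_power) * white)

    lag_samples = int(round(params.lag_seconds * cfg.fs))
    signal = np.empty((cfg.n_channels, n_samples))
    for c in range(cfg.n_channels):
        mixed = np.zeros(n_samples)
        shift = (c * lag_samples) % n_samples
        for k in range(sources.shape[0]):
            mixed += np.roll(sources[k], shift)
        signal[c] = params.coupling_strength * mixed + noise[c]
    signal *= params.amplitude_scale

    return EEGRecording(
        signal=signal,
        fs=cfg.fs,
        channel_labels=cfg.channel_labels(),
        subject_id=subject_id,
        group_label=group_label,
    )


def generate_cohort(params_sz: GroupParams, params_hc: GroupParams,
                    cfg: CohortConfig) -> list[EEGRecording]:
    """Simulate a labeled two-group cohort.

    Subject seeds are derived deterministically from ``cfg.seed`` via a
    ``numpy`` SeedSequence, so the whole cohort is reproducible from one
    integer.
    """
    cfg.validate()
    params_sz.validate(cfg.fs)
    params_hc.validate(cfg.fs)
    n_sz, n_hc = cfg.counts()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_sz + n_hc) % (2**31)

    recordings: list[EEGRecording] = []
    for i in range(n_sz):
        recordings.append(generate_recording(
            params_sz, cfg, int(seeds[i]),
            subject_id=f"sz{i:03d}", group_label=SCHIZOPHRENIA))
    for i in range(n_hc):
        recordings.append(generate_recording(
            params_hc, cfg, int(seeds[n_sz + i]),
            subject_id=f"hc{i:03d}", group_label=CONTROL))
    return recordings
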