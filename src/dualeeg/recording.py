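"""Core containers for multichannel EEG recordings and analysis windows.

A recording is a channels x samples array with a sampling rate, ordered
channel labels, a subject identifier and a binary group label
(schizophrenia vs healthy control).  A window is one fixed-duration,
non-overlapping segment of a recording — the classification unit of the
pipeline (25 s by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 31 scalp electrodes of the 10-20 montage used throughout, in
#: acquisition order.  A 32nd ground channel, when present in a file, is
#: dropped before analysis so feature matrices are 31-row / 465-pair.
MONTAGE_31: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8", "FT9", "FC5", "FC1",
    "FC2", "FC6", "FT10", "T7", "C3", "C4", "T8", "TP9", "CP5", "CP1",
    "CP2", "CP6", "TP10", "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
)

#: Conventional name of the non-signal ground ("terrestrial") channel.
GROUND_CHANNEL = "GND"

SCHIZOPHRENIA = "schizophrenia"
CONTROL = "control"
VALID_LABELS = (SCHIZOPHRENIA, CONTROL, "unknown")


@dataclass
class EEGRecording:
    """One subject's continuous multichannel EEG signal.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (arbitrary units after normalization).
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Ordered channel names; length must equal ``signal.shape[0]``.
    subject_id : str
        Subject identifier.
    group_label : str
        ``"schizophrenia"``, ``"control"`` or ``"unknown"``.
    """

    signal: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    group_label: str = "unknown"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.group_label not in VALID_LABELS:
            raise ValueError(f"group_label must be one of {VALID_LABELS}")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.fs

    def drop_channels(self, names: tuple[str, ...] = (GROUND_CHANNEL,)) -> "EEGRecording":
        """Return a copy without the named channels (e.g. the ground)."""
        keep = [i for i, c in enumerate(self.channel_labels) if c not in names]
        return replace(
            self,
            signal=self.signal[keep],
            channel_labels=tuple(self.channel_labels[i] for i in keep),
        )


@dataclass
class EEGWindow:
    """One fixed-duration segment of a recording (channels x T_w).

    ``normalized`` is True once per-channel within-window z-scoring has
    been applied; feature extractors require it.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    window_index: int = 0
    label: str = "unknown"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("window data must be 2-D (channels x samples)")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def channel_pairs(labels: tuple[str, ...]) -> list[tuple[str, str]]:
    """All unordered channel pairs in canonical (lexicographic-index) order.

    For C channels this yields C(C-1)/2 pairs — 465 for the 31-channel
    montage — ordered (0,1), (0,2), ..., (C-2, C-1) by channel index.
    """
    n = len(labels)
    return [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)]
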