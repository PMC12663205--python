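"""Reading and writing multichannel EEG with labels and metadata.

Three on-disk forms are supported:

* EDF (16-bit European Data Format) — written by a small built-in writer
  (one data record per second, per-channel physical scaling) and read back
  through :func:`mne.io.read_raw_edf`;
* plain delimited text — tab-separated, one row per channel, full float
  precision, losslessly round-trippable;
* a YAML manifest mapping files to subject ids, group labels, sampling
  rates and seeds, which carries cohort-level metadata alongside either
  signal format.
"""

from __future__ import annotations

import datetime
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recording import GROUND_CHANNEL, VALID_LABELS, EEGRecording

__all__ = [
    "read_edf", "write_edf", "read_delimited", "write_delimited",
    "write_cohort", "read_cohort",
]

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | os.PathLike) -> Path:
    """Write a recording as EDF with 1-s data records.

    The sampling rate must be a positive integer (samples per 1-s record);
    a trailing partial second, if any, is dropped with a warning.  Each
    channel is scaled to the full 16-bit digital range from its own
    physical min/max, so quantization error is at most one part in 2^16 of
    the channel's range.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    nr = int(round(fs))
    n_records = rec.n_samples // nr
    if n_records == 0:
        raise ValueError("recording shorter than one 1-s EDF record")
    if n_records * nr != rec.n_samples:
        warnings.warn(
            f"dropping trailing {rec.n_samples - n_records * nr} samples "
            "(partial EDF record)")
    data = rec.signal[:, : n_records * nr]
    ns = rec.n_channels

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    gain = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * gain[:, None]) + _EDF_DIG_MIN
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    now = datetime.datetime(2000, 1, 1)  # fixed date: output is content-deterministic
    header = b"".join([
        _edf_field("0", 8),
        _edf_field(rec.subject_id or "X", 80),
        _edf_field("Startdate 01-JAN-2000", 80),
        _edf_field(now.strftime("%d.%m.%y"), 8),
        _edf_field(now.strftime("%H.%M.%S"), 8),
        _edf_field(str(256 * (ns + 1)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),
        _edf_field(str(ns), 4),
    ])
    header += b"".join(_edf_field(lbl, 16) for lbl in rec.channel_labels)
    header += b"".join(_edf_field("", 80) for _ in range(ns))
    header += b"".join(_edf_field("uV", 8) for _ in range(ns))
    header += b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_min)
    header += b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_max)
    header += b"".join(_edf_field(str(_EDF_DIG_MIN), 8) for _ in range(ns))
    header += b"".join(_edf_field(str(_EDF_DIG_MAX), 8) for _ in range(ns))
    header += b"".join(_edf_field("", 80) for _ in range(ns))
    header += b"".join(_edf_field(str(nr), 8) for _ in range(ns))
    header += b"".join(_edf_field("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header)
        # records: for each second, each channel's nr int16 samples
        for r in range(n_records):
            fh.write(digital[:, r * nr:(r + 1) * nr].tobytes())
    return path


def _edf_header_sample_rates(path: Path) -> list[float]:
    """Per-signal sampling rates from an EDF header (for validation only)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise OSError(f"{path}: truncated or empty EDF header")
        try:
            duration = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise OSError(f"{path}: not a valid EDF file ({exc})") from exc
        if ns < 1:
            raise OSError(f"{path}: EDF file declares zero signal channels")
        sig_head = fh.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise OSError(f"{path}: truncated EDF signal header")
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    rates = []
    for i in range(ns):
        nr = int(sig_head[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip())
        rates.append(nr / duration if duration > 0 else float("nan"))
    return rates


def read_edf(path: str | os.PathLike, label: str = "unknown",
             subject_id: str | None = None,
             drop_ground: bool = True) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording`.

    All signal channels must share one sampling rate (mixed-rate files are
    rejected rather than silently resampled).  Annotation channels are
    dropped; the ground channel, if present by name, is dropped when
    ``drop_ground`` is True.  Values are returned in microvolts.
    """
    import mne

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise OSError(f"{path}: missing or empty EDF file")
    rates = _edf_header_sample_rates(path)
    if len(set(rates)) > 1:
        raise ValueError(
            f"{path}: mixed per-channel sampling rates {sorted(set(rates))}; "
            "select channels with a single rate")
    if label not in VALID_LABELS:
        raise ValueError(f"label must be one of {VALID_LABELS}")

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = mne.pick_types(raw.info, eeg=True, stim=False, misc=True)
    if len(picks) == 0:
        raise ValueError(f"{path}: no signal channels")
    data = raw.get_data(picks=picks) * 1e6  # mne returns volts for uV channels
    labels = tuple(raw.ch_names[i] for i in picks)
    rec = EEGRecording(
        signal=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        subject_id=subject_id if subject_id is not None else path.stem,
        group_label=label,
    )
    if drop_ground:
        rec = rec.drop_channels((GROUND_CHANNEL,))
    return rec


def write_delimited(rec: EEGRecording, path: str | os.PathLike) -> Path:
    """Write the signal as tab-separated text, one row per channel, at full
    float precision (lossless round trip)."""
    path = Path(path)
    np.savetxt(path, rec.signal, fmt="%.17g", delimiter="\t")
    return path


def read_delimited(path: str | os.PathLike, fs: float,
                   labels: tuple[str, ...], label: str = "unknown",
                   subject_id: str = "") -> EEGRecording:
    """Read a rectangular numeric table (one row per channel)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=None, dtype=float,
                            float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged rows — {exc}") from exc
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell — {exc}") from exc
    data = frame.to_numpy()
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise ValueError(
            f"{path}: non-finite value at row {bad[0]}, column {bad[1]}")
    if data.shape[0] != len(labels):
        raise ValueError(
            f"{path}: {data.shape[0]} rows but {len(labels)} channel labels")
    return EEGRecording(signal=data, fs=fs, channel_labels=labels,
                        subject_id=subject_id, group_label=label)


def write_cohort(recordings: list[EEGRecording], outdir: str | os.PathLike,
                 fmt: str = "edf", seeds: list[int] | None = None,
                 force: bool = False) -> Path:
    """Write a cohort (one file per subject) plus a YAML manifest.

    Returns the manifest path.  Refuses to write into a non-empty directory
    unless ``force`` is set.
    """
    if fmt not in ("edf", "txt"):
        raise ValueError(f"fmt must be 'edf' or 'txt', got {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    existing = [p for p in outdir.iterdir() if p.name != "manifest.yaml"]
    if existing and not force:
        raise FileExistsError(f"{outdir} is not empty (use force to overwrite)")

    entries = []
    for i, rec in enumerate(recordings):
        fname = f"{rec.subject_id or f'subj{i:03d}'}.{fmt}"
        fpath = outdir / fname
        if fmt == "edf":
            write_edf(rec, fpath)
        else:
            write_delimited(rec, fpath)
        entry = {
            "file": fname,
            "subject_id": rec.subject_id,
            "group_label": rec.group_label,
            "fs": float(rec.fs),
            "channel_labels": list(rec.channel_labels),
        }
        if seeds is not None:
            entry["seed"] = int(seeds[i])
        entries.append(entry)

    manifest = outdir / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"format": fmt, "recordings": entries}, fh,
                       sort_keys=False)
    return manifest


def read_cohort(manifest_path: str | os.PathLike) -> list[EEGRecording]:
    """Load every recording listed in a cohort manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    fmt = manifest["format"]
    recordings = []
    for entry in manifest["recordings"]:
        fpath = manifest_path.parent / entry["file"]
        if fmt == "edf":
            rec = read_edf(fpath, label=entry["group_label"],
                           subject_id=entry["subject_id"])
        else:
            rec = read_delimited(
                fpath, fs=entry["fs"],
                labels=tuple(entry["channel_labels"]),
                label=entry["group_label"], subject_id=entry["subject_id"])
        recordings.append(rec)
    return recordings
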