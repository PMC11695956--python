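"""Reading overnight SpO2 series from CSV or EDF and normalising to 1 Hz.

Saturation values are percent (0-100); missing samples are NaN, never a
sentinel value. Polysomnography exports are accepted either as EDF/EDF+
(the native container of most sleep systems) or as plain CSV with one
(spo2) or two (time_s, spo2) columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Spo2Record",
    "read_spo2_csv",
    "read_spo2_edf",
    "write_spo2_csv",
    "downsample_to_1hz",
]


@dataclass
class Spo2Record:
    """A raw saturation series with sampling rate and implicit validity mask.

    Parameters
    ----------
    case_id : str
        Identifier carried through the pipeline.
    fs : float
        Sampling rate in Hz, strictly positive.
    values : ndarray of float
        Saturation percent per sample; NaN marks a missing sample.
        Non-missing values must lie in [0, 100].
    start_offset_s : float
        Offset of the first sample from the start of the study, seconds.
    """

    case_id: str
    fs: float
    values: np.ndarray = field(repr=False)
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("invalid sampling rate")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("no samples")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("saturation values outside [0, 100]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs


def read_spo2_csv(path, fs: float = 1.0, case_id: str | None = None) -> Spo2Record:
    """Read a one- or two-column CSV of saturation values.

    Two columns are interpreted as (time_s, spo2); one column as spo2 only.
    An optional header row is detected and skipped. Non-numeric cells become
    missing (NaN) with the row count preserved.
    """
    if fs <= 0:
        raise ValueError("invalid sampling rate")
    try:
        df = pd.read_csv(path, header=None, skip_blank_lines=True, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError("no samples") from None
    # header row: first row entirely non-numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().all():
        df = df.iloc[1:]
    if df.empty:
        raise ValueError("no samples")
    col = df.iloc[:, -1] if df.shape[1] >= 2 else df.iloc[:, 0]
    values = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    name = case_id if case_id is not None else _stem(path)
    return Spo2Record(case_id=name, fs=fs, values=values)


def write_spo2_csv(rec: Spo2Record, path) -> None:
    """Write a record as a two-column (time_s, spo2) CSV; NaN becomes 'NA'."""
    t = rec.start_offset_s + np.arange(len(rec)) / rec.fs
    df = pd.DataFrame({"time_s": t, "spo2": rec.values})
    df.to_csv(path, index=False, na_rep="NA")


def _stem(path) -> str:
    if isinstance(path, (str, bytes)):
        import os

        return os.path.splitext(os.path.basename(os.fsdecode(path)))[0]
    if isinstance(path, io.IOBase):
        return "spo2"
    try:  # pathlib
        return path.stem
    except AttributeError:
        return "spo2"


DEFAULT_CHANNEL_PATTERNS = ("spo2", "sao2")


def read_spo2_edf(path, channel: str | None = None, case_id: str | None = None) -> Spo2Record:
    """Read the saturation channel of an EDF/EDF+ file.

    The channel is located by case-insensitive substring match: ``channel``
    if given, else any label containing "SpO2" or "SaO2". The record keeps
    the channel's native sampling rate from the EDF header; resample with
    :func:`downsample_to_1hz` afterwards.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    labels = list(raw.ch_names)
    patterns = (channel.lower(),) if channel else DEFAULT_CHANNEL_PATTERNS
    picked = next((l for l in labels for p in patterns if p in l.lower()), None)
    if picked is None:
        raise ValueError(f"channel not found; available labels: {labels}")
    # Re-read with the channel typed misc so physical values are untouched
    # (mne rescales channels it believes to be EEG volts).
    raw = mne.io.read_raw_edf(
        path, include=[picked], misc=[picked], preload=True, verbose="error"
    )
    values = raw.get_data(picks=[picked])[0]
    fs = float(raw.info["sfreq"])
    name = case_id if case_id is not None else _stem(path)
    return Spo2Record(case_id=name, fs=fs, values=np.asarray(values, dtype=float))


def downsample_to_1hz(rec: Spo2Record) -> Spo2Record:
    """Reduce a record to 1 Hz by non-overlapping 1-second block means.

    Each output sample is the mean of the non-missing inputs of one second;
    a block with every input missing stays missing. A trailing partial block
    is dropped. Block averaging (rather than decimation) is robust to
    single-sample spikes. ``fs`` must be a positive integer number of Hz.
    """
    step = rec.fs
    if step < 1 or abs(step - round(step)) > 1e-9:
        raise ValueError("unsupported rate")
    step = int(round(step))
    if step == 1:
        return rec
    n = (len(rec.values) // step) * step
    if n == 0:
        raise ValueError("no samples")
    blocks = rec.values[:n].reshape(-1, step)
    with np.errstate(invalid="ignore"):
        counts = np.sum(np.isfinite(blocks), axis=1)
        sums = np.nansum(blocks, axis=1)
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return replace(rec, fs=1.0, values=out)
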