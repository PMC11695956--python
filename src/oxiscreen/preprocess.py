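"""Three-step artifact rejection for 1 Hz SpO2 and segmentation into valid runs.

The cleaning rules mirror common oximetry practice for home and in-lab
recordings: (1) physiologically impossible values below 50% are rejected;
(2) drops of more than 4 percentage points within one second are rejected as
probe artifacts; (3) invalid stretches longer than one minute (probe
disconnection, movement) break the record, while shorter gaps are repaired
by linear interpolation so spectral and entropy analysis see a continuous
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import Spo2Record

__all__ = [
    "PreprocessConfig",
    "CleanSignal",
    "mask_low_values",
    "mask_abrupt_drops",
    "segment_valid",
    "clean",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the cleaning pipeline.

    low_cutoff : saturation percent below which a sample is rejected.
    max_drop_per_s : largest credible 1-second fall, percentage points.
    max_gap_s : longest invalid run bridged by interpolation, seconds.
    min_segment_s : shortest segment kept; shorter runs cannot support
        20-scale entropy or 0.001 Hz-resolution spectra.
    """

    low_cutoff: float = 50.0
    max_drop_per_s: float = 4.0
    max_gap_s: int = 60
    min_segment_s: int = 300


@dataclass
class CleanSignal:
    """Artifact-free 1 Hz segments of one overnight recording.

    ``segments`` are contiguous runs of valid (possibly interpolated)
    samples in temporal order; ``segment_starts_s`` gives each run's offset
    from the start of the raw record.
    """

    case_id: str
    segments: list[np.ndarray] = field(repr=False)
    segment_starts_s: list[int] = field(default_factory=list, repr=False)
    total_duration_s: float = 0.0

    @property
    def valid_duration_s(self) -> float:
        return float(sum(len(s) for s in self.segments))

    def pooled(self) -> np.ndarray:
        """All valid samples concatenated across segments."""
        if not self.segments:
            return np.empty(0)
        return np.concatenate(self.segments)

    def longest_segment(self) -> np.ndarray:
        return max(self.segments, key=len)

    def to_record(self) -> Spo2Record:
        """Reassemble a 1 Hz record, missing everywhere outside the segments."""
        n = int(round(self.total_duration_s))
        values = np.full(max(n, 1), np.nan)
        for seg, start in zip(self.segments, self.segment_starts_s):
            values[start : start + len(seg)] = seg
        return Spo2Record(case_id=self.case_id, fs=1.0, values=values)


def _require_1hz(rec: Spo2Record) -> None:
    if abs(rec.fs - 1.0) > 1e-9:
        raise ValueError("preprocessing requires a 1 Hz record; downsample first")


def mask_low_values(rec: Spo2Record, low_cutoff: float = 50.0) -> Spo2Record:
    """Mark samples below ``low_cutoff`` percent as missing (boundary kept)."""
    _require_1hz(rec)
    values = rec.values.copy()
    with np.errstate(invalid="ignore"):
        values[values < low_cutoff] = np.nan
    return replace(rec, values=values)


def mask_abrupt_drops(rec: Spo2Record, max_drop_per_s: float = 4.0) -> Spo2Record:
    """Mark samples falling more than ``max_drop_per_s`` points below the
    last accepted sample as missing.

    The comparison always proceeds from the last *accepted* sample, so a
    rejected spike keeps masking the low run it starts until the signal
    recovers, while genuine desaturations (which ramp at <= 4 points/s)
    pass untouched. A drop of exactly the threshold is allowed.
    """
    _require_1hz(rec)
    values = rec.values.copy()
    last = np.nan
    for i, v in enumerate(values):
        if not np.isfinite(v):
            continue
        if np.isfinite(last) and (last - v) > max_drop_per_s:
            values[i] = np.nan
        else:
            last = v
    return replace(rec, values=values)


def segment_valid(
    rec: Spo2Record,
    max_gap_s: int = 60,
    min_segment_s: int = 300,
) -> CleanSignal:
    """Split a masked record into continuous valid segments.

    Missing runs of at most ``max_gap_s`` seconds are bridged by linear
    interpolation between the flanking valid samples; longer runs split the
    record. Leading/trailing missing runs are dropped. Segments shorter
    than ``min_segment_s`` are discarded.
    """
    _require_1hz(rec)
    values = rec.values
    valid = np.isfinite(values)
    if not valid.any():
        raise ValueError("record unusable after cleaning")

    segments: list[np.ndarray] = []
    starts: list[int] = []
    idx = np.flatnonzero(valid)
    seg_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        gap = i - prev - 1
        if gap > max_gap_s:
            segments.append(_interp_run(values, seg_start, prev))
            starts.append(seg_start)
            seg_start = i
        prev = i
    segments.append(_interp_run(values, seg_start, prev))
    starts.append(seg_start)

    kept = [(s, a) for s, a in zip(segments, starts) if len(s) >= min_segment_s]
    if not kept:
        raise ValueError("record unusable after cleaning")
    return CleanSignal(
        case_id=rec.case_id,
        segments=[s for s, _ in kept],
        segment_starts_s=[a for _, a in kept],
        total_duration_s=rec.duration_s,
    )


def _interp_run(values: np.ndarray, start: int, stop: int) -> np.ndarray:
    """Contiguous slice [start, stop] with interior NaN gaps interpolated."""
    seg = values[start : stop + 1].copy()
    bad = ~np.isfinite(seg)
    if bad.any():
        good = np.flatnonzero(~bad)
        seg[bad] = np.interp(np.flatnonzero(bad), good, seg[good])
    return seg


def clean(rec: Spo2Record, config: PreprocessConfig | None = None) -> CleanSignal:
    """Canonical cleaning pipeline: low-value mask, abrupt-drop mask, segment."""
    cfg = config or PreprocessConfig()
    rec = mask_low_values(rec, cfg.low_cutoff)
    rec = mask_abrupt_drops(rec, cfg.max_drop_per_s)
    return segment_valid(rec, cfg.max_gap_s, cfg.min_segment_s)
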