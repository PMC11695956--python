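"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from oxiscreen.preprocess import CleanSignal


# --------------------------------------------------------------- oracles


def brute_force_sample_entropy(x, m=2, r=None):
    """O(N^2) reference SampEn: explicit template pair counting,
    Chebyshev distance, <= r matches, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if r is None:
        r = 0.15 * x.std()
    nt = n - m

    def count(length):
        total = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                if np.max(np.abs(x[i : i + length] - x[j : j + length])) <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if b == 0:
        return 0.0
    if a == 0:
        return float(np.log(nt * (nt - 1)))
    return float(-np.log(a / b))


def pair_count_auc(y, scores):
    """O(n^2) AUC oracle: fraction of (positive, negative) pairs ranked
    correctly, ties counted half."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else 0.5 if p == q else 0.0
    return wins / (len(pos) * len(neg))


# --------------------------------------------------------- fixture builders


def make_clean(values, case_id="t", total=None) -> CleanSignal:
    """Wrap one or more plain arrays as a CleanSignal without preprocessing."""
    segs = [np.asarray(v, dtype=float) for v in (values if isinstance(values, list) else [values])]
    starts = []
    pos = 0
    for s in segs:
        starts.append(pos)
        pos += len(s) + 61
    return CleanSignal(
        case_id=case_id,
        segments=segs,
        segment_starts_s=starts,
        total_duration_s=float(total if total is not None else pos),
    )


def _pad(text, width):
    b = str(text).encode("ascii")
    assert len(b) <= width
    return b + b" " * (width - len(b))


def write_edf(path, channels):
    """Write a minimal EDF file; ``channels`` is a list of
    ``(label, fs, samples)`` with integer-valued samples in [0, 100].

    One-second data records, 16-bit little-endian samples, physical and
    digital ranges both 0-100 so stored values equal physical values.
    """
    ns = len(channels)
    n_records = min(len(s) // int(fs) for _, fs, s in channels)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("synthetic patient", 80),
            _pad("synthetic recording", 80),
            _pad("01.01.20", 8),
            _pad("22.00.00", 8),
            _pad(256 * (1 + ns), 8),
            _pad("", 44),
            _pad(n_records, 8),
            _pad("1", 8),
            _pad(ns, 4),
        ]
    )
    for field, width in [
        ([label for label, _, _ in channels], 16),
        (["" for _ in channels], 80),
        (["%" for _ in channels], 8),
        (["0" for _ in channels], 8),
        (["100" for _ in channels], 8),
        (["0" for _ in channels], 8),
        (["100" for _ in channels], 8),
        (["" for _ in channels], 80),
        ([str(int(fs)) for _, fs, _ in channels], 8),
        (["" for _ in channels], 32),
    ]:
        header += b"".join(_pad(v, width) for v in field)
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for _, fs, samples in channels:
                fs = int(fs)
                chunk = np.asarray(samples[rec * fs : (rec + 1) * fs], dtype=np.int16)
                fh.write(struct.pack(f"<{fs}h", *chunk))


@pytest.fixture
def edf_writer():
    return write_edf
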