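"""The 128 oximetry features used to grade sleep-apnea severity.

Four families, concatenated in a fixed order:

* 7 distribution statistics of the pooled valid samples
  (mean, median, maximum, minimum, kurtosis, variance, skewness);
* 100 relative spectral-power values in 0.001 Hz bins from 0.001 to
  0.100 Hz — cyclic desaturation in apnea concentrates power around
  0.01-0.03 Hz (periods of roughly 30-100 s);
* 20 multiscale-entropy values: sample entropy of the coarse-grained
  series at scales 1..20;
* 1 approximated oxygen desaturation index (ODI4): 4-point desaturation
  events per hour of artifact-free recording (sleep staging is not
  available from the oximeter alone, so valid recording time stands in
  for total sleep time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from scipy.spatial import cKDTree

from .preprocess import CleanSignal

__all__ = [
    "FeatureConfig",
    "OximetryFeatures",
    "distribution_features",
    "psd_features",
    "relative_power_spectrum",
    "coarse_grain",
    "sample_entropy",
    "mse_features",
    "estimate_odi",
    "extract_all",
    "feature_names",
]

N_PSD_BINS = 100
N_MSE_SCALES = 20


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction tunables.

    psd_window_s : Welch window length in seconds. 1000 samples at 1 Hz is
        the one window giving exactly the 0.001 Hz bin spacing of the
        spectral features.
    mse_m : sample-entropy template length.
    mse_r_factor : entropy tolerance as a fraction of the scale-1 standard
        deviation; the tolerance is frozen across scales so that the curve
        reflects coarse-graining, not tolerance re-scaling.
    odi_* : constants of the desaturation detector (ODI4 convention):
        running baseline is the maximum saturation over the preceding
        ``odi_baseline_window_s``; an event starts when the signal falls
        ``odi_onset_drop`` points below it and ends on recovery to within
        ``odi_recovery_margin`` points of the onset baseline or after
        ``odi_max_event_s``; events are separated by at least
        ``odi_min_separation_s``.
    """

    psd_window_s: int = 1000
    mse_m: int = 2
    mse_r_factor: float = 0.15
    odi_baseline_window_s: int = 120
    odi_onset_drop: float = 4.0
    odi_recovery_margin: float = 2.0
    odi_max_event_s: int = 180
    odi_min_separation_s: int = 10


DEFAULT_CONFIG = FeatureConfig()

DIST_NAMES = (
    "dist_mean",
    "dist_median",
    "dist_max",
    "dist_min",
    "dist_kurtosis",
    "dist_variance",
    "dist_skewness",
)


def feature_names() -> list[str]:
    """The 128 feature names, in extraction order (``dist_mean`` .. ``odi``)."""
    names = list(DIST_NAMES)
    names += [f"psd_{k / 1000:.3f}hz" for k in range(1, N_PSD_BINS + 1)]
    names += [f"mse_{tau}" for tau in range(1, N_MSE_SCALES + 1)]
    names.append("odi")
    return names


@dataclass
class OximetryFeatures:
    """The 128-value oximetry feature vector of one recording."""

    case_id: str
    dist: np.ndarray = field(repr=False)
    psd: np.ndarray = field(repr=False)
    mse: np.ndarray = field(repr=False)
    odi: float = 0.0

    def vector(self) -> np.ndarray:
        return np.concatenate([self.dist, self.psd, self.mse, [self.odi]])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(feature_names(), self.vector()))


# ---------------------------------------------------------------- distribution


def distribution_features(sig: CleanSignal) -> np.ndarray:
    """Mean, median, max, min, excess kurtosis, population variance, skewness
    of all valid samples pooled across segments.

    Skewness and kurtosis use the bias-adjusted Fisher definitions and are 0
    by convention for a constant signal.
    """
    x = sig.pooled()
    if x.size == 0:
        raise ValueError("no valid samples")
    var = float(np.var(x))
    if var > 0 and x.size > 2:
        skew = float(spstats.skew(x, bias=False))
        kurt = float(spstats.kurtosis(x, bias=False))
    else:
        skew = kurt = 0.0
    return np.array(
        [float(np.mean(x)), float(np.median(x)), float(np.max(x)), float(np.min(x)), kurt, var, skew]
    )


# ------------------------------------------------------------------------ PSD


def _segment_relative_psd(seg: np.ndarray, window_s: int) -> np.ndarray:
    """Relative power of one segment in every non-DC bin (0.001 Hz spacing).

    Welch estimate with a Hann window of ``window_s`` samples and 50%
    overlap on the mean-subtracted segment; each bin is divided by the
    total non-DC power so the full band sums to 1. A constant segment has
    zero total power and returns zeros.
    """
    _, pxx = sps.welch(
        seg - np.mean(seg),
        fs=1.0,
        window="hann",
        nperseg=window_s,
        noverlap=window_s // 2,
        detrend=False,
    )
    power = pxx[1:]  # DC excluded
    total = power.sum()
    if total <= 0:
        return np.zeros_like(power)
    return power / total


def relative_power_spectrum(sig: CleanSignal, config: FeatureConfig | None = None):
    """Duration-weighted relative power spectrum over the full non-DC band.

    Returns ``(freqs, relpower)`` with freqs ``k * 0.001 Hz`` for
    ``k = 1 .. window_s/2``.
    """
    cfg = config or DEFAULT_CONFIG
    long_enough = [s for s in sig.segments if len(s) >= cfg.psd_window_s]
    if not long_enough:
        raise ValueError("insufficient continuous signal for PSD")
    weights = np.array([len(s) for s in long_enough], dtype=float)
    spectra = np.array([_segment_relative_psd(s, cfg.psd_window_s) for s in long_enough])
    rel = np.average(spectra, axis=0, weights=weights)
    freqs = np.arange(1, rel.size + 1) / cfg.psd_window_s
    return freqs, rel


def psd_features(sig: CleanSignal, config: FeatureConfig | None = None) -> np.ndarray:
    """The first 100 relative-power bins, centred at k*0.001 Hz, k = 1..100."""
    _, rel = relative_power_spectrum(sig, config)
    return rel[:N_PSD_BINS].copy()


# -------------------------------------------------------------------- entropy


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Average non-overlapping blocks of ``tau`` consecutive samples."""
    if tau < 1:
        raise ValueError("invalid scale")
    x = np.asarray(series, dtype=float)
    if x.size < tau:
        raise ValueError("series shorter than scale")
    if tau == 1:
        return x.copy()
    n = (x.size // tau) * tau
    return x[:n].reshape(-1, tau).mean(axis=1)


def _template_matches(x: np.ndarray, length: int, n_templates: int, r: float) -> float:
    """Unordered pairs of length-``length`` templates within Chebyshev r.

    Templates are compressed to unique rows with multiplicities before the
    KD-tree pair count — exact, and far faster on quantised oximetry data
    where few distinct templates occur.
    """
    emb = np.lib.stride_tricks.sliding_window_view(x, length)[:n_templates]
    uniq, counts = np.unique(emb, axis=0, return_counts=True)
    w = counts.astype(float)
    tree = cKDTree(uniq)
    total = tree.count_neighbors(tree, r, p=np.inf, weights=(w, w))
    return (total - w.sum()) / 2.0


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -ln(A/B) with A (B) the number of template pairs of
    length m+1 (m) within Chebyshev tolerance r, self-matches excluded.

    ``r`` defaults to 0.15 times the series SD. When no m+1 template pair
    matches (A = 0) the estimator diverges; the finite cap
    ``ln((N-m)(N-m-1))`` — the largest value a single matching pair could
    produce — is returned instead.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if m < 1:
        raise ValueError("invalid template length")
    if n <= m + 1:
        raise ValueError("insufficient length for entropy")
    if r is None:
        r = 0.15 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance must be positive")
    n_templates = n - m
    b = _template_matches(x, m, n_templates, r)
    a = _template_matches(x, m + 1, n_templates, r)
    if b == 0:
        return 0.0
    if a == 0:
        return float(np.log(n_templates * (n_templates - 1)))
    return float(-np.log(a / b))


def mse_features(sig: CleanSignal, config: FeatureConfig | None = None) -> np.ndarray:
    """Sample entropy of the longest segment at coarse-graining scales 1..20.

    The tolerance r is fixed from the scale-1 SD of that segment. The
    longest segment is used alone: coarse-graining across segment
    boundaries would fabricate dynamics that are not in the data.
    """
    cfg = config or DEFAULT_CONFIG
    seg = sig.longest_segment()
    if len(seg) < N_MSE_SCALES * (cfg.mse_m + 2):
        raise ValueError("insufficient length for entropy")
    sd = float(np.std(seg))
    r = cfg.mse_r_factor * sd
    if r <= 0:
        # constant segment: zero complexity at every scale
        return np.zeros(N_MSE_SCALES)
    out = np.empty(N_MSE_SCALES)
    for tau in range(1, N_MSE_SCALES + 1):
        out[tau - 1] = sample_entropy(coarse_grain(seg, tau), cfg.mse_m, r)
    return out


# ------------------------------------------------------------------------ ODI


def _detect_events(seg: np.ndarray, cfg: FeatureConfig) -> int:
    """Count 4-point desaturation events in one continuous segment.

    Running baseline at time t is the maximum saturation over the
    preceding ``odi_baseline_window_s`` seconds (excluding t). An event
    starts when the value falls at least ``odi_onset_drop`` below it, ends
    on recovery to within ``odi_recovery_margin`` of the onset baseline or
    after ``odi_max_event_s``, and a refractory ``odi_min_separation_s``
    follows each event.
    """
    n = len(seg)
    w = cfg.odi_baseline_window_s
    # rolling max over [t-w, t-1]
    windows = np.lib.stride_tricks.sliding_window_view(
        np.concatenate([np.full(w, -np.inf), seg[:-1]]), w
    )
    baseline = windows.max(axis=1)
    baseline[0] = seg[0]

    count = 0
    t = 0
    next_allowed = 0
    while t < n:
        if t >= next_allowed and seg[t] <= baseline[t] - cfg.odi_onset_drop:
            onset_baseline = baseline[t]
            count += 1
            end = t + 1
            while (
                end < n
                and end - t < cfg.odi_max_event_s
                and seg[end] < onset_baseline - cfg.odi_recovery_margin
            ):
                end += 1
            next_allowed = end + cfg.odi_min_separation_s
            t = end
        else:
            t += 1
    return count


def estimate_odi(sig: CleanSignal, config: FeatureConfig | None = None) -> float:
    """Approximated oxygen desaturation index: 4-point desaturation events
    per hour of valid (artifact-free) recording time."""
    cfg = config or DEFAULT_CONFIG
    hours = sig.valid_duration_s / 3600.0
    if hours <= 0:
        raise ValueError("no valid samples")
    events = sum(_detect_events(seg, cfg) for seg in sig.segments)
    return events / hours


# ------------------------------------------------------------------- assembly


def extract_all(sig: CleanSignal, config: FeatureConfig | None = None) -> OximetryFeatures:
    """The full 128-value vector in order [dist(7), psd(100), mse(20), odi]."""
    cfg = config or DEFAULT_CONFIG
    try:
        dist = distribution_features(sig)
    except ValueError as e:
        raise ValueError(f"distribution features: {e}") from None
    try:
        psd = psd_features(sig, cfg)
    except ValueError as e:
        raise ValueError(f"psd features: {e}") from None
    try:
        mse = mse_features(sig, cfg)
    except ValueError as e:
        raise ValueError(f"mse features: {e}") from None
    odi = estimate_odi(sig, cfg)
    return OximetryFeatures(case_id=sig.case_id, dist=dist, psd=psd, mse=mse, odi=odi)
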