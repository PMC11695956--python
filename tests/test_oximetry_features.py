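"""Distribution, spectral, entropy and ODI features of the SpO2 signal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxiscreen import (
    coarse_grain,
    distribution_features,
    estimate_odi,
    extract_all,
    feature_names,
    mse_features,
    psd_features,
    relative_power_spectrum,
    sample_entropy,
)
from conftest import brute_force_sample_entropy, make_clean


class TestDistribution:
    def test_constant_signal_degenerate_stats(self):
        f = distribution_features(make_clean(np.full(600, 95.0)))
        mean, median, mx, mn, kurt, var, skew = f
        assert (mean, median, mx, mn) == (95, 95, 95, 95)
        assert var == 0 and skew == 0 and kurt == 0

    def test_symmetric_three_point(self):
        f = distribution_features(make_clean(np.array([90.0, 95.0, 100.0])))
        assert f[0] == pytest.approx(95)
        assert f[5] == pytest.approx(50 / 3)  # population variance
        assert f[6] == pytest.approx(0)  # symmetric -> zero skew

    def test_low_outlier_lowers_min_and_skews_left(self):
        base = np.full(600, 96.0)
        f = distribution_features(make_clean(np.concatenate([base, [80.0]])))
        assert f[3] == 80
        assert f[6] < 0

    def test_min_le_median_le_max(self):
        rng = np.random.default_rng(0)
        f = distribution_features(make_clean(95 + rng.normal(0, 1, 500)))
        assert f[3] <= f[1] <= f[2]


class TestPsd:
    def test_sinusoid_peaks_in_matching_bin(self):
        t = np.arange(3600.0)
        sig = make_clean(96 + 2 * np.sin(2 * np.pi * 0.020 * t))
        p = psd_features(sig)
        assert len(p) == 100
        assert np.argmax(p) == 19  # bin k=20 is 0.020 Hz

    def test_full_band_relative_power_sums_to_one(self):
        rng = np.random.default_rng(1)
        sig = make_clean(96 + rng.normal(0, 0.5, 4000))
        _, rel = relative_power_spectrum(sig)
        assert rel.sum() == pytest.approx(1.0, abs=1e-9)
        assert (rel >= 0).all()

    def test_constant_signal_yields_zeros(self):
        p = psd_features(make_clean(np.full(2000, 96.0)))
        np.testing.assert_array_equal(p, 0)

    def test_short_segments_rejected(self):
        with pytest.raises(ValueError, match="insufficient continuous signal"):
            psd_features(make_clean(np.full(600, 96.0)))

    def test_duration_weighted_segment_combination(self):
        rng = np.random.default_rng(2)
        a = 96 + rng.normal(0, 0.5, 3000)
        b = 96 + rng.normal(0, 0.5, 1000)
        combined = psd_features(make_clean([a, b]))
        pa, pb = psd_features(make_clean(a)), psd_features(make_clean(b))
        np.testing.assert_allclose(combined, (3000 * pa + 1000 * pb) / 4000, atol=1e-12)


class TestCoarseGrain:
    def test_scale_one_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_block_means(self):
        np.testing.assert_array_equal(coarse_grain(np.array([1.0, 2, 3, 4]), 2), [1.5, 3.5])

    def test_floor_length(self):
        assert len(coarse_grain(np.arange(101.0), 20)) == 5

    def test_invalid_scale(self):
        with pytest.raises(ValueError, match="invalid scale"):
            coarse_grain(np.arange(10.0), 0)


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.full(100, 95.0), m=2, r=0.5) == 0.0

    def test_alternating_series_matches_bruteforce(self):
        x = np.array([1.0, 2, 1, 2, 1, 2, 1, 2, 1, 2])
        r = 0.2 * x.std()
        assert sample_entropy(x, 2, r) == pytest.approx(brute_force_sample_entropy(x, 2, r))

    def test_noise_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=300)
        r = 0.15 * x.std()
        assert sample_entropy(x, 2, r) == pytest.approx(brute_force_sample_entropy(x, 2, r))

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="insufficient length"):
            sample_entropy(np.array([1.0, 2.0, 3.0]), m=2, r=0.1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=90, max_value=99), min_size=10, max_size=60))
    def test_matches_bruteforce_on_quantized_series(self, vals):
        x = np.asarray(vals, dtype=float)
        if x.std() == 0:
            return
        r = 0.2 * x.std()
        assert sample_entropy(x, 2, r) == pytest.approx(brute_force_sample_entropy(x, 2, r))


class TestMse:
    def test_scale_one_equals_raw_sample_entropy(self):
        rng = np.random.default_rng(6)
        x = np.round(96 + rng.normal(0, 1, 1500))
        sig = make_clean(x)
        mse = mse_features(sig)
        assert len(mse) == 20
        assert mse[0] == pytest.approx(sample_entropy(x, 2, 0.15 * x.std()))

    def test_constant_signal_all_zero(self):
        np.testing.assert_array_equal(mse_features(make_clean(np.full(600, 95.0))), 0)

    def test_white_noise_entropy_decreasing_trend(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 10000)
        mse = mse_features(make_clean(np.clip(96 + x, 50, 100)))
        diffs = np.diff(mse)
        assert mse[-1] < mse[0]
        assert (diffs <= 0.1).all()  # non-increasing within sampling error


def _twelve_event_trace(n=3600, depth=6.0, spacing=300):
    """Flat 96 baseline with 12 constructed desaturations of 40 s."""
    v = np.full(n, 96.0)
    prof = np.concatenate([np.linspace(0, depth, 12, endpoint=False), np.full(16, depth), np.linspace(depth, 0, 13)[1:]])
    for k in range(12):
        s = 100 + k * spacing
        v[s : s + 40] -= prof
    return v


class TestOdi:
    def test_flat_signal_zero(self):
        assert estimate_odi(make_clean(np.full(7200, 96.0))) == 0.0

    def test_constructed_events_counted_exactly(self):
        sig = make_clean(_twelve_event_trace())
        assert estimate_odi(sig) == pytest.approx(12.0)

    def test_denominator_linearity(self):
        sig = make_clean([_twelve_event_trace(), np.full(3600, 96.0)])
        assert estimate_odi(sig) == pytest.approx(6.0)

    def test_flat_padding_preserves_event_count(self):
        v = _twelve_event_trace()
        padded = np.concatenate([np.full(600, 96.0), v, np.full(600, 96.0)])
        n_ev = estimate_odi(make_clean(v)) * (len(v) / 3600)
        n_ev_padded = estimate_odi(make_clean(padded)) * (len(padded) / 3600)
        assert n_ev == pytest.approx(n_ev_padded)

    def test_shallow_dip_not_counted(self):
        v = np.full(3600, 96.0)
        v[1000:1030] = 93.0  # 3-point dip, below the 4-point criterion
        assert estimate_odi(make_clean(v)) == 0.0


class TestExtractAll:
    def test_vector_shape_names_and_determinism(self):
        rng = np.random.default_rng(8)
        x = np.round(np.clip(96 + rng.normal(0, 1, 4000), 50, 100))
        sig = make_clean(x)
        f1 = extract_all(sig).vector()
        f2 = extract_all(make_clean(x.copy())).vector()
        assert len(f1) == 128
        np.testing.assert_array_equal(f1, f2)
        names = feature_names()
        assert names[0] == "dist_mean" and names[-1] == "odi"
        assert len(names) == 128 and len(set(names)) == 128

    def test_error_carries_family_context(self):
        with pytest.raises(ValueError, match="psd features"):
            extract_all(make_clean(np.full(600, 96.0)))
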