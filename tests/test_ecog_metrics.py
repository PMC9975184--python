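"""Filtering, binned RMS, normalization, percentile criterion, spectrogram."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seizurespan import (
    BinnedSeries,
    EcogRecording,
    ElectrodeGrid,
    NormalizedSeries,
    apply_standard_filters,
    detect_significant_deviation,
    display_scale,
    normalize_to_pretreatment,
    rms_binned,
    spectrogram_normalized,
)


def tone_recording(freq_hz, amplitude=100.0, fs=3000.0, duration_s=10.0, n_channels=1):
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    grid = ElectrodeGrid(n_rows=1, n_cols=n_channels)
    return EcogRecording(grid=grid, sample_rate_hz=fs,
                         samples=np.tile(x, (n_channels, 1)))


def rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


class TestStandardFilters:
    def test_line_noise_tone_attenuated_40db(self):
        rec = tone_recording(50.0)
        out = apply_standard_filters(rec)
        # ignore filtfilt edge transients
        sl = slice(3000, -3000)
        atten_db = 20 * np.log10(rms(rec.samples[0][sl]) / rms(out.samples[0][sl]))
        assert atten_db >= 40.0

    def test_passband_tone_within_1db(self):
        rec = tone_recording(10.0)
        out = apply_standard_filters(rec)
        sl = slice(3000, -3000)
        delta_db = abs(20 * np.log10(rms(out.samples[0][sl]) / rms(rec.samples[0][sl])))
        assert delta_db <= 1.0

    def test_zero_signal_stays_zero(self):
        rec = tone_recording(10.0, amplitude=0.0, duration_s=2.0)
        out = apply_standard_filters(rec)
        assert np.allclose(out.samples, 0.0)

    def test_low_sample_rate_rejected(self):
        rec = tone_recording(10.0, fs=100.0, duration_s=2.0)
        with pytest.raises(ValueError, match="sample rate"):
            apply_standard_filters(rec)

    def test_invalid_channels_pass_through(self):
        grid = ElectrodeGrid(n_rows=1, n_cols=2, valid_mask=(True, False))
        x = np.vstack([np.sin(2 * np.pi * 50 * np.arange(6000) / 3000)] * 2)
        rec = EcogRecording(grid=grid, sample_rate_hz=3000.0, samples=x * 100)
        out = apply_standard_filters(rec)
        np.testing.assert_array_equal(out.samples[1], rec.samples[1])
        assert rms(out.samples[0]) < rms(rec.samples[0])

    @settings(max_examples=20, deadline=None)
    @given(c=st.floats(min_value=0.1, max_value=50.0))
    def test_filter_scalar_homogeneity(self, c):
        rng = np.random.default_rng(5)
        grid = ElectrodeGrid(n_rows=1, n_cols=1)
        x = rng.normal(0, 10, size=(1, 2000))
        base = apply_standard_filters(
            EcogRecording(grid=grid, sample_rate_hz=500.0, samples=x)
        ).samples
        scaled = apply_standard_filters(
            EcogRecording(grid=grid, sample_rate_hz=500.0, samples=c * x)
        ).samples
        np.testing.assert_allclose(scaled, c * base, rtol=1e-9, atol=1e-9)


class TestRmsBinned:
    def test_constant_signal(self, dcz_timeline):
        tl = dcz_timeline(treatment_s=120.0)
        grid = ElectrodeGrid(n_rows=1, n_cols=2)
        fs = 200.0
        samples = np.full((2, int(240 * fs)), -3.0)
        rec = EcogRecording(grid=grid, sample_rate_hz=fs, samples=samples)
        series = rms_binned(rec, tl, bin_range_min=(-2, 2))
        np.testing.assert_allclose(series.values, 3.0)

    def test_sinusoid_rms_analytic(self, dcz_timeline):
        tl = dcz_timeline(treatment_s=120.0)
        fs, A = 1000.0, 42.0
        t = np.arange(int(240 * fs)) / fs
        x = A * np.sin(2 * np.pi * 7.0 * t)
        rec = EcogRecording(
            grid=ElectrodeGrid(n_rows=1, n_cols=1), sample_rate_hz=fs, samples=x[None, :]
        )
        series = rms_binned(rec, tl, bin_range_min=(-2, 2))
        np.testing.assert_allclose(series.values, A / np.sqrt(2), rtol=1e-3)

    def test_matches_bruteforce_oracle(self, dcz_timeline, rng):
        tl = dcz_timeline(treatment_s=60.0)
        fs = 100.0
        samples = rng.normal(0, 5, size=(2, int(180 * fs)))
        rec = EcogRecording(
            grid=ElectrodeGrid(n_rows=1, n_cols=2), sample_rate_hz=fs, samples=samples
        )
        series = rms_binned(rec, tl, bin_range_min=(-1, 2))
        for i, k in enumerate([-1, 0, 1]):
            i0 = int((60.0 + k * 60.0) * fs)
            block = samples[:, i0 : i0 + int(60 * fs)]
            expected = np.mean(np.sqrt(np.mean(block**2, axis=1)))
            assert series.values[i] == pytest.approx(expected, rel=1e-12)

    def test_rms_scale_equivariance(self, dcz_timeline, rng):
        tl = dcz_timeline(treatment_s=60.0)
        fs = 50.0
        samples = rng.normal(0, 5, size=(1, int(120 * fs)))
        rec = lambda s: EcogRecording(
            grid=ElectrodeGrid(n_rows=1, n_cols=1), sample_rate_hz=fs, samples=s
        )
        a = rms_binned(rec(samples), tl, bin_range_min=(-1, 1)).values
        b = rms_binned(rec(-2.5 * samples), tl, bin_range_min=(-1, 1)).values
        np.testing.assert_allclose(b, 2.5 * a, rtol=1e-12)

    def test_empty_or_invalid_channel_set_rejected(self, dcz_timeline):
        tl = dcz_timeline(treatment_s=60.0)
        grid = ElectrodeGrid(n_rows=1, n_cols=2, valid_mask=(True, False))
        rec = EcogRecording(
            grid=grid, sample_rate_hz=50.0, samples=np.ones((2, 6000))
        )
        with pytest.raises(ValueError, match="empty"):
            rms_binned(rec, tl, channels=[], bin_range_min=(-1, 1))
        with pytest.raises(ValueError, match="not valid"):
            rms_binned(rec, tl, channels=[1], bin_range_min=(-1, 1))

    def test_bins_outside_recording_rejected(self, dcz_timeline):
        tl = dcz_timeline(treatment_s=60.0)
        rec = EcogRecording(
            grid=ElectrodeGrid(n_rows=1, n_cols=1), sample_rate_hz=50.0,
            samples=np.ones((1, 6000)),
        )
        with pytest.raises(ValueError, match="outside recording"):
            rms_binned(rec, tl, bin_range_min=(-5, 1))


def percentile_oracle(values, q=95.0):
    """Independent linear-interpolation percentile (sort + interpolate)."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestNormalization:
    def test_baseline_five_post_ten(self):
        series = BinnedSeries(np.arange(-3, 1, dtype=float), [5.0, 5.0, 5.0, 10.0])
        nser = normalize_to_pretreatment(series, (-3, 0))
        assert nser.values[-1] == pytest.approx(2.0)
        assert nser.baseline_mean == pytest.approx(5.0)

    def test_identity_series_all_ones(self):
        series = BinnedSeries(np.arange(-5, 0, dtype=float), np.full(5, 7.7))
        nser = normalize_to_pretreatment(series, (-5, 0))
        np.testing.assert_allclose(nser.values, 1.0)
        assert nser.baseline_p95 == pytest.approx(1.0)

    def test_p95_matches_sort_interp_oracle(self, rng):
        for _ in range(100):
            vals = rng.uniform(0.5, 10.0, size=15)
            series = BinnedSeries(np.arange(-15, 0, dtype=float), vals)
            nser = normalize_to_pretreatment(series, (-15, 0))
            expected = percentile_oracle(vals / vals.mean())
            assert nser.baseline_p95 == pytest.approx(expected, rel=1e-12)

    def test_degenerate_baseline_rejected(self):
        series = BinnedSeries(np.arange(-3, 0, dtype=float), np.zeros(3))
        with pytest.raises(ValueError, match="degenerate"):
            normalize_to_pretreatment(series, (-3, 0))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=4, max_size=40))
    def test_baseline_mean_exactly_one(self, vals):
        n = len(vals)
        series = BinnedSeries(np.arange(-n, 0, dtype=float), vals)
        nser = normalize_to_pretreatment(series, (-n, 0))
        assert abs(nser.values.mean() - 1.0) < 1e-9


class TestDisplayScale:
    def make(self):
        starts = np.arange(-4, 4, dtype=float)
        vals = np.array([1.0, 1.1, 0.9, 1.0, 4.0, 2.0, 0.5, 0.25])
        series = BinnedSeries(starts, vals)
        return normalize_to_pretreatment(series, (-4, 0))

    def test_scales_by_window_max(self):
        nser = self.make()
        scaled = display_scale(nser, (-4, 4))
        factor = np.max(np.abs(nser.values))
        assert scaled.display_scale_factor == pytest.approx(factor)
        np.testing.assert_allclose(scaled.values, nser.values / factor)

    def test_idempotent_after_first_application(self):
        once = display_scale(self.make(), (-4, 4))
        twice = display_scale(once, (-4, 4))
        np.testing.assert_allclose(twice.values, once.values)
        assert twice.display_scale_factor == pytest.approx(once.display_scale_factor)

    def test_deviation_calls_invariant_to_scaling(self):
        nser = self.make()
        scaled = display_scale(nser, (-4, 4))
        rep = detect_significant_deviation(nser)
        rep_scaled = detect_significant_deviation(scaled)
        np.testing.assert_array_equal(rep.below_p95, rep_scaled.below_p95)
        np.testing.assert_array_equal(rep.above_p95, rep_scaled.above_p95)
        assert rep.suppression_onset_min == rep_scaled.suppression_onset_min


def onset_oracle(starts, values, p95):
    """Brute-force scan: latest run of below-threshold bins reaching the end,
    clipped to the post-treatment region."""
    post = [i for i, s in enumerate(starts) if s >= 0]
    if not post or not values[post[-1]] < p95:
        return None
    onset_idx = post[-1]
    for i in reversed(post):
        if values[i] < p95:
            onset_idx = i
        else:
            break
    return starts[onset_idx]


def make_normalized(starts, values, p95):
    base = BinnedSeries(np.asarray(starts, float), np.asarray(values, float))
    return NormalizedSeries(
        raw=base, values=np.asarray(values, float),
        baseline_window_min=(starts[0], 0.0), baseline_mean=1.0, baseline_p95=p95,
    )


class TestDeviationDetection:
    def test_immediate_persistent_drop_onset_one(self):
        starts = np.arange(-3, 6, dtype=float)
        vals = [1.0, 1.0, 1.0, 1.05, 0.3, 0.2, 0.2, 0.1, 0.1]
        rep = detect_significant_deviation(make_normalized(starts, vals, 1.02))
        assert rep.suppression_onset_min == 1.0

    def test_relapse_moves_onset_to_final_run(self):
        starts = np.arange(-2, 8, dtype=float)
        vals = [1.0, 1.0, 1.1, 0.3, 0.3, 0.3, 1.5, 0.2, 0.2, 0.2]
        rep = detect_significant_deviation(make_normalized(starts, vals, 1.02))
        assert rep.suppression_onset_min == 5.0

    def test_flat_series_no_onset(self):
        starts = np.arange(-3, 4, dtype=float)
        rep = detect_significant_deviation(make_normalized(starts, np.ones(7), 1.0))
        assert rep.suppression_onset_min is None
        assert not rep.above_p95.any()

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            n_pre, n_post = rng.integers(2, 6), rng.integers(1, 10)
            starts = np.arange(-n_pre, n_post, dtype=float)
            vals = rng.uniform(0.0, 2.0, size=starts.size)
            p95 = rng.uniform(0.5, 1.5)
            rep = detect_significant_deviation(make_normalized(starts, vals, p95))
            assert rep.suppression_onset_min == onset_oracle(starts, vals, p95)


class TestSpectrogram:
    def make_rec(self, x, fs=500.0):
        return EcogRecording(
            grid=ElectrodeGrid(n_rows=1, n_cols=1), sample_rate_hz=fs, samples=x[None, :]
        )

    def test_baseline_rows_average_one(self, rng):
        x = rng.normal(0, 10, size=30 * 500)
        spec = spectrogram_normalized(self.make_rec(x), 0, (0.0, 30.0))
        row_means = spec.power.mean(axis=1)
        np.testing.assert_allclose(row_means[1:], 1.0, rtol=1e-9)

    def test_amplitude_doubling_is_6db(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        amp = np.where(t < 30, 10.0, 20.0)
        x = amp * np.sin(2 * np.pi * 25.0 * t)
        spec = spectrogram_normalized(self.make_rec(x), 0, (0.0, 29.0))
        f_idx = np.argmin(np.abs(spec.frequencies_hz - 25.0))
        late = spec.times_s > 32
        db = 10 * np.log10(spec.power[f_idx, late]).mean()
        assert db == pytest.approx(6.02, abs=0.3)

    def test_windowed_parseval(self, rng):
        fs = 500.0
        x = rng.normal(0, 3, size=int(20 * fs))
        spec = spectrogram_normalized(
            self.make_rec(x), 0, (0.0, 20.0), window="boxcar", overlap=0.0
        )
        # with a boxcar window and 'spectrum' scaling, the one-sided power
        # spectrum sums to the segment mean square
        nper = int(fs)
        for j, tc in enumerate(spec.times_s[:5]):
            i0 = int(round((tc - 0.5) * fs))
            seg = x[i0 : i0 + nper]
            assert np.sum(spec.power_raw[:, j]) == pytest.approx(
                np.mean(seg**2), rel=1e-6
            )

    def test_baseline_shorter_than_window_rejected(self, rng):
        x = rng.normal(size=5000)
        with pytest.raises(ValueError, match="baseline window"):
            spectrogram_normalized(self.make_rec(x), 0, (100.0, 101.0))
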