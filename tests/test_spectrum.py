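import numpy as np
import pytest

from pyzapline.core import CleaningConfig, Recording
from pyzapline.errors import (
    EmptySearchRangeError,
    ResolutionTooCoarseError,
    WindowOutOfRangeError,
    WindowTooLongError,
)
from pyzapline.spectrum import (
    SpectrumEstimate,
    center_power,
    chunk_log_spectrum,
    detect_chunk_peak,
    detect_next_noise_frequency,
    fine_threshold,
    welch_log_spectrum,
)
from pyzapline.synthetic import pink_background

CFG = CleaningConfig()


def _flat_spectrum(level=0.0, fmax=125.0, df=1 / 30):
    freqs = np.arange(0.0, fmax + df / 2, df)
    curve = np.full(freqs.size, level)
    return SpectrumEstimate(freqs, curve[None, :], curve)


class TestWelch:
    def test_white_noise_spectrum_is_flat(self, rng):
        rec = Recording(rng.standard_normal((2, 15000)), 250.0)
        spec = welch_log_spectrum(rec, 250)  # ~119 averaged segments
        band = (spec.freqs >= 1) & (spec.freqs <= 100)
        assert np.ptp(spec.mean_log_psd[band]) < 3.0

    def test_sinusoid_peaks_at_its_frequency(self):
        srate, n = 250.0, 25000
        t = np.arange(n) / srate
        rec = Recording(np.tile(np.sin(2 * np.pi * 50.0 * t), (2, 1)), srate)
        spec = welch_log_spectrum(rec, 2500)
        assert spec.freqs[np.argmax(spec.mean_log_psd)] == pytest.approx(50.0, abs=0.1)

    def test_identical_channels_mean_equals_channel(self, rng):
        x = rng.standard_normal(5000)
        rec = Recording(np.vstack([x, x]), 250.0)
        spec = welch_log_spectrum(rec, 500)
        np.testing.assert_allclose(spec.mean_log_psd, spec.log_psd[0])

    def test_geometric_mean_below_arithmetic_mean(self, rng):
        rec = Recording(rng.standard_normal((4, 5000)) * [[1], [2], [5], [10]], 250.0)
        spec = welch_log_spectrum(rec, 500)
        linear = 10.0 ** (spec.log_psd / 10.0)
        arith = 10.0 * np.log10(linear.mean(axis=0))
        assert np.all(spec.mean_log_psd <= arith + 1e-9)

    def test_window_longer_than_data_rejected(self, rng):
        rec = Recording(rng.standard_normal((2, 100)), 250.0)
        with pytest.raises(WindowTooLongError):
            welch_log_spectrum(rec, 101)

    def test_bin_spacing_is_srate_over_window(self, rng):
        rec = Recording(rng.standard_normal((2, 7500)), 250.0)
        assert welch_log_spectrum(rec, 7500).df == pytest.approx(250.0 / 7500)


class TestCenterPower:
    def test_flat_curve(self):
        spec = _flat_spectrum(-10.0)
        assert center_power(spec.mean_log_psd, spec.freqs, 50.0, 6.0) == -10.0

    def test_center_bin_excluded(self):
        spec = _flat_spectrum(0.0)
        curve = spec.mean_log_psd.copy()
        curve[np.argmin(np.abs(spec.freqs - 50.0))] = 50.0
        assert center_power(curve, spec.freqs, 50.0, 6.0) == 0.0

    def test_linear_ramp_gives_midpoint_value(self):
        spec = _flat_spectrum()
        curve = 0.3 * spec.freqs  # linear in frequency
        mid = 0.3 * 50.0
        assert center_power(curve, spec.freqs, 50.0, 6.0) == pytest.approx(mid, abs=1e-6)

    def test_window_out_of_range(self):
        spec = _flat_spectrum()
        with pytest.raises(WindowOutOfRangeError):
            center_power(spec.mean_log_psd, spec.freqs, 1.0, 6.0)


def _brute_quantile(values, q):
    """Independent linear-interpolation quantile on sorted values."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = q * (v.size - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, v.size - 1)
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


class TestFineThreshold:
    def test_flat_curve_degenerates(self):
        spec = _flat_spectrum(-5.0)
        thr = fine_threshold(spec.mean_log_psd, spec.freqs, 50.0, CFG)
        assert thr.deviation == 0.0
        assert thr.upper == thr.lower == thr.center_power == -5.0

    def test_matches_brute_force_quantiles_on_ramp(self):
        # dense grid whose flanking thirds each span a ~[-1, 0] ramp
        spec = _flat_spectrum(df=0.005)
        curve = -np.abs((spec.freqs - 50.0)) / 3.0  # v-shape: thirds ramp over [-1,-1/3]
        thr = fine_threshold(curve, spec.freqs, 50.0, CFG)
        idx = np.nonzero((spec.freqs >= 47.0) & (spec.freqs <= 53.0))[0]
        third = idx.size // 3
        left, right = curve[idx[:third]], curve[idx[-third:]]
        center = np.concatenate([left, right]).mean()
        deviation = center - 0.5 * (_brute_quantile(left, 0.05) + _brute_quantile(right, 0.05))
        assert thr.deviation == pytest.approx(deviation, rel=1e-9)
        assert thr.upper == pytest.approx(center + 2 * deviation, rel=1e-9)

    def test_zero_multiplier_collapses_bounds(self, rng):
        spec = _flat_spectrum()
        curve = rng.standard_normal(spec.freqs.size)
        cfg = CleaningConfig(freq_detect_mult_fine=0.0)
        thr = fine_threshold(curve, spec.freqs, 50.0, cfg)
        assert thr.upper == thr.lower == thr.center_power

    def test_upper_nondecreasing_in_multiplier(self, rng):
        spec = _flat_spectrum()
        curve = rng.standard_normal(spec.freqs.size)
        uppers = [
            fine_threshold(
                curve, spec.freqs, 50.0, CleaningConfig(freq_detect_mult_fine=m)
            ).upper
            for m in (0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(uppers) >= 0)


class TestCoarseDetection:
    def test_flat_spectrum_yields_none(self):
        spec = _flat_spectrum()
        assert detect_next_noise_frequency(spec, 17.0, 99.0, CFG) is None

    def test_single_outlier_bin_found(self):
        spec = _flat_spectrum()
        i = np.argmin(np.abs(spec.freqs - 50.0))
        spec.mean_log_psd[i] = 5.0
        f = detect_next_noise_frequency(spec, 17.0, 99.0, CFG)
        assert f == pytest.approx(spec.freqs[i])

    def test_peak_below_minfreq_ignored(self):
        spec = _flat_spectrum()
        spec.mean_log_psd[np.argmin(np.abs(spec.freqs - 10.0))] = 5.0
        assert detect_next_noise_frequency(spec, 17.0, 99.0, CFG) is None

    def test_translation_equivariance(self):
        hits = []
        for f0 in (40.0, 43.0, 61.0):
            spec = _flat_spectrum()
            spec.mean_log_psd[np.argmin(np.abs(spec.freqs - f0))] = 6.0
            hits.append(detect_next_noise_frequency(spec, 17.0, 99.0, CFG))
        assert hits == pytest.approx([40.0, 43.0, 61.0], abs=1e-9)

    def test_region_peak_returned_not_first_crossing(self):
        # ramp up to a maximum: detection stops at first crossing but reports
        # the region's maximum
        spec = _flat_spectrum()
        sel = np.abs(spec.freqs - 50.0) < 0.5
        spec.mean_log_psd[sel] = 5.0
        top = np.argmin(np.abs(spec.freqs - 50.2))
        spec.mean_log_psd[top] = 8.0
        f = detect_next_noise_frequency(spec, 17.0, 99.0, CFG)
        assert f == pytest.approx(spec.freqs[top])

    def test_raising_threshold_never_creates_detection(self):
        spec = _flat_spectrum()
        spec.mean_log_psd[np.argmin(np.abs(spec.freqs - 50.0))] = 5.0
        strict = CleaningConfig(coarse_freq_detect_power_diff=100.0)
        assert detect_next_noise_frequency(spec, 17.0, 99.0, strict) is None

    def test_empty_search_range_rejected(self):
        spec = _flat_spectrum()
        with pytest.raises(EmptySearchRangeError):
            detect_next_noise_frequency(spec, 99.0, 17.0, CFG)


class TestChunkPeak:
    def test_planted_peak_recovered(self, rng):
        srate, dur = 250.0, 60.0
        bg = pink_background(4, dur, srate, 11)
        t = np.arange(bg.n_samples) / srate
        data = bg.data + 3.0 * np.outer(
            rng.standard_normal(4), np.sin(2 * np.pi * 50.03 * t)
        )
        spec = chunk_log_spectrum(Recording(data, srate))
        f_peak, present = detect_chunk_peak(spec, 50.0, CFG)
        assert present
        assert abs(f_peak - 50.03) <= spec.df

    def test_flat_spectrum_not_flagged(self):
        spec = _flat_spectrum()
        f_peak, present = detect_chunk_peak(spec, 50.0, CFG)
        assert not present

    def test_false_positive_rate_on_pink_noise(self):
        hits = 0
        for seed in range(20):
            chunk = pink_background(4, 60.0, 250.0, 500 + seed)
            _, present = detect_chunk_peak(chunk_log_spectrum(chunk), 50.0, CFG)
            hits += present
        assert hits <= 1  # <= 5% false positives

    def test_too_coarse_resolution_rejected(self):
        freqs = np.arange(0.0, 125.0, 0.5)  # 0.5 Hz bins: none within +-0.05
        freqs = freqs + 0.17
        spec = SpectrumEstimate(freqs, np.zeros((1, freqs.size)), np.zeros(freqs.size))
        with pytest.raises(ResolutionTooCoarseError):
            detect_chunk_peak(spec, 50.0, CFG)
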