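import numpy as np
import pytest

from pyzapline.core import CleaningConfig, Recording
from pyzapline.errors import (
    ChunkShorterThanNfftError,
    DegenerateCovarianceError,
    FrequencyTooHighError,
    NRemoveOutOfRangeError,
)
from pyzapline.spectrum import welch_log_spectrum
from pyzapline.synthetic import pink_background
from pyzapline.zapline import (
    bias_covariances,
    decompose_chunk,
    default_nfft,
    dss_decompose,
    remove_components,
    smooth_split,
    zapline_chunk,
)

CFG = CleaningConfig()
SRATE = 250.0


def _noisy_chunk(seed=5, f=50.0, amp=2.0, dur=60.0, n_ch=8):
    """Pink background plus one spatially fixed sinusoid; returns all parts."""
    bg = pink_background(n_ch, dur, SRATE, seed)
    rng = np.random.default_rng(seed + 1)
    topo = rng.standard_normal(n_ch)
    t = np.arange(bg.n_samples) / SRATE
    sine = amp * np.sin(2 * np.pi * f * t + 0.7)
    chunk = Recording(bg.data + np.outer(topo, sine), SRATE)
    return chunk, bg, topo, sine


def _band_power(rec, f, half=0.05):
    spec = welch_log_spectrum(rec, min(7500, rec.n_samples))
    band = (spec.freqs >= f - half) & (spec.freqs <= f + half)
    return spec.mean_log_psd[band].mean()


class TestSmoothSplit:
    def test_constant_signal_is_all_smooth(self):
        chunk = Recording(np.full((2, 5000), 3.7), SRATE)
        smoothed, residual = smooth_split(chunk, 50.0)
        np.testing.assert_allclose(smoothed.data, chunk.data, rtol=1e-12)
        np.testing.assert_allclose(residual.data, 0.0, atol=1e-10)

    def test_integer_period_sinusoid_goes_to_residual(self):
        t = np.arange(5000) / SRATE
        x = np.sin(2 * np.pi * 50.0 * t)  # period = 5 samples, integer
        chunk = Recording(np.tile(x, (2, 1)), SRATE)
        smoothed, residual = smooth_split(chunk, 50.0)
        interior = slice(100, -100)
        rms_in = np.sqrt(np.mean(chunk.data[:, interior] ** 2))
        rms_smooth = np.sqrt(np.mean(smoothed.data[:, interior] ** 2))
        assert rms_smooth < 1e-6 * rms_in

    def test_complement_identity(self, rng):
        chunk = Recording(rng.standard_normal((3, 4000)), SRATE)
        smoothed, residual = smooth_split(chunk, 47.3)  # fractional period
        recon = smoothed.data + residual.data
        scale = np.abs(chunk.data).max()
        assert np.abs(recon - chunk.data).max() < 1e-12 * scale

    def test_harmonic_also_suppressed(self):
        t = np.arange(5000) / SRATE
        x = np.sin(2 * np.pi * 100.0 * t)  # first harmonic of 50 Hz
        chunk = Recording(np.tile(x, (2, 1)), SRATE)
        smoothed, _ = smooth_split(chunk, 50.0)
        interior = slice(100, -100)
        assert np.sqrt(np.mean(smoothed.data[:, interior] ** 2)) < 1e-6

    def test_frequency_above_nyquist_rejected(self):
        chunk = Recording(np.zeros((2, 1000)), SRATE)
        with pytest.raises(FrequencyTooHighError):
            smooth_split(chunk, 130.0)


class TestBiasCovariances:
    def test_white_noise_energy_fraction(self, rng):
        rec = Recording(rng.standard_normal((4, 60000)), SRATE)
        nfft = 256
        C0, C1 = bias_covariances(rec, 50.0, nfft)
        k = np.unique(np.round(np.arange(1, 3) * 50.0 * nfft / SRATE)).size
        expected = 2 * k / nfft  # kept full-spectrum bins / nfft
        frac = np.trace(C1) / np.trace(C0)
        assert frac == pytest.approx(expected, rel=0.2)

    def test_rank_one_source_direction_recovered(self, rng):
        n_ch = 6
        topo = rng.standard_normal(n_ch)
        t = np.arange(30000) / SRATE
        data = np.outer(topo, np.sin(2 * np.pi * 50.0 * t))
        data += 0.01 * rng.standard_normal(data.shape)
        _, C1 = bias_covariances(Recording(data, SRATE), 50.0, 256)
        w, V = np.linalg.eigh(C1)
        lead = V[:, -1]
        cos = np.dot(lead, topo) / np.linalg.norm(topo)
        assert abs(cos) > 0.99

    def test_zero_input_gives_zero_covariances(self):
        rec = Recording(np.zeros((3, 2000)), SRATE)
        C0, C1 = bias_covariances(rec, 50.0, 256)
        assert not np.any(C0) and not np.any(C1)

    def test_chunk_shorter_than_nfft_rejected(self):
        rec = Recording(np.zeros((3, 200)), SRATE)
        with pytest.raises(ChunkShorterThanNfftError):
            bias_covariances(rec, 50.0, 256)

    def test_default_nfft_power_of_two(self):
        assert default_nfft(250.0, 10**6) == 256
        assert default_nfft(250.0, 100) == 100


class TestDss:
    def test_equal_covariances_give_unit_scores(self, rng):
        A = rng.standard_normal((5, 5))
        C0 = A @ A.T + 5 * np.eye(5)
        dss = dss_decompose(C0, C0)
        np.testing.assert_allclose(dss.scores, 1.0, rtol=1e-8)

    def test_rank_one_bias_with_identity_baseline(self, rng):
        w = rng.standard_normal(6)
        dss = dss_decompose(np.eye(6), np.outer(w, w))
        assert dss.scores[0] == pytest.approx(np.dot(w, w), rel=1e-9)
        np.testing.assert_allclose(dss.scores[1:], 0.0, atol=1e-9)

    def test_nkeep_truncates_dimensions(self, rng):
        A = rng.standard_normal((30, 30))
        C0 = A @ A.T
        dss = dss_decompose(C0, C0, nkeep=5)
        assert dss.n_effective <= 5

    def test_scores_sorted_descending(self, rng):
        A = rng.standard_normal((8, 100))
        B = rng.standard_normal((8, 100))
        dss = dss_decompose(np.cov(A), np.cov(B))
        assert np.all(np.diff(dss.scores) <= 1e-12)

    def test_components_uncorrelated_wrt_baseline(self, rng):
        A = rng.standard_normal((6, 500))
        C0 = np.cov(A)
        B = rng.standard_normal((6, 500))
        dss = dss_decompose(C0, np.cov(B))
        gram = dss.rotation.T @ C0 @ dss.rotation
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_zero_baseline_rejected(self):
        with pytest.raises(DegenerateCovarianceError):
            dss_decompose(np.zeros((4, 4)), np.eye(4))


class TestRemoveComponents:
    def test_zero_removal_is_identity(self, rng):
        chunk, *_ = _noisy_chunk()
        _, residual, dss = decompose_chunk(chunk, 50.0, CFG)
        out = remove_components(residual, dss, 0)
        np.testing.assert_array_equal(out.data, residual.data)

    def test_planted_noise_attenuated_20db(self):
        chunk, bg, topo, sine = _noisy_chunk()
        _, residual, dss = decompose_chunk(chunk, 50.0, CFG)
        out = remove_components(residual, dss, 1)
        assert _band_power(residual, 50.0) - _band_power(out, 50.0) >= 20.0

    def test_out_of_range_rejected(self):
        chunk, *_ = _noisy_chunk()
        _, residual, dss = decompose_chunk(chunk, 50.0, CFG)
        with pytest.raises(NRemoveOutOfRangeError):
            remove_components(residual, dss, dss.n_effective + 1)


class TestZaplineChunk:
    def test_zero_removal_returns_chunk_exactly(self):
        chunk, *_ = _noisy_chunk()
        clean, scores = zapline_chunk(chunk, 50.0, 0, CFG)
        np.testing.assert_array_equal(clean.data, chunk.data)

    def test_conservation_of_parts(self):
        chunk, *_ = _noisy_chunk()
        smoothed, residual, dss = decompose_chunk(chunk, 50.0, CFG)
        denoised = remove_components(residual, dss, 2)
        removed = residual.data - denoised.data
        clean = smoothed.data + denoised.data
        scale = np.abs(chunk.data).max()
        assert np.abs(clean + removed - chunk.data).max() < 1e-10 * scale

    def test_noise_band_power_monotone_in_nremove(self):
        chunk, *_ = _noisy_chunk()
        powers = [
            _band_power(zapline_chunk(chunk, 50.0, n, CFG)[0], 50.0)
            for n in range(0, 4)
        ]
        assert np.all(np.diff(powers) <= 1e-9)

    def test_rank_preserved(self):
        chunk, *_ = _noisy_chunk()
        clean, _ = zapline_chunk(chunk, 50.0, 1, CFG)
        sv = np.linalg.svd(clean.data, compute_uv=False)
        assert sv[-1] > 1e-8 * sv[0]

    def test_matches_sinusoid_regression_oracle(self):
        # exactly one spatially fixed sinusoid: removing one component must
        # agree with analytically regressing the sinusoid out of each channel
        chunk, bg, topo, sine = _noisy_chunk(amp=3.0, n_ch=24)
        clean, _ = zapline_chunk(chunk, 50.0, 1, CFG)
        t = np.arange(chunk.n_samples) / SRATE
        design = np.column_stack(
            [np.sin(2 * np.pi * 50.0 * t), np.cos(2 * np.pi * 50.0 * t)]
        )
        coef, *_ = np.linalg.lstsq(design, chunk.data.T, rcond=None)
        oracle = chunk.data - (design @ coef).T
        rms_diff = np.sqrt(np.mean((clean.data - oracle) ** 2))
        rms_chunk = np.sqrt(np.mean(chunk.data**2))
        assert rms_diff < 0.05 * rms_chunk
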