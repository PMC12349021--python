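"""The DE / band-power signal chain against closed forms and FFT oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mbmstfnet.features import (
    BandSpec, DEFAULT_BANDS, average_reference, band_power, baseline_correct,
    butter_bandpass, differential_entropy, extract_slice_features,
    extract_trial_features, hanning_window, slice_signal, welch_psd,
    SliceFeatures,
)

FS = 128.0
LOG_2PIE = np.log(2 * np.pi * np.e)


def _sine(freq, n=64, fs=FS, amp=1.0, phase=0.3):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


# --------------------------------------------------------------- entropy
class TestDifferentialEntropy:
    def test_closed_form_unit_variance(self):
        seg = np.array([-1.0, 1.0]) / np.sqrt(2)  # sample variance exactly 1
        assert differential_entropy(seg) == pytest.approx(0.5 * LOG_2PIE,
                                                          rel=1e-12)

    def test_zero_entropy_variance(self):
        var = 1.0 / (2 * np.pi * np.e)
        seg = np.array([-1.0, 1.0]) * np.sqrt(var / 2)
        assert differential_entropy(seg) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(a=st.floats(0.1, 50.0), seed=st.integers(0, 1000))
    def test_scaling_law(self, a, seed):
        """DE(a x) - DE(x) = ln a for any non-constant segment."""
        x = np.random.default_rng(seed).standard_normal(64)
        got = differential_entropy(a * x) - differential_entropy(x)
        assert got == pytest.approx(np.log(a), rel=1e-9, abs=1e-11)

    def test_constant_segment_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            differential_entropy(np.ones(10))


# --------------------------------------------------------------- windows
class TestHanning:
    def test_endpoints_zero_and_symmetry(self):
        w = hanning_window(64)
        assert w[0] == 0.0 and w[-1] == 0.0
        assert np.allclose(w, w[::-1], atol=1e-15)

    def test_matches_direct_formula(self):
        w = hanning_window(64)
        # oracle: evaluate the raised-cosine expression independently
        expected = 0.5 * (1 - np.cos(2 * np.pi * 31 / 63))
        assert w[31] == pytest.approx(expected, rel=1e-15)
        assert np.allclose(w, np.hanning(64), atol=1e-15)

    def test_too_short(self):
        with pytest.raises(ValueError):
            hanning_window(1)


# ------------------------------------------------------------------ welch
class TestWelchPSD:
    def test_zero_segment(self):
        spec = welch_psd(np.zeros(64), FS)
        assert np.all(spec.psd == 0.0)
        assert spec.psd.shape == (65,)

    def test_delta_f_is_one_hz(self):
        spec = welch_psd(np.zeros(64), FS, nfft=128)
        assert spec.delta_f == 1.0
        assert spec.nfft == 128

    def test_peak_at_sine_frequency(self):
        spec = welch_psd(_sine(10.0), FS)
        peak = spec.freqs[np.argmax(spec.psd)]
        assert abs(peak - 10.0) <= spec.delta_f

    def test_matches_independent_fft_oracle(self):
        """Brute-force |FFT|^2 / N_FFT of the tapered, padded window."""
        x = np.random.default_rng(5).standard_normal(64)
        spec = welch_psd(x, FS, nfft=128)
        xw = np.zeros(128)
        xw[:64] = x * (0.5 * (1 - np.cos(2 * np.pi * np.arange(64) / 63)))
        full = np.abs(np.fft.fft(xw)) ** 2 / 128
        assert np.allclose(spec.psd, full[:65], rtol=1e-10, atol=1e-12)

    def test_nfft_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(64), FS, nfft=32)


class TestBandPower:
    def test_zero_spectrum(self):
        spec = welch_psd(np.zeros(64), FS)
        assert band_power(spec, DEFAULT_BANDS[0]) == 0.0

    def test_alpha_sine_concentration(self):
        spec = welch_psd(_sine(10.0), FS)
        alpha = band_power(spec, BandSpec("alpha", 8, 13))
        total = float(np.sum(spec.psd) * spec.delta_f)
        assert alpha / total >= 0.8

    def test_band_sum_below_total(self):
        spec = welch_psd(np.random.default_rng(0).standard_normal(64), FS)
        total = float(np.sum(spec.psd) * spec.delta_f)
        band_sum = sum(band_power(spec, b) for b in DEFAULT_BANDS)
        # 8/13/30 Hz bins are counted twice at shared edges, hence the slack
        edge = sum(float(spec.psd[int(v)]) for v in (8, 13, 30)) * spec.delta_f
        assert band_sum <= total + edge + 1e-12

    def test_empty_band_rejected(self):
        spec = welch_psd(np.zeros(64), FS)
        with pytest.raises(ValueError):
            band_power(spec, BandSpec("narrow", 10.2, 10.8))

    def test_white_noise_power_proportional_to_bandwidth(self):
        """Average over many noise slices: P_band tracks the bin count."""
        rng = np.random.default_rng(42)
        slices = rng.standard_normal((1200, 64))
        powers = np.zeros(len(DEFAULT_BANDS))
        for i, band in enumerate(DEFAULT_BANDS):
            for s in range(0, 1200, 200):
                spec_block = slices[s:s + 200]
                vals = [band_power(welch_psd(x, FS), band)
                        for x in spec_block]
                powers[i] += np.mean(vals)
        bins = np.array([5, 6, 18, 16], dtype=float)  # inclusive edges
        ratio = (powers / powers.sum()) / (bins / bins.sum())
        assert np.all(np.abs(ratio - 1) < 0.1)


# ------------------------------------------------------------- filtering
class TestButterworth:
    def test_zero_in_zero_out(self):
        out = butter_bandpass(np.zeros(512), DEFAULT_BANDS[1], FS)
        assert np.allclose(out, 0.0)

    def test_passband_gain_near_unity(self):
        x = _sine(10.0, n=1280)
        out = butter_bandpass(x, BandSpec("alpha", 8, 13), FS)
        core = slice(256, -256)  # trim filter edge transients
        ratio = out[core].var() / x[core].var()
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_attenuation(self):
        x = _sine(10.0, n=1280)
        out = butter_bandpass(x, BandSpec("gamma", 30, 45), FS)
        assert out[256:-256].var() < 0.01 * x[256:-256].var()

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            butter_bandpass(np.zeros(512), BandSpec("bad", 30, 70), FS)


class TestAverageReference:
    def test_channel_sum_zeroed(self, rng):
        frame = rng.standard_normal((32, 64))
        out = average_reference(frame)
        assert np.allclose(out.sum(axis=0), 0.0, atol=1e-12)

    def test_identical_channels_vanish(self):
        frame = np.tile(np.arange(10.0), (4, 1))
        assert np.allclose(average_reference(frame), 0.0)

    def test_two_channel_arithmetic(self):
        assert np.allclose(average_reference(np.array([[1.0], [3.0]])),
                           [[-1.0], [1.0]])

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            average_reference(np.ones((1, 10)))


class TestSlicing:
    def test_sixty_seconds_gives_120_slices_of_64(self):
        trial = np.zeros((32, int(60 * FS)))
        frames = slice_signal(trial, FS, 0.5)
        assert frames.shape == (120, 32, 64)

    def test_remainder_discarded(self):
        frames = slice_signal(np.zeros((2, 130)), FS, 0.5)
        assert frames.shape == (2, 2, 64)

    def test_window_longer_than_trial(self):
        with pytest.raises(ValueError):
            slice_signal(np.zeros((2, 63)), FS, 0.5)


# --------------------------------------------------------- slice features
class TestSliceFeatures:
    def test_shapes(self, rng):
        frame = rng.standard_normal((32, 64))
        feats = extract_slice_features(frame, FS)
        assert feats.de.shape == (4, 32) and feats.bp.shape == (4, 32)

    def test_beta_sine_dominates_beta_row(self):
        frame = np.tile(_sine(20.0), (32, 1))
        frame += np.random.default_rng(0).normal(0, 1e-3, frame.shape)
        feats = extract_slice_features(frame, FS)
        assert np.all(feats.bp[2] > feats.bp[[0, 1, 3]].max(axis=0))

    def test_amplitude_scaling_laws(self, rng):
        frame = rng.standard_normal((32, 64))
        f1 = extract_slice_features(frame, FS)
        f2 = extract_slice_features(2 * frame, FS)
        assert np.allclose(f2.de - f1.de, np.log(2), atol=1e-9)
        assert np.allclose(f2.bp, 4 * f1.bp, rtol=1e-9)


class TestBaselineCorrection:
    def _feats(self, de, bp):
        return SliceFeatures(de=de, bp=bp)

    def test_identical_baseline_zeroes_features(self, rng):
        mat = rng.standard_normal((4, 32))
        corrected = baseline_correct([self._feats(mat, mat**2)],
                                     [self._feats(mat, mat**2)] * 6)
        assert np.allclose(corrected[0].de, 0.0)
        assert np.allclose(corrected[0].bp, 0.0)

    def test_three_second_baseline_is_six_slices(self, tiny_recording):
        feats = extract_trial_features(tiny_recording.data[0],
                                       tiny_recording.fs)
        n_base = int(tiny_recording.fs * tiny_recording.baseline_sec) // 64
        assert n_base == 6
        assert len(feats) == 6 + int(8.0 / 0.5)

    def test_correction_is_pure_shift(self, rng):
        trial = [self._feats(rng.standard_normal((4, 32)),
                             rng.random((4, 32))) for _ in range(5)]
        base = [self._feats(rng.standard_normal((4, 32)),
                            rng.random((4, 32))) for _ in range(6)]
        out = baseline_correct(trial, base)
        var_before = np.var([f.de for f in trial], axis=0)
        var_after = np.var([f.de for f in out], axis=0)
        assert np.allclose(var_before, var_after, rtol=1e-10)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct([], [])
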