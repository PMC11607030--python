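"""Transfer functions, relative TFs, fractional-octave smoothing, band averages."""

import numpy as np
import pytest

from laparosound.audio import ImpulseResponse
from laparosound.transfer import (RelativeTF, band_average, ir_from_tf,
                                  relative_tf, smooth_fractional_octave,
                                  tf_from_ir)


def _delta(fs=48_000, gain=1.0, n=64):
    h = np.zeros(n)
    h[0] = gain
    return ImpulseResponse(samples=h, fs=fs)


class TestTfFromIr:
    def test_unit_impulse_is_flat_0db(self):
        tf = tf_from_ir(_delta())
        np.testing.assert_allclose(np.abs(tf.values), 1.0, atol=1e-12)

    def test_scalar_gain(self):
        tf = tf_from_ir(_delta(gain=0.5))
        np.testing.assert_allclose(tf.magnitude_db(), -6.0206, atol=1e-3)

    def test_two_tap_closed_form(self):
        """|H(f)| = 2|cos(pi f / fs)| for the FIR [1, 1]; sqrt(2) at fs/4."""
        ir = ImpulseResponse(samples=[1.0, 1.0], fs=48_000)
        tf = tf_from_ir(ir, n_fft=8)
        i = np.argmin(np.abs(tf.freqs_hz - 12_000))
        assert tf.freqs_hz[i] == 12_000
        assert np.abs(tf.values[i]) == pytest.approx(np.sqrt(2), rel=1e-12)
        expected = 2 * np.abs(np.cos(np.pi * tf.freqs_hz / 48_000))
        np.testing.assert_allclose(np.abs(tf.values), expected, atol=1e-12)

    def test_nfft_too_small_rejected(self):
        with pytest.raises(ValueError, match="n_fft"):
            tf_from_ir(_delta(n=128), n_fft=64)

    def test_inverse_transform_round_trip(self, tube_ir):
        tf = tf_from_ir(tube_ir)
        recovered = ir_from_tf(tf)
        padded = np.zeros(tf.n_fft)
        padded[: len(tube_ir)] = tube_ir.samples
        err = np.linalg.norm(recovered - padded) / np.linalg.norm(padded)
        assert err <= 1e-10


class TestRelativeTf:
    def test_self_comparison_is_exactly_zero(self, tube_ir):
        tf = tf_from_ir(tube_ir)
        rtf = relative_tf(tf, tf)
        finite = np.isfinite(rtf.delta_db)
        assert np.all(rtf.delta_db[finite] == 0.0)

    def test_scalar_quotient(self):
        a, b = tf_from_ir(_delta(gain=0.5)), tf_from_ir(_delta(gain=1.0))
        rtf = relative_tf(a, b)
        np.testing.assert_allclose(rtf.delta_db, -6.0206, atol=1e-3)

    def test_antisymmetry(self, tube_ir, dual_channel_ir):
        ha, hb = tf_from_ir(tube_ir), tf_from_ir(dual_channel_ir)
        ab, ba = relative_tf(ha, hb), relative_tf(hb, ha)
        both = np.isfinite(ab.delta_db) & np.isfinite(ba.delta_db)
        np.testing.assert_allclose(ab.delta_db[both], -ba.delta_db[both], atol=1e-9)

    def test_tube_matches_designed_gain_at_1khz(self, tube_ir, reference_ir):
        from laparosound.synth import default_channel_profiles

        rtf = relative_tf(tf_from_ir(tube_ir), tf_from_ir(reference_ir))
        i = np.argmin(np.abs(rtf.freqs_hz - 1000))
        designed = default_channel_profiles()["tube"].gain_db_at(
            np.array([rtf.freqs_hz[i]]))[0]
        assert rtf.delta_db[i] == pytest.approx(designed, abs=2.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            relative_tf(tf_from_ir(_delta(n=64)), tf_from_ir(_delta(n=256)))


def _log_grid_rtf(values, n=400):
    freqs = np.logspace(np.log10(50), np.log10(20_000), n)
    return RelativeTF(freqs_hz=freqs, delta_db=values)


class TestFractionalOctaveSmoothing:
    def test_constant_curve_unchanged(self):
        rtf = _log_grid_rtf(np.full(400, -9.4))
        out = smooth_fractional_octave(rtf)
        assert out.smoothed
        np.testing.assert_allclose(out.delta_db, -9.4, atol=1e-9)

    def test_log_frequency_ramp_unchanged(self):
        freqs = np.logspace(np.log10(50), np.log10(20_000), 400)
        ramp = -3.0 * np.log2(freqs / 1000.0)
        out = smooth_fractional_octave(RelativeTF(freqs_hz=freqs, delta_db=ramp))
        np.testing.assert_allclose(out.delta_db, ramp, atol=1e-8)

    def test_noise_on_ramp_reduced(self):
        """Per-bin noise on an FFT-style linear grid is at least halved."""
        rng = np.random.default_rng(5)
        freqs = np.linspace(50, 20_000, 2000)  # grid shape tf_from_ir produces
        ramp = -3.0 * np.log2(freqs / 1000.0)
        noisy = ramp + 3.0 * rng.standard_normal(2000)
        out = smooth_fractional_octave(RelativeTF(freqs_hz=freqs, delta_db=noisy))
        rms_before = np.sqrt(np.mean((noisy - ramp) ** 2))
        rms_after = np.sqrt(np.mean((out.delta_db - ramp) ** 2))
        assert rms_after <= 0.5 * rms_before

    def test_double_smoothing_rejected(self):
        out = smooth_fractional_octave(_log_grid_rtf(np.zeros(400)))
        with pytest.raises(ValueError, match="already"):
            smooth_fractional_octave(out)

    def test_too_few_points_rejected(self):
        rtf = RelativeTF(freqs_hz=np.array([100.0, 101.0]),
                         delta_db=np.zeros(2))
        with pytest.raises(ValueError):
            smooth_fractional_octave(rtf)


class TestBandAverage:
    def test_constant_curve(self):
        rtf = _log_grid_rtf(np.full(400, -3.0))
        assert band_average(rtf, 100, 10_000) == pytest.approx(-3.0)

    def test_mean_bounded_by_extremes(self):
        freqs = np.logspace(np.log10(250), np.log10(4000), 401)  # symmetric about 1 kHz
        vals = np.where(freqs < 1000, -10.0, -20.0)
        avg = band_average(RelativeTF(freqs_hz=freqs, delta_db=vals), 500, 2000)
        assert -20.0 < avg < -10.0

    def test_dual_channel_average_attenuation(self, dual_channel_ir, reference_ir):
        """Near-flat insert: 9.4 dB average attenuation over the analysis band."""
        rtf = relative_tf(tf_from_ir(dual_channel_ir), tf_from_ir(reference_ir))
        assert band_average(rtf, 100, 7500) == pytest.approx(-9.4, abs=0.5)

    def test_empty_band_rejected(self):
        rtf = _log_grid_rtf(np.zeros(400))
        with pytest.raises(ValueError):
            band_average(rtf, 30_000, 40_000)
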