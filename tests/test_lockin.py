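"""Digital lock-in: demodulation precision, filters, FFT mode."""

import math

import numpy as np
import pytest

import ulfbis as u


def _tone_block(f, fs, periods, amplitude=1.0, phase=0.0, extra=None):
    n = round(periods * fs / f)
    t = np.arange(n) / fs
    sig = amplitude * np.cos(2 * np.pi * f * t - phase)
    if extra is not None:
        sig = sig + extra(t)
    return u.WaveformBlock(fs=fs, f_exc=f, v_gen=max(amplitude, 1e-9), channels=np.vstack([sig] * 4))


class TestDemodulate:
    def test_instrument_grade_amplitude_and_phase(self, pure_tone_block):
        """Clean 1 kHz cosine, 37.5 kS/s, 100 periods: amplitude within
        1 ppm and phase within 0.01 degrees."""
        ph = u.demodulate(pure_tone_block(), 0)
        assert abs(ph.amplitude - 1.0) * 1e6 < 1.0
        assert abs(math.degrees(ph.phase)) < 0.01

    def test_phase_recovery_quarter_pi(self, pure_tone_block):
        ph = u.demodulate(pure_tone_block(phase_rad=math.pi / 4), 0)
        assert ph.phase == pytest.approx(math.pi / 4, abs=1e-6)

    def test_third_harmonic_does_not_bias_amplitude(self):
        """An equal-amplitude tone at 3x the reference is orthogonal over
        whole periods and leaves the fundamental estimate untouched."""
        f, fs = 1000.0, 37500.0
        block = _tone_block(
            f, fs, 100, extra=lambda t: 1.0 * np.cos(2 * np.pi * 3 * f * t - 0.7)
        )
        ph = u.demodulate(block, 0)
        assert abs(ph.amplitude - 1.0) < 1e-9

    def test_amplitude_invariant_phase_linear_in_reference_phase(self):
        f, fs = 50.0, 5000.0
        block = _tone_block(f, fs, 40, amplitude=0.3, phase=0.4)
        for phi_r in np.linspace(-2.5, 2.5, 7):
            ph = u.demodulate(block, 0, u.ReferenceConfig(fr=f, phi_r=phi_r))
            assert ph.amplitude == pytest.approx(0.3, rel=1e-9)
            assert ph.phase == pytest.approx(0.4, abs=1e-9)

    def test_complex_phasor_roundtrip(self):
        ph = u.Phasor(amplitude=2.0, phase=0.3)
        back = u.Phasor.from_complex(ph.to_complex())
        assert back.amplitude == pytest.approx(2.0)
        assert back.phase == pytest.approx(0.3)

    def test_reference_frequency_mismatch_rejected(self, pure_tone_block):
        with pytest.raises(ValueError):
            u.demodulate(pure_tone_block(), 0, u.ReferenceConfig(fr=999.0))

    def test_less_than_one_period_rejected(self):
        f, fs = 1.0, 1000.0
        t = np.arange(500) / fs  # half a period
        sig = np.cos(2 * np.pi * f * t)
        block = u.WaveformBlock(fs=fs, f_exc=f, v_gen=1.0, channels=np.vstack([sig] * 4))
        with pytest.raises(ValueError):
            u.demodulate(block, 0)

    def test_integration_equals_lowpass_then_average(self):
        """Whole-period integration and the engaged RC low-pass agree within
        0.1% once the record spans >= 100 periods."""
        f, fs = 1000.0, 37500.0
        block = _tone_block(f, fs, 200, amplitude=0.8, phase=0.5)
        plain = u.demodulate(block, 0)
        filtered = u.demodulate(
            block, 0, filt=u.FilterConfig(lowpass_order=1, lowpass_cutoff=50.0)
        )
        assert filtered.amplitude == pytest.approx(plain.amplitude, rel=1e-3)
        assert filtered.phase == pytest.approx(plain.phase, abs=1e-3)

    def test_white_noise_amplitude_shrinks_with_periods(self):
        """Noise-only demodulated amplitude RMS scales ~ 1/sqrt(periods)."""
        f, fs = 1.0, 200.0
        rng = np.random.default_rng(0)

        def amp_rms(periods, n_trials=25):
            amps = []
            for _ in range(n_trials):
                sig = rng.standard_normal(round(periods * fs / f))
                block = u.WaveformBlock(
                    fs=fs, f_exc=f, v_gen=1.0, channels=np.vstack([sig] * 4)
                )
                amps.append(u.demodulate(block, 0).amplitude)
            return np.sqrt(np.mean(np.square(amps)))

        ratio = amp_rms(16) / amp_rms(256)
        assert ratio == pytest.approx(4.0, rel=0.5)


class TestLowpass:
    def test_unity_dc_gain(self):
        x = np.full(5000, 3.7)
        y = u.apply_lowpass(x, 1000.0, 1, 5.0)
        assert y[-1] == pytest.approx(3.7, rel=1e-9)

    def test_corner_attenuation_first_order(self):
        """Steady-state amplitude ratio at the corner is 1/sqrt(2) (2%)."""
        fs, fc = 50000.0, 50.0
        t = np.arange(int(2.0 * fs)) / fs
        x = np.cos(2 * np.pi * fc * t)
        y = u.apply_lowpass(x, fs, 1, fc)
        tail = y[len(y) // 2 :]
        ratio = (tail.max() - tail.min()) / 2.0
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            u.apply_lowpass(np.ones(10), 1000.0, 1, 500.0)  # cutoff >= fs/2
        with pytest.raises(ValueError):
            u.apply_lowpass(np.ones(10), 1000.0, 3, 5.0)  # bad order

    def test_second_order_attenuates_more(self):
        fs, fc = 50000.0, 50.0
        t = np.arange(int(2.0 * fs)) / fs
        x = np.cos(2 * np.pi * 10 * fc * t)
        a1 = np.ptp(u.apply_lowpass(x, fs, 1, fc)[len(x) // 2 :])
        a2 = np.ptp(u.apply_lowpass(x, fs, 2, fc)[len(x) // 2 :])
        assert a2 < a1 / 5


class TestFFTSpectrum:
    def test_full_scale_tone_reads_zero_db(self):
        fs, f = 1024.0, 64.0
        t = np.arange(1024) / fs
        sig = np.cos(2 * np.pi * f * t)
        block = u.WaveformBlock(fs=fs, f_exc=f, v_gen=1.0, channels=np.vstack([sig] * 4))
        freqs, mag_db = u.fft_spectrum(block, 0)
        assert mag_db[np.argmin(np.abs(freqs - f))] == pytest.approx(0.0, abs=1e-9)

    def test_hann_window_coherent_gain_corrected(self):
        fs, f = 1024.0, 64.0
        t = np.arange(4096) / fs
        sig = np.cos(2 * np.pi * f * t)
        block = u.WaveformBlock(fs=fs, f_exc=f, v_gen=1.0, channels=np.vstack([sig] * 4))
        freqs, mag_db = u.fft_spectrum(block, 0, window="hann")
        assert mag_db[np.argmin(np.abs(freqs - f))] == pytest.approx(0.0, abs=0.1)

    def test_noiseless_phantom_peak_at_excitation(self, phantom):
        fs = u.select_sampling_rate(0.8, "fast")
        block = u.synthesize_waveforms(phantom, 0.8, 0.5, fs, 8, u.QUIET)
        freqs, mag_db = u.fft_spectrum(block, 1)
        assert freqs[int(np.argmax(mag_db))] == pytest.approx(0.8, rel=1e-6)

    def test_white_noise_floor_matches_parseval_estimate(self):
        rng = np.random.default_rng(5)
        sigma, n, fs = 1e-3, 65536, 1000.0
        sig = sigma * rng.standard_normal(n)
        block = u.WaveformBlock(fs=fs, f_exc=1.0, v_gen=1.0, channels=np.vstack([sig] * 4))
        _, mag_db = u.fft_spectrum(block, 0)
        mean_floor = np.mean(10 ** (mag_db[1:-1] / 20.0))
        expected = sigma * np.sqrt(2.0 / n)
        assert 20 * np.log10(mean_floor / expected) == pytest.approx(0.0, abs=3.0)
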