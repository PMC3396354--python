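"""Spectral shifting and shift-policy tests."""

import numpy as np
import pytest

from heartscribe.core import WindowFrame
from heartscribe.pitch import PitchConfig, dominant_frequency, pitch_number, spectrum
from heartscribe.shift import ShiftConfig, apply_shift_policy, inverse_fft, shift_spectrum

from conftest import make_tone_frame


def reestimate(sp, pcfg=PitchConfig()):
    return dominant_frequency(spectrum(inverse_fft(sp)), pcfg)


class TestShiftSpectrum:
    def test_zero_semitones_is_identity(self):
        sp = spectrum(make_tone_frame(100.0, 4000))
        out = shift_spectrum(sp, 0)
        np.testing.assert_array_equal(out.coefficients, sp.coefficients)

    def test_octave_doubles_peak_bin(self):
        # 100 Hz at bin 25 (bin width 4 Hz) -> 200 Hz at bin 50
        sp = spectrum(make_tone_frame(100.0, 4000, 250.0))
        out = shift_spectrum(sp, 12)
        mags = np.abs(out.coefficients[: sp.n // 2])
        assert np.argmax(mags[1:]) + 1 == 50

    def test_fourteen_semitones_remaps_bin_15_to_34(self):
        # 60 Hz on the 4 Hz grid: round(15 * 2^(14/12)) = 34, i.e. 136 Hz,
        # within one bin of the exact 60 * 2^(14/12) = 134.7 Hz
        sp = spectrum(make_tone_frame(60.0, 4000, 250.0))
        f = reestimate(shift_spectrum(sp, 14))
        assert f == pytest.approx(136.0)
        assert abs(f - 60.0 * 2 ** (14 / 12)) <= 4.0

    @pytest.mark.parametrize("semitones", [8, 12, 14, 20, 26])
    @pytest.mark.parametrize("freq", [40.0, 80.0, 120.0])
    def test_scaling_law_within_one_bin(self, semitones, freq):
        sp = spectrum(make_tone_frame(freq, 4000, 250.0))
        f = reestimate(shift_spectrum(sp, semitones),
                       PitchConfig(f_max=1000.0))
        assert abs(f - freq * 2 ** (semitones / 12)) <= 4.0

    def test_two_octaves_quadruple_frequency_exactly(self):
        sp = spectrum(make_tone_frame(100.0, 4000, 250.0))
        f = reestimate(shift_spectrum(shift_spectrum(sp, 12), 12))
        assert f / 100.0 == pytest.approx(4.0)

    def test_pitch_additivity_of_octave_shift(self):
        # frequencies away from the 40*log10(2) rounding boundaries,
        # where doubling adds exactly 12 pitch steps
        for freq in (60.0, 80.0, 100.0, 200.0):
            sp = spectrum(make_tone_frame(freq, 4000, 250.0))
            before = pitch_number(dominant_frequency(sp, PitchConfig()))
            after = pitch_number(reestimate(shift_spectrum(sp, 12)))
            assert after - before == 12, freq

    def test_peak_magnitude_preserved(self):
        sp = spectrum(make_tone_frame(100.0, 4000, 250.0))
        out = shift_spectrum(sp, 14)
        src_mag = np.abs(sp.coefficients[25])
        dest = round(25 * 2 ** (14 / 12))
        np.testing.assert_allclose(np.abs(out.coefficients[dest]), src_mag)

    def test_beyond_nyquist_content_is_discarded(self):
        # 1500 Hz shifted up two octaves would land at 6000 Hz > Nyquist
        sp = spectrum(make_tone_frame(1500.0, 4000, 250.0))
        out = shift_spectrum(shift_spectrum(sp, 12), 12)
        assert np.max(np.abs(out.coefficients)) < 1e-6 * np.max(np.abs(sp.coefficients))

    def test_output_is_conjugate_symmetric(self):
        rng = np.random.default_rng(5)
        sp = spectrum(WindowFrame(0, rng.standard_normal(512), 128.0))
        out = shift_spectrum(sp, 7)
        x = np.fft.ifft(out.coefficients)
        np.testing.assert_allclose(x.imag, 0.0, atol=1e-12)

    def test_negative_semitones_rejected(self):
        sp = spectrum(make_tone_frame(100.0, 4000))
        with pytest.raises(ValueError):
            shift_spectrum(sp, -1)


class TestInverseFFT:
    def test_round_trip_recovers_frame(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(2000)
        frame = WindowFrame(3, x, 250.0)
        out = inverse_fft(spectrum(frame), index=3)
        np.testing.assert_allclose(out.samples, x, rtol=1e-9, atol=1e-12)
        assert out.duration_ms == pytest.approx(250.0)

    def test_dc_spectrum_inverts_to_constant(self):
        from heartscribe.core import Spectrum
        out = inverse_fft(Spectrum([4.0, 0.0, 0.0, 0.0], 250.0))
        np.testing.assert_allclose(out.samples, np.ones(4))


class TestShiftPolicy:
    def test_above_trigger_no_shift(self):
        event = apply_shift_policy(make_tone_frame(120.0, 8000, 250.0),
                                   PitchConfig(), ShiftConfig())
        assert (event.shift_count, event.pitch, event.unresolved) == (0, 46, False)
        assert event.freq_hz == pytest.approx(120.0)

    def test_single_shift_crosses_trigger(self):
        # 60 Hz -> bin 15 -> round(15 * 2.2449) = 34 -> 136 Hz >= 100 Hz
        event = apply_shift_policy(make_tone_frame(60.0, 8000, 250.0),
                                   PitchConfig(), ShiftConfig())
        assert event.shift_count == 1
        assert event.freq_hz == pytest.approx(136.0)
        assert not event.unresolved

    def test_very_low_original_gets_two_applications(self):
        # 30 Hz on the 2 Hz grid (500 ms window): 15 -> 34 (68 Hz) -> 76
        # (152 Hz), near the exact 30 * 2^(28/12) = 151.2 Hz
        event = apply_shift_policy(
            make_tone_frame(30.0, 8000, 500.0),
            PitchConfig(window_ms=500.0), ShiftConfig()
        )
        assert event.shift_count == 2
        assert event.freq_hz == pytest.approx(152.0)
        assert abs(event.freq_hz - 30.0 * 2 ** (28 / 12)) <= 2.0

    def test_silent_frame_is_rest(self):
        event = apply_shift_policy(WindowFrame(0, np.zeros(2000), 250.0),
                                   PitchConfig(), ShiftConfig())
        assert (event.pitch, event.freq_hz, event.shift_count) == (0, None, 0)

    def test_zero_shift_low_tone_terminates_unresolved(self):
        event = apply_shift_policy(
            make_tone_frame(60.0, 8000, 250.0),
            PitchConfig(), ShiftConfig(shift_semitones=0)
        )
        assert event.unresolved
        assert event.shift_count == ShiftConfig().max_applications
        assert event.freq_hz == pytest.approx(60.0)
        assert event.pitch == pitch_number(60.0)

    @pytest.mark.parametrize("freq", [4.0, 24.0, 48.0, 72.0, 96.0, 104.0])
    def test_terminates_within_max_applications(self, freq):
        event = apply_shift_policy(make_tone_frame(freq, 8000, 250.0),
                                   PitchConfig(), ShiftConfig())
        assert event.shift_count <= ShiftConfig().max_applications
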