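"""Windowing, spectrum and pitch-quantization unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heartscribe.core import AudioSignal, WindowFrame
from heartscribe.pitch import (
    PitchConfig,
    dominant_frequency,
    pitch_number,
    segment_windows,
    spectrum,
)

from conftest import make_tone, make_tone_frame


class TestPitchNumber:
    @pytest.mark.parametrize(
        "freq, expected",
        [
            (261.6, 60),   # C4 anchor
            (523.2, 72),   # one octave up: +12
            (130.8, 48),   # one octave down: -12
            (120.0, 46),   # 40*log10(120/261.6)+60 = 46.46
            (180.0, 54),
            (100.0, 43),
            (1e-3, 1),     # clamped at the bottom (0 reserved for rests)
            (1e9, 127),    # clamped at the top
        ],
    )
    def test_quantization(self, freq, expected):
        assert pitch_number(freq) == expected

    @pytest.mark.parametrize("freq", [0.0, -10.0])
    def test_nonpositive_frequency_rejected(self, freq):
        with pytest.raises(ValueError):
            pitch_number(freq)

    @given(st.floats(min_value=1.0, max_value=2000.0),
           st.floats(min_value=1.0, max_value=2000.0))
    @settings(deadline=None)
    def test_monotone_in_frequency(self, f1, f2):
        lo, hi = sorted((f1, f2))
        assert pitch_number(lo) <= pitch_number(hi)

    def test_octave_adds_twelve_away_from_rounding_boundaries(self):
        # 40*log10(2) = 12.041, so doubling adds 12 except where the 0.041
        # excess pushes the rounded value across a half-step boundary.
        boundary = {38, 85, 90, 101, 107, 120, 160, 226}
        for f in range(20, 251):
            diff = pitch_number(2 * f) - pitch_number(f)
            assert diff == (13 if f in boundary else 12), f


class TestSegmentation:
    @pytest.mark.parametrize(
        "duration_s, window_ms, n_windows, n_samples",
        [
            (10.0, 250.0, 40, 2000),
            (10.1, 250.0, 40, 2000),  # 800 trailing samples dropped
            (10.0, 500.0, 20, 4000),
            (10.0, 100.0, 100, 800),
            (0.1, 250.0, 0, None),    # shorter than one window -> empty
        ],
    )
    def test_window_arithmetic(self, duration_s, window_ms, n_windows, n_samples):
        sig = make_tone(100.0, 8000, duration_s)
        frames = segment_windows(sig, PitchConfig(window_ms=window_ms))
        assert len(frames) == n_windows
        if frames:
            assert all(f.n == n_samples for f in frames)
            assert [f.index for f in frames] == list(range(n_windows))

    def test_frames_tile_the_signal(self):
        sig = make_tone(100.0, 8000, 1.0)
        frames = segment_windows(sig, PitchConfig(window_ms=250.0))
        np.testing.assert_array_equal(
            np.concatenate([f.samples for f in frames]), sig.samples[:8000]
        )


class TestSpectrum:
    def test_impulse_gives_flat_spectrum(self):
        frame = WindowFrame(0, [1.0, 0.0, 0.0, 0.0], 1.0)
        np.testing.assert_allclose(spectrum(frame).coefficients, np.ones(4))

    def test_dc_frame(self):
        frame = WindowFrame(0, [1.0, 1.0, 1.0, 1.0], 1.0)
        np.testing.assert_allclose(
            spectrum(frame).coefficients, [4.0, 0.0, 0.0, 0.0], atol=1e-12
        )

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_parseval(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(rng.integers(4, 256))
        sp = spectrum(WindowFrame(0, x, 100.0))
        time_energy = np.sum(x**2)
        freq_energy = np.sum(np.abs(sp.coefficients) ** 2) / x.size
        np.testing.assert_allclose(freq_energy, time_energy, rtol=1e-9)

    def test_bin_width(self):
        frame = make_tone_frame(100.0, sample_rate=8000, window_ms=250.0)
        assert spectrum(frame).bin_hz == pytest.approx(4.0)


class TestDominantFrequency:
    @pytest.mark.parametrize("freq", [20.0, 100.0, 248.0, 496.0])
    @pytest.mark.parametrize("amp", [1e-3, 1.0, 50.0])
    def test_on_grid_tone_recovered_exactly(self, freq, amp):
        frame = make_tone_frame(freq, sample_rate=4000, window_ms=250.0, amp=amp)
        f = dominant_frequency(spectrum(frame), PitchConfig())
        assert f == pytest.approx(freq)

    def test_off_grid_tone_within_one_and_a_half_bins(self):
        frame = make_tone_frame(101.7, sample_rate=4000, window_ms=250.0)
        f = dominant_frequency(spectrum(frame), PitchConfig())
        assert abs(f - 101.7) <= 1.5 * 4.0

    def test_strongest_component_wins(self):
        n, fs = 1000, 4000
        t = np.arange(n) / fs
        x = 1.0 * np.sin(2 * np.pi * 80 * t) + 0.5 * np.sin(2 * np.pi * 300 * t)
        f = dominant_frequency(spectrum(WindowFrame(0, x, 250.0)), PitchConfig())
        assert f == pytest.approx(80.0)

    def test_all_zero_frame_is_rest(self):
        frame = WindowFrame(0, np.zeros(2000), 250.0)
        assert dominant_frequency(spectrum(frame), PitchConfig()) is None

    def test_band_excludes_dc_and_out_of_band(self):
        # strong DC plus weak in-band tone: the tone must win
        frame = make_tone_frame(100.0, sample_rate=4000, amp=0.1)
        x = frame.samples + 10.0
        f = dominant_frequency(spectrum(WindowFrame(0, x, 250.0)), PitchConfig())
        assert f == pytest.approx(100.0)

    def test_unusable_band_is_an_error(self):
        frame = make_tone_frame(100.0, sample_rate=4000)
        with pytest.raises(ValueError):
            dominant_frequency(spectrum(frame), PitchConfig(f_min=0.5, f_max=0.9))
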