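"""Windowing, FFT spectrum, dominant-frequency estimation and pitch quantization.

The record is cut into consecutive non-overlapping windows of duration
``window_ms`` (no onset detection: one note per window).  Each window's DFT

    X_k = sum_j x_j exp(-i 2 pi k j / N),   k = 0..N-1

is computed by FFT without tapering.  The dominant frequency is the largest
magnitude bin inside the 1–500 Hz analysis band, and the musical pitch is

    N(p) = round(40 * log10(f / 261.6) + 60)

so that 261.6 Hz (C4) maps to pitch 60 and a frequency doubling adds one
octave (12 semitones, up to the 40*log10(2) = 12.04 rounding boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .core import AudioSignal, Spectrum, WindowFrame

__all__ = [
    "PitchConfig",
    "segment_windows",
    "spectrum",
    "dominant_frequency",
    "pitch_number",
    "band_bins",
]


@dataclass(frozen=True)
class PitchConfig:
    """Analysis parameters.

    ``window_ms`` is the analysis window duration (100/250/500 ms are the
    studied sizes; 250 ms is the default working point).  The search band
    [f_min, f_max] = [1, 500] Hz excludes DC and caps the analysis where
    heart-sound content (even after shifting) ends.  ``ref_freq`` anchors
    pitch 60.  Windows whose RMS falls below ``silence_epsilon`` (relative
    to full scale 1.0) are rests.
    """

    window_ms: float = 250.0
    f_min: float = 1.0
    f_max: float = 500.0
    ref_freq: float = 261.6
    silence_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.f_min < self.f_max:
            raise ValueError("need 0 < f_min < f_max")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if self.ref_freq <= 0:
            raise ValueError("ref_freq must be positive")


def window_length(sample_rate: float, window_ms: float) -> int:
    return int(round(window_ms / 1000.0 * sample_rate))


def segment_windows(s: AudioSignal, cfg: PitchConfig) -> List[WindowFrame]:
    """Cut the record into consecutive non-overlapping frames.

    The trailing partial window is discarded; a record shorter than one
    window yields an empty list.
    """
    n = window_length(s.sample_rate, cfg.window_ms)
    count = s.samples.size // n
    return [
        WindowFrame(index=i, samples=s.samples[i * n : (i + 1) * n],
                    duration_ms=cfg.window_ms)
        for i in range(count)
    ]


def spectrum(f: WindowFrame) -> Spectrum:
    """Full-length complex DFT of one window (plain FFT, no tapering)."""
    coeff = np.fft.fft(f.samples)
    return Spectrum(coefficients=coeff, bin_hz=f.sample_rate / f.n)


def band_bins(sp: Spectrum, cfg: PitchConfig) -> np.ndarray:
    """Indices of spectrum bins inside [f_min, f_max], capped below Nyquist."""
    k_lo = int(math.ceil(cfg.f_min / sp.bin_hz))
    k_hi = int(math.floor(cfg.f_max / sp.bin_hz))
    k_hi = min(k_hi, (sp.n - 1) // 2)
    if k_hi < k_lo:
        raise ValueError(
            f"f_max {cfg.f_max} Hz leaves no usable bin (bin width {sp.bin_hz} Hz)"
        )
    return np.arange(max(k_lo, 1), k_hi + 1)


def dominant_frequency(
    sp: Spectrum, cfg: PitchConfig, frame_rms: Optional[float] = None
) -> Optional[float]:
    """Frequency of the largest-magnitude bin in the band, or None for silence.

    Ties break toward the lower frequency (heart-sound fundamentals sit
    below their harmonics).  ``frame_rms`` may be supplied by the caller;
    otherwise it is recovered from the spectrum via Parseval.
    """
    if frame_rms is None:
        frame_rms = float(np.sqrt(np.sum(np.abs(sp.coefficients) ** 2)) / sp.n)
    if frame_rms < cfg.silence_epsilon:
        return None
    ks = band_bins(sp, cfg)
    mags = np.abs(sp.coefficients[ks])
    k_best = int(ks[int(np.argmax(mags))])  # argmax: first max -> lowest bin
    return k_best * sp.bin_hz


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def pitch_number(f_hz: float, ref_freq: float = 261.6) -> int:
    """Quantize a frequency to the nearest integer pitch number.

    N(p) = round(40 log10(f / ref) + 60), clamped to [1, 127]; rounding is
    half-away-from-zero (pitch 0 stays reserved for rests).
    """
    if f_hz <= 0:
        raise ValueError(f"frequency must be positive, got {f_hz}")
    value = 40.0 * math.log10(f_hz / ref_freq) + 60.0
    return max(1, min(127, _round_half_away(value)))
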