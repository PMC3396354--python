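"""Spectral frequency shifting: the transcription method's core step.

Heart-sound fundamentals (20–150 Hz) sit below the range where integer-
semitone pitch decisions are reliable at the FFT's native resolution.  When
a window's estimated frequency falls below a trigger (100 Hz), its spectrum
is lifted by a fixed number of semitones ``f_sh``: every bin k moves to
round(k * 2^(f_sh/12)).  The shifted spectrum is inverted back to audio and
the pitch re-estimated; very low estimates (< 50 Hz) receive the shift at
least twice.  A semitone shift is multiplicative in Hz — one octave (12
semitones) doubles the frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import PitchEvent, Spectrum, WindowFrame
from .pitch import PitchConfig, dominant_frequency, pitch_number, spectrum

__all__ = ["ShiftConfig", "shift_spectrum", "inverse_fft", "apply_shift_policy"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShiftConfig:
    """Shifting policy parameters.

    ``shift_semitones`` is f_sh (studied values 8/14/20/26; 14 is the
    working point).  The shift is applied while the estimate stays below
    ``trigger_hz``; an original estimate below ``very_low_hz`` receives at
    least two applications.  ``max_applications`` is a termination guard.
    """

    shift_semitones: int = 14
    trigger_hz: float = 100.0
    very_low_hz: float = 50.0
    max_applications: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.very_low_hz < self.trigger_hz:
            raise ValueError("need 0 < very_low_hz < trigger_hz")
        if self.shift_semitones < 0:
            raise ValueError("shift_semitones must be >= 0")
        if self.max_applications < 2:
            raise ValueError("max_applications must be >= 2")

    @property
    def factor(self) -> float:
        return 2.0 ** (self.shift_semitones / 12.0)


def shift_spectrum(sp: Spectrum, semitones: int) -> Spectrum:
    """Relocate every positive-frequency bin k to round(k * 2^(semitones/12)).

    Colliding destinations accumulate (complex sum); destinations at or
    beyond Nyquist are discarded; DC stays put.  Conjugate symmetry is
    rebuilt afterwards so the inverse transform is real.  For semitones >= 0
    the map is injective (factor >= 1), so magnitudes are preserved
    bin-for-bin and the spectral argmax moves exactly with the remap.
    """
    if semitones < 0:
        raise ValueError("semitones must be >= 0")
    if semitones == 0:
        return Spectrum(sp.coefficients.copy(), sp.bin_hz)
    n = sp.n
    factor = 2.0 ** (semitones / 12.0)
    k_max = (n - 1) // 2  # highest strictly-below-Nyquist bin
    half = np.zeros(k_max + 1, dtype=np.complex128)
    half[0] = sp.coefficients[0]
    src = np.arange(1, n // 2 + 1)
    dest = np.floor(src * factor + 0.5).astype(np.int64)
    keep = dest <= k_max
    np.add.at(half, dest[keep], sp.coefficients[src[keep]])
    full = np.zeros(n, dtype=np.complex128)
    full[: k_max + 1] = half
    full[n - k_max :] = np.conj(half[1:][::-1])
    return Spectrum(full, sp.bin_hz)


def inverse_fft(sp: Spectrum, index: int = 0) -> WindowFrame:
    """Reconstruct the real time-domain frame from a (shifted) spectrum."""
    x = np.fft.ifft(sp.coefficients).real
    duration_ms = 1000.0 / sp.bin_hz
    return WindowFrame(index=index, samples=x, duration_ms=duration_ms)


def apply_shift_policy(
    frame: WindowFrame, pcfg: PitchConfig, scfg: ShiftConfig
) -> PitchEvent:
    """Estimate, shift while below the trigger, and quantize one window.

    The very-low rule keys on the ORIGINAL estimate: below ``very_low_hz``
    the shift runs at least twice before the trigger test applies.  If the
    estimate is still below the trigger after ``max_applications`` the event
    is flagged unresolved and the pitch comes from the last estimate.
    """
    sp = spectrum(frame)
    f = dominant_frequency(sp, pcfg, frame_rms=frame.rms())
    if f is None:
        return PitchEvent(window_index=frame.index, freq_hz=None,
                          shift_count=0, pitch=0)

    min_applications = 2 if f < scfg.very_low_hz else 0
    count = 0
    while count < scfg.max_applications and (
        count < min_applications or f < scfg.trigger_hz
    ):
        sp = shift_spectrum(sp, scfg.shift_semitones)
        frame = inverse_fft(sp, index=frame.index)
        sp = spectrum(frame)
        count += 1
        f_new = dominant_frequency(sp, pcfg)
        if f_new is None:
            break  # all content fell out of the band; keep last estimate
        f = f_new

    unresolved = f < scfg.trigger_hz
    if unresolved:
        logger.warning(
            "window %d: estimate %.1f Hz still below trigger %.1f Hz after "
            "%d shift applications",
            frame.index, f, scfg.trigger_hz, count,
        )
    return PitchEvent(
        window_index=frame.index,
        freq_hz=f,
        shift_count=count,
        pitch=pitch_number(f, pcfg.ref_freq),
        unresolved=unresolved,
    )
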