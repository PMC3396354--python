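"""Domain types shared by every stage of the transcription pipeline.

A phonocardiogram (PCG) enters as an :class:`AudioSignal`, is cut into
fixed-duration :class:`WindowFrame` s, each of which yields a
:class:`Spectrum` and finally a :class:`PitchEvent` — one musical note (or
rest) per window.  The ordered events plus the configuration that produced
them form a :class:`Transcript`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

__all__ = [
    "AudioSignal",
    "WindowFrame",
    "Spectrum",
    "PitchEvent",
    "Transcript",
    "REST_PITCH",
]

#: Pitch code reserved for a silent (rest) window.  Heart-sound pitches are
#: always well above MIDI note 0, so 0 is safe to reserve.
REST_PITCH = 0

#: Minimum sample rate able to resolve the 500 Hz analysis ceiling (Nyquist).
MIN_SAMPLE_RATE = 2000


@dataclass(frozen=True)
class AudioSignal:
    """A sampled mono waveform — the PCG record.

    Parameters
    ----------
    samples
        Amplitude values (dimensionless, finite).  Stored as float64.
    sample_rate
        Sampling frequency in Hz; must be at least 2 kHz so that the
        1–500 Hz analysis band sits safely below Nyquist.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("AudioSignal requires a non-empty 1-D sample vector")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must all be finite")
        if int(self.sample_rate) < MIN_SAMPLE_RATE:
            raise ValueError(
                f"sample_rate must be >= {MIN_SAMPLE_RATE} Hz, got {self.sample_rate}"
            )
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class WindowFrame:
    """One fixed-duration analysis window (the analysis unit ``w``)."""

    index: int
    samples: np.ndarray
    duration_ms: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.index < 0:
            raise ValueError("window index must be >= 0")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("WindowFrame requires a non-empty 1-D sample vector")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def sample_rate(self) -> float:
        return self.n * 1000.0 / self.duration_ms

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class Spectrum:
    """Complex DFT coefficients of one window with the bin→Hz mapping."""

    coefficients: np.ndarray
    bin_hz: float

    def __post_init__(self) -> None:
        coeff = np.asarray(self.coefficients, dtype=np.complex128)
        object.__setattr__(self, "coefficients", coeff)
        if coeff.ndim != 1 or coeff.size < 1:
            raise ValueError("Spectrum requires a non-empty coefficient vector")
        if not self.bin_hz > 0:
            raise ValueError("bin_hz must be positive")

    @property
    def n(self) -> int:
        return int(self.coefficients.size)

    @property
    def sample_rate(self) -> float:
        return self.bin_hz * self.n

    def magnitudes(self) -> np.ndarray:
        return np.abs(self.coefficients)


@dataclass(frozen=True)
class PitchEvent:
    """Per-window result: estimated frequency, shifts applied, quantized pitch.

    ``pitch == 0`` encodes a rest and coincides with ``freq_hz is None``.
    ``unresolved`` flags a window whose estimate stayed below the shifting
    trigger even after the maximum number of shift applications.
    """

    window_index: int
    freq_hz: Optional[float]
    shift_count: int
    pitch: int
    unresolved: bool = False

    def __post_init__(self) -> None:
        if self.window_index < 0:
            raise ValueError("window_index must be >= 0")
        if self.shift_count < 0:
            raise ValueError("shift_count must be >= 0")
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch must lie in [0, 127], got {self.pitch}")
        if (self.pitch == REST_PITCH) != (self.freq_hz is None):
            raise ValueError("pitch 0 is reserved for rests (freq_hz absent)")

    @property
    def is_rest(self) -> bool:
        return self.pitch == REST_PITCH


@dataclass(frozen=True)
class Transcript:
    """Ordered pitch events plus the configuration snapshot that produced them."""

    events: tuple
    config: Any = None
    source_id: str = ""

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        for i, ev in enumerate(events):
            if ev.window_index != i:
                raise ValueError(
                    f"event indices must be consecutive from 0; event {i} "
                    f"has window_index {ev.window_index}"
                )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def pitches(self) -> np.ndarray:
        return np.array([ev.pitch for ev in self.events], dtype=np.int64)

    @property
    def frequencies(self) -> list:
        return [ev.freq_hz for ev in self.events]
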