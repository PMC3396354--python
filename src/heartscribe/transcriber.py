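"""Whole-record transcription: batch (NRT) and streaming (RT emulation) paths.

Batch mode filters zero-phase, gates against the global A_max, segments and
runs the shift policy per window.  Streaming mode consumes chunks of
arbitrary size, filters causally, gates each completed window against a
rolling 2 s amplitude maximum, and emits each pitch event as soon as its
window completes.  On stationary signals the two paths agree; they differ
only through the causal-vs-zero-phase filter and rolling-vs-global gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any, Dict, Iterable, Iterator

import numpy as np

from .core import AudioSignal, PitchEvent, Transcript
from .preprocess import (
    ROLLING_AMAX_SECONDS,
    PreprocessConfig,
    StreamingLowpass,
    amplitude_reconstruct,
    gate_samples,
    lowpass_filter,
)
from .pitch import PitchConfig, segment_windows, window_length
from .shift import ShiftConfig, apply_shift_policy

__all__ = ["TranscriptionConfig", "transcribe", "transcribe_stream"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranscriptionConfig:
    """Bundle of stage configurations plus the processing mode."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    pitch: PitchConfig = field(default_factory=PitchConfig)
    shift: ShiftConfig = field(default_factory=ShiftConfig)
    mode: str = "batch"

    def __post_init__(self) -> None:
        if self.mode not in ("batch", "streaming"):
            raise ValueError("mode must be 'batch' or 'streaming'")

    def validate_for_rate(self, sample_rate: float) -> None:
        self.preprocess.validate_for_rate(sample_rate)
        if self.pitch.f_max > sample_rate / 2:
            raise ValueError(
                f"pitch f_max ({self.pitch.f_max} Hz) exceeds Nyquist "
                f"({sample_rate / 2} Hz)"
            )

    def as_dict(self) -> Dict[str, Any]:
        return {
            "window_ms": self.pitch.window_ms,
            "threshold": self.preprocess.threshold_ratio,
            "shift": self.shift.shift_semitones,
            "trigger_hz": self.shift.trigger_hz,
            "very_low_hz": self.shift.very_low_hz,
            "f_pass": self.preprocess.f_pass,
            "f_stop": self.preprocess.f_stop,
            "f_min": self.pitch.f_min,
            "f_max": self.pitch.f_max,
            "ref_freq": self.pitch.ref_freq,
            "mode": self.mode,
        }


def transcribe(s: AudioSignal, cfg: TranscriptionConfig,
               source_id: str = "") -> Transcript:
    """Transcribe a whole record in batch mode.

    Deterministic: the same input and config always yield the same events.
    A record shorter than one window yields an empty transcript.
    """
    cfg.validate_for_rate(s.sample_rate)
    filtered = lowpass_filter(s, cfg.preprocess)
    gated = amplitude_reconstruct(filtered, cfg.preprocess)
    frames = segment_windows(gated, cfg.pitch)
    if not frames:
        logger.warning("record shorter than one %g ms window; empty transcript",
                       cfg.pitch.window_ms)
    events = tuple(
        apply_shift_policy(f, cfg.pitch, cfg.shift) for f in frames
    )
    return Transcript(events=events, config=cfg, source_id=source_id)


def transcribe_stream(
    chunks: Iterable[np.ndarray],
    cfg: TranscriptionConfig,
    sample_rate: int,
) -> Iterator[PitchEvent]:
    """Transcribe a live chunk stream, emitting one event per completed window.

    The filter is causal and the gate threshold uses the maximum absolute
    filtered amplitude over the trailing 2 s (up to the window's end), so no
    future samples are consulted.  A trailing partial window is dropped,
    matching batch mode.
    """
    cfg.validate_for_rate(sample_rate)
    n = window_length(sample_rate, cfg.pitch.window_ms)
    history = max(n, int(round(ROLLING_AMAX_SECONDS * sample_rate)))
    lp = StreamingLowpass(sample_rate, cfg.preprocess)
    buffer = np.empty(0, dtype=np.float64)
    tail = np.empty(0, dtype=np.float64)  # trailing filtered samples for A_max
    index = 0
    from .core import WindowFrame  # local import to avoid cycle at module load

    for chunk in chunks:
        buffer = np.concatenate([buffer, lp.process(np.asarray(chunk, float))])
        while buffer.size >= n:
            window, buffer = buffer[:n], buffer[n:]
            tail = np.concatenate([tail, window])[-history:]
            a_max = float(np.max(np.abs(tail)))
            gated = gate_samples(window, cfg.preprocess.threshold_ratio * a_max)
            frame = WindowFrame(index=index, samples=gated,
                                duration_ms=cfg.pitch.window_ms)
            yield apply_shift_policy(frame, cfg.pitch, cfg.shift)
            index += 1
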