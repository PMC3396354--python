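"""Reading and writing of the standard formats.

* WAV (RIFF PCM 16-bit and IEEE float) via :mod:`scipy.io.wavfile`; stereo
  inputs are mixed to mono by channel mean, integer PCM is rescaled to
  [-1, 1].
* The raw byte transcript (``.hst``): exactly one unsigned byte per window
  holding the pitch number (0 = rest), no header.  Provenance and the
  producing configuration live in a JSON sidecar with the same stem.
* A human-readable TSV transcript, and the simulator's truth TSV.
* Standard MIDI File type 0: one note per non-rest window at a fixed
  120 bpm mapping, so a 250 ms window is an eighth note.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.io import wavfile

from .core import AudioSignal, PitchEvent, Transcript
from .transcriber import TranscriptionConfig

__all__ = [
    "AudioFormatError",
    "TranscriptFormatError",
    "read_wav",
    "write_wav",
    "write_transcript_binary",
    "read_transcript_binary",
    "write_sidecar",
    "read_sidecar",
    "write_transcript_tsv",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_midi",
]

PathLike = Union[str, Path]


class AudioFormatError(ValueError):
    """Unreadable, corrupt or empty audio input."""


class TranscriptFormatError(ValueError):
    """Invalid transcript byte stream."""


_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


def read_wav(path: PathLike) -> AudioSignal:
    """Read a mono or stereo PCM/float WAV file as a mono AudioSignal."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises ValueError on malformed RIFF
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"WAV file {path} contains no audio")
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32 / float64
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples, int(rate))


def write_wav(path: PathLike, s: AudioSignal, pcm16: bool = True) -> None:
    """Write an AudioSignal as 16-bit PCM (default) or 32-bit float WAV."""
    if pcm16:
        clipped = np.clip(s.samples, -1.0, 32767.0 / 32768.0)
        data = np.round(clipped * 32768.0).astype(np.int16)
    else:
        data = s.samples.astype(np.float32)
    wavfile.write(Path(path), s.sample_rate, data)


def write_transcript_binary(t: Transcript, path: PathLike) -> int:
    """Write one unsigned byte per window (the pitch number); no header.

    Returns the number of bytes written, which equals the window count.
    """
    pitches = t.pitches
    if pitches.size and (pitches.min() < 0 or pitches.max() > 127):
        raise TranscriptFormatError("pitch outside [0, 127] cannot be serialized")
    payload = bytes(int(p) for p in pitches)
    Path(path).write_bytes(payload)
    return len(payload)


def _pitch_center_freq(pitch: int, ref_freq: float) -> float:
    # center frequency of an integer pitch under N(p) = 40 log10(f/ref) + 60
    return ref_freq * 10.0 ** ((pitch - 60) / 40.0)


def read_transcript_binary(
    path: PathLike, config: Optional[TranscriptionConfig] = None
) -> Transcript:
    """Read a raw byte transcript back into a Transcript.

    The byte stream stores only pitch numbers, so each non-rest event's
    frequency is reconstructed as its pitch's center frequency and the
    shift count is unknown (0).  The pitch sequence round-trips exactly.
    """
    raw = Path(path).read_bytes()
    cfg = config if config is not None else TranscriptionConfig()
    ref = cfg.pitch.ref_freq
    events = []
    for i, byte in enumerate(raw):
        if byte > 127:
            raise TranscriptFormatError(
                f"byte {byte:#x} at offset {i} outside the pitch range [0, 127]"
            )
        freq = None if byte == 0 else _pitch_center_freq(byte, ref)
        events.append(
            PitchEvent(window_index=i, freq_hz=freq, shift_count=0, pitch=byte)
        )
    return Transcript(events=tuple(events), config=config)


def sidecar_path(path: PathLike) -> Path:
    return Path(str(path) + ".json")


def write_sidecar(t: Transcript, path: PathLike) -> None:
    """Write the transcript's provenance/config next to the byte stream."""
    cfg = t.config if t.config is not None else TranscriptionConfig()
    payload = dict(cfg.as_dict(), source_id=t.source_id, windows=len(t))
    sidecar_path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_sidecar(path: PathLike) -> dict:
    return json.loads(sidecar_path(path).read_text())


def write_transcript_tsv(t: Transcript, path: PathLike) -> None:
    """One line per window: window_index, freq_hz (post-shift), shift_count, pitch."""
    lines = ["window_index\tfreq_hz\tshift_count\tpitch"]
    for ev in t.events:
        freq = "" if ev.freq_hz is None else f"{ev.freq_hz:.3f}"
        lines.append(f"{ev.window_index}\t{freq}\t{ev.shift_count}\t{ev.pitch}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_tsv(pitches: np.ndarray, path: PathLike) -> None:
    lines = ["window_index\texpected_pitch"]
    lines += [f"{i}\t{int(p)}" for i, p in enumerate(pitches)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_tsv(path: PathLike) -> np.ndarray:
    rows = Path(path).read_text().strip().splitlines()[1:]
    return np.array([int(r.split("\t")[1]) for r in rows], dtype=np.int64)


# --- Standard MIDI File type 0 ------------------------------------------------

_MIDI_DIVISION = 480  # ticks per quarter note
_MIDI_TEMPO_US = 500_000  # 120 bpm, so a 250 ms window = one eighth note
_MIDI_VELOCITY = 64


def _vlq(value: int) -> bytes:
    """MIDI variable-length quantity encoding."""
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def write_midi(t: Transcript, path: PathLike) -> None:
    """Write a type-0 Standard MIDI File: one note per non-rest window.

    Window duration maps to ticks at the fixed 120 bpm tempo (250 ms window
    = eighth note = 240 ticks); rests advance time without emitting notes.
    """
    cfg = t.config if t.config is not None else TranscriptionConfig()
    window_ticks = int(round(_MIDI_DIVISION * cfg.pitch.window_ms / 500.0))
    track = bytearray()
    track += _vlq(0) + bytes([0xFF, 0x51, 0x03])
    track += _MIDI_TEMPO_US.to_bytes(3, "big")
    pending = 0  # delta time accumulated across rests
    for ev in t.events:
        if ev.is_rest:
            pending += window_ticks
            continue
        track += _vlq(pending) + bytes([0x90, ev.pitch, _MIDI_VELOCITY])
        track += _vlq(window_ticks) + bytes([0x80, ev.pitch, 0])
        pending = 0
    track += _vlq(pending) + bytes([0xFF, 0x2F, 0x00])  # end of track
    header = b"MThd" + (6).to_bytes(4, "big")
    header += (0).to_bytes(2, "big") + (1).to_bytes(2, "big")
    header += _MIDI_DIVISION.to_bytes(2, "big")
    chunk = b"MTrk" + len(track).to_bytes(4, "big") + bytes(track)
    Path(path).write_bytes(header + chunk)
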