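"""Synthetic phonocardiogram generator with per-window ground-truth pitch.

Emulates eight heart-sound categories (normal through continuous murmur)
as schedules of tone bursts and band-limited murmur noise:

======== ===================== ==========================================
category name                  construction
======== ===================== ==========================================
A1       Normal Sound          S1 then S2 per cycle (100 ms bursts)
A2       Split Second Sound    S2 split into two 40 ms sub-bursts 60 ms apart
A3       Ejection Sound        A1 + 30 ms click early after S1
A4       Clicks                A1 + 30 ms click in mid-systole
A5       Gallop Rhythm         A1 + third low-frequency (40 Hz) pulse
A6       Systolic Murmurs      A1 + band-limited noise filling systole
A7       Diastolic Murmurs     A1 + band-limited noise filling diastole
A8       Continues Murmurs     A1 + band-limited noise across the cycle
======== ===================== ==========================================

Tone bursts are sines under a raised-cosine envelope (pulse fundamentals in
the physiological 20–150 Hz band, ~100 ms duration); cycle lengths jitter by
±2 % so pulses do not phase-lock to the analysis grid; white noise is added
at a configurable level.  Everything is deterministic given the seed.

Ground truth labels each analysis window on the CLEAN (noise-free) signal
after the same filtering/gating the transcriber publishes, and lifts the
dominant bin through a closed-form integer recurrence k ← round(k·2^(s/12))
that mirrors the shifting policy arithmetically — independently of the
spectral remap / inverse-FFT machinery under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .core import AudioSignal
from .pitch import PitchConfig, pitch_number, window_length
from .preprocess import amplitude_reconstruct, lowpass_filter
from .shift import ShiftConfig
from .transcriber import TranscriptionConfig

__all__ = [
    "CATEGORIES",
    "PCGSpec",
    "GroundTruth",
    "SourceEvent",
    "generate",
    "render_clean",
    "ground_truth",
    "lifted_bin",
]

CATEGORIES: Dict[str, str] = {
    "A1": "Normal Sound",
    "A2": "Split Second Sound",
    "A3": "Ejection Sound",
    "A4": "Clicks",
    "A5": "Gallop Rhythm",
    "A6": "Systolic Murmurs",
    "A7": "Diastolic Murmurs",
    "A8": "Continues Murmurs",
}

# Source amplitudes relative to the S1 peak (= full scale).  S2 is the
# physiologically softer pulse; clicks and gallops sit above the default
# 0.6 gate so they survive preprocessing; murmurs are low-level broadband
# noise that the default gate removes.
S1_AMP = 1.0
S2_AMP = 0.8
CLICK_AMP = 0.7
GALLOP_AMP = 0.7
MURMUR_RMS = 0.12

CLICK_FREQ_HZ = 200.0
GALLOP_FREQ_HZ = 40.0
CLICK_MS = 30.0
SPLIT_SUB_MS = 40.0
SPLIT_GAP_MS = 60.0

_JITTER = 0.02  # ±2 % cycle-length jitter


@dataclass(frozen=True)
class SourceEvent:
    """One scheduled sound source: a tone burst or a murmur segment."""

    kind: str  # s1 | s2 | s2a | s2b | click | gallop | murmur
    onset_s: float
    dur_s: float
    freq_hz: Optional[float]  # None for murmur noise
    amp: float


@dataclass(frozen=True)
class PCGSpec:
    """Parameters of one synthetic recording."""

    category: str = "A1"
    heart_rate_bpm: float = 70.0
    s1_freq_hz: float = 120.0
    s2_freq_hz: float = 80.0
    pulse_ms: float = 100.0
    systole_ms: float = 300.0
    noise_level: float = 0.05
    murmur_band: Tuple[float, float] = (100.0, 240.0)
    duration_s: float = 10.0
    sample_rate: int = 8000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        for f in (self.s1_freq_hz, self.s2_freq_hz):
            if not 20.0 <= f <= 150.0:
                raise ValueError(
                    f"pulse fundamentals must lie in 20-150 Hz, got {f}"
                )
        if not 0.0 <= self.noise_level < 1.0:
            raise ValueError("noise_level must lie in [0, 1)")
        if self.duration_s <= 0 or self.heart_rate_bpm <= 0:
            raise ValueError("duration and heart rate must be positive")
        if not 0 < self.murmur_band[0] < self.murmur_band[1]:
            raise ValueError("murmur_band must be an increasing (lo, hi) pair")


@dataclass(frozen=True)
class GroundTruth:
    """Per-window expected pitch aligned to ``window_ms`` (0 = rest)."""

    pitches: np.ndarray
    window_ms: float
    events: Tuple[SourceEvent, ...]
    category: str
    config: TranscriptionConfig

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pitches", np.asarray(self.pitches, dtype=np.int64)
        )

    def __len__(self) -> int:
        return int(self.pitches.size)

    @property
    def cycle_onsets(self) -> List[float]:
        return [ev.onset_s for ev in self.events if ev.kind == "s1"]


def _schedule(spec: PCGSpec, rng: np.random.Generator) -> List[SourceEvent]:
    """Lay out source events cycle by cycle with jittered cycle lengths."""
    period = 60.0 / spec.heart_rate_bpm
    pulse = spec.pulse_ms / 1000.0
    systole = spec.systole_ms / 1000.0
    events: List[SourceEvent] = []
    t = 0.1  # lead-in before the first S1
    while t + systole + pulse < spec.duration_s:
        cycle = period * (1.0 + rng.uniform(-_JITTER, _JITTER))
        s2_on = t + systole
        events.append(SourceEvent("s1", t, pulse, spec.s1_freq_hz, S1_AMP))
        if spec.category == "A2":
            sub = SPLIT_SUB_MS / 1000.0
            gap = SPLIT_GAP_MS / 1000.0
            events.append(SourceEvent("s2a", s2_on, sub, spec.s2_freq_hz, S2_AMP))
            events.append(
                SourceEvent("s2b", s2_on + gap, sub, spec.s2_freq_hz, S2_AMP)
            )
        else:
            events.append(SourceEvent("s2", s2_on, pulse, spec.s2_freq_hz, S2_AMP))
        if spec.category == "A3":
            events.append(
                SourceEvent("click", t + pulse + 0.04, CLICK_MS / 1000.0,
                            CLICK_FREQ_HZ, CLICK_AMP)
            )
        elif spec.category == "A4":
            events.append(
                SourceEvent("click", t + pulse + 0.10, CLICK_MS / 1000.0,
                            CLICK_FREQ_HZ, CLICK_AMP)
            )
        elif spec.category == "A5":
            events.append(
                SourceEvent("gallop", s2_on + pulse + 0.05, pulse,
                            GALLOP_FREQ_HZ, GALLOP_AMP)
            )
        elif spec.category == "A6":
            events.append(
                SourceEvent("murmur", t + pulse, systole - pulse, None,
                            MURMUR_RMS)
            )
        elif spec.category == "A7":
            dur = max(cycle - systole - 2 * pulse, 0.0)
            events.append(
                SourceEvent("murmur", s2_on + pulse, dur, None, MURMUR_RMS)
            )
        elif spec.category == "A8":
            events.append(SourceEvent("murmur", t, cycle, None, MURMUR_RMS))
        t += cycle
    return events


def _raised_cosine(n: int) -> np.ndarray:
    # Hann window over the burst duration: smooth, leakage-limiting.
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1))


def _render_event(
    ev: SourceEvent, spec: PCGSpec, out: np.ndarray, rng: np.random.Generator
) -> None:
    fs = spec.sample_rate
    i0 = int(round(ev.onset_s * fs))
    n = int(round(ev.dur_s * fs))
    if n <= 0 or i0 >= out.size:
        return
    n = min(n, out.size - i0)
    if ev.freq_hz is not None:
        t = np.arange(n) / fs
        burst = ev.amp * _raised_cosine(n) * np.sin(2.0 * np.pi * ev.freq_hz * t)
    else:
        lo, hi = spec.murmur_band
        noise = rng.standard_normal(n)
        sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos", fs=fs)
        noise = sps.sosfiltfilt(sos, noise)
        rms = float(np.sqrt(np.mean(noise**2)))
        if rms > 0:
            noise *= ev.amp / rms
        ramp = int(round(0.02 * fs))  # 20 ms on/off ramps
        env = np.ones(n)
        if n > 2 * ramp:
            edge = _raised_cosine(2 * ramp)
            env[:ramp] = edge[:ramp]
            env[-ramp:] = edge[ramp:]
        burst = noise * env
    out[i0 : i0 + n] += burst


def render_clean(spec: PCGSpec) -> Tuple[np.ndarray, List[SourceEvent]]:
    """Render the noise-free signal and its event schedule.

    The murmur noise (part of the heart sound itself) is included; only the
    additive white background noise is left out.
    """
    rng = np.random.default_rng(spec.seed)
    events = _schedule(spec, rng)
    out = np.zeros(int(round(spec.duration_s * spec.sample_rate)))
    for ev in events:
        _render_event(ev, spec, out, rng)
    return out, events


def lifted_bin(k0: int, bin_hz: float, scfg: ShiftConfig) -> Tuple[int, int]:
    """Closed-form mirror of the shifting policy on integer bin indices.

    Returns (final bin, applications).  Because the spectral remap moves bin
    k to round(k·2^(s/12)) and is injective and magnitude-preserving for
    s >= 0, the transcriber's re-estimated dominant bin after each shift
    equals this recurrence — making it an independent arithmetic oracle for
    the DSP chain.
    """
    f0 = k0 * bin_hz
    min_apps = 2 if f0 < scfg.very_low_hz else 0
    k, napps = k0, 0
    while napps < scfg.max_applications and (
        napps < min_apps or k * bin_hz < scfg.trigger_hz
    ):
        k = int(math.floor(k * scfg.factor + 0.5))
        napps += 1
    return k, napps


def ground_truth(
    clean: AudioSignal,
    cfg: TranscriptionConfig,
    events: List[SourceEvent],
    category: str,
) -> GroundTruth:
    """Label every analysis window of the clean signal with its true pitch.

    The clean signal is filtered and gated exactly as the transcriber
    publishes; each surviving window's dominant bin (rfft argmax over the
    1–500 Hz band, ties to the lower bin) is then lifted by the closed-form
    recurrence and quantized.  Silent windows are rests (pitch 0).
    """
    filtered = lowpass_filter(clean, cfg.preprocess)
    gated = amplitude_reconstruct(filtered, cfg.preprocess)
    n = window_length(clean.sample_rate, cfg.pitch.window_ms)
    n_windows = gated.samples.size // n
    bin_hz = clean.sample_rate / n
    k_lo = max(int(math.ceil(cfg.pitch.f_min / bin_hz)), 1)
    k_hi = min(int(math.floor(cfg.pitch.f_max / bin_hz)), (n - 1) // 2)
    pitches = np.zeros(n_windows, dtype=np.int64)
    for i in range(n_windows):
        w = gated.samples[i * n : (i + 1) * n]
        if math.sqrt(float(np.mean(w**2))) < cfg.pitch.silence_epsilon:
            continue
        mags = np.abs(np.fft.rfft(w))
        k0 = k_lo + int(np.argmax(mags[k_lo : k_hi + 1]))
        k_final, _ = lifted_bin(k0, bin_hz, cfg.shift)
        pitches[i] = pitch_number(k_final * bin_hz, cfg.pitch.ref_freq)
    return GroundTruth(
        pitches=pitches,
        window_ms=cfg.pitch.window_ms,
        events=tuple(events),
        category=category,
        config=cfg,
    )


def generate(
    spec: PCGSpec, cfg: Optional[TranscriptionConfig] = None
) -> Tuple[AudioSignal, GroundTruth]:
    """Generate a labelled synthetic PCG record.

    Returns the (possibly noisy) audio and the ground truth computed on the
    noise-free version under ``cfg`` (default configuration if omitted).
    Deterministic given ``spec.seed``.
    """
    if cfg is None:
        cfg = TranscriptionConfig()
    clean_samples, events = render_clean(spec)
    clean = AudioSignal(clean_samples, spec.sample_rate)
    truth = ground_truth(clean, cfg, events, spec.category)
    if spec.noise_level > 0:
        # separate stream so the schedule/murmur draw is noise-independent
        noise_rng = np.random.default_rng((spec.seed, 0xA5))
        noisy = clean_samples + spec.noise_level * noise_rng.standard_normal(
            clean_samples.size
        )
        signal = AudioSignal(noisy, spec.sample_rate)
    else:
        signal = clean
    return signal, truth
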