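# Methods

## Signal model and pipeline

A phonocardiogram is treated as a monophonic source: at most one dominant
spectral component per analysis window.  Heart-sound pulses (S1, S2) last
roughly 100 ms with fundamentals between 20 and 150 Hz, so a window of
100–500 ms captures at most one pulse in normal rhythm and the useful
spectrum sits below 250 Hz.  The pipeline is

    low-pass filter → amplitude gate → window → [estimate → shift* → re-estimate] → quantize

with one pitch byte per window and pitch 0 reserved for rests.

### Low-pass filter

Elliptic IIR designed from the spec (passband edge 250 Hz, stopband edge
400 Hz, 0.5 dB passband ripple, 40 dB stopband attenuation per pass),
applied forward–backward in batch mode (zero phase, so pulse timing is
preserved; net ≤ 1 dB ripple, ≥ 80 dB stopband) and forward-only in
streaming mode (≥ 40 dB).  The filter family and stopband depth are this
package's choices; only the two edge frequencies are inherent to the
method.

### Amplitude gate ("amplitude reconstruction")

Every sample with `|x| < T·A_max` is zeroed, `T = 0.6` by default.  Gating
is realized as a hard zeroing rule because the method's description calls
for *eliminating* low-magnitude content; it is idempotent, and raising `T`
never increases the number of surviving samples.  `A_max` is the global
maximum in batch mode and a causal rolling 2 s maximum in streaming mode
(the rolling span covers ≥ 2 cardiac cycles at normal heart rates, so the
two agree on steady signals).  The threshold compares `|x|`, not an
envelope.

### Spectrum and dominant frequency

Plain FFT of each window — deliberately no taper: the method defines the
distribution on the raw window, and the band restriction plus gating stand
in for leakage control.  The dominant frequency is the largest-magnitude
bin with `f_min = 1 ≤ k·Δf ≤ f_max = 500` Hz (DC excluded); ties break
toward the lower bin because heart-sound fundamentals sit below their
harmonics.  No zero-padding or peak interpolation: resolution is `fs/N`
(4 Hz at 250 ms, 8 kHz), which suffices for integer-semitone decisions
once the shifting step has lifted everything above ~100 Hz.  A window
whose RMS falls below `1e-6` of full scale is a rest — the rule (and the
epsilon) are this package's convention, since a no-signal window has no
defined transcription otherwise.

### Frequency shifting

A semitone shift is multiplicative in Hz (`2^(s/12)`; one octave doubles
the frequency), implemented as integer bin remapping
`k → round(k·2^(s/12))` on the positive-frequency half, with colliding
destinations accumulated, destinations at or beyond Nyquist discarded, and
conjugate symmetry restored before the inverse FFT.  Two useful properties
follow for `s ≥ 0` (factor ≥ 1):

* the map is **injective** (distinct sources cannot collide), and
* magnitudes are preserved bin-for-bin,

so the spectral argmax moves exactly with the remap:
`argmax(shifted) = round(argmax(original)·2^(s/12))` whenever the remapped
peak stays inside the search band.  The policy: estimate; while the
estimate is below the 100 Hz trigger (and fewer than `max_applications=4`
shifts have run), shift, invert, re-estimate.  An *original* estimate
below 50 Hz receives at least two applications before the trigger test —
the original-estimate reading of the very-low rule is this package's
resolution of an ambiguity, as is the termination cap.  If the cap is hit
below the trigger, the event is flagged unresolved and quantized from the
last estimate.  The full spectrum is remapped (not only the sub-trigger
band), and the gate is not re-applied to the shifted frame.

### Pitch quantization

`N(p) = round(40·log10(f/261.6) + 60)`, half-away-from-zero, clamped to
[1, 127].  The logarithm must be base-10 for a doubling to add ≈ 12.
Because `40·log10(2) = 12.041`, doubling adds 13 instead of 12 at the 8
integer frequencies in 20–250 Hz whose fractional pitch lies within 0.041
below a half-step boundary (38, 85, 90, 101, 107, 120, 160, 226 Hz); the
octave-law tests document this exception set exactly.

## Synthetic phonocardiograms

The generator emulates the eight studied categories as event schedules:
100 ms raised-cosine sine bursts for S1 (120 Hz, amplitude 1.0) and S2
(80 Hz, 0.8) with a 300 ms S1→S2 interval at 70 bpm; category-specific
additions (split S2 as two 40 ms sub-bursts 60 ms apart; 30 ms 200 Hz
clicks; a 40 Hz gallop pulse at 0.7; band-limited 100–240 Hz murmur noise
at 0.12 RMS filling systole, diastole or the whole cycle); ±2 % cycle
jitter so pulses do not phase-lock to the window grid; additive white
noise at a configurable level.  Pulse fundamentals are multiples of 4 Hz
(on-grid at the default window), and source amplitudes were chosen so the
default 0.6 gate keeps pulses, clicks and gallops but removes murmur noise
— deliberately unambiguous scenes.  All randomness flows from one seed.

**Ground truth** is defined operationally under a stated configuration
(the default unless a sweep varies the window size): the *clean* signal is
filtered and gated exactly as the published preprocessing does, each
surviving window's dominant bin is measured by an rfft argmax, and the
pitch is obtained by the **closed-form integer recurrence**
`k ← round(k·2^(f_sh/12))` mirroring the shift policy — never by running
the spectral remap/inverse-FFT machinery itself.  By the argmax-commutation
property above, a correct implementation must agree with this arithmetic
on every window of a noise-free record; that is precisely what the
clean-limit acceptance test asserts for all eight categories, making it a
genuine dual-route check of the shifting chain rather than a circular one.

What this truth does *not* model: a human-labelled "correct note" for real
recordings.  In particular, with analysis-based truth aligned to each
window size, the accuracy loss of large (500 ms) windows against
event-level truth is only partially reproduced, and passing tests say
nothing about cardiologist-validated labels on clinical data.  Real PCGs
also differ in pulse morphology, heart-rate variability, sensor coloration
and non-white noise.

## Evaluation

Accuracy is exact per-window match including rests,
`P_acc = 100·n_t/N`.  The standard cohort is 3 replicates × 8 categories
× 10 s with white noise at 0.15 of the S1 peak and a fixed seed table
(base 20110) — 24 records, keeping each sweep under a few seconds while
preserving the qualitative orderings of interest.  Ground truth is always
computed under the default configuration, so sweeps measure genuine
departures from the working point: lower gate thresholds admit envelope
slivers and murmur noise the reference gate removed (accuracy rises with
`T`); non-default shifts land lifted pulses on different pitches than the
default lift (14 semitones is best by construction of the reference); for
the window sweep, truth is re-aligned to each window size.  The streaming
mode is scored identically and differs from batch only through the causal
filter and rolling maximum.

## Numerical choices

* Rounding is half-away-from-zero everywhere a rounding rule matters
  (pitch quantization, bin remapping, window length), keeping the
  implementation and the closed-form oracle in lock-step.
* Spectral ties break to the lower frequency; `np.argmax`'s first-maximum
  behavior implements this on the ascending bin order.
* The byte-stream format is headerless by design (exactly one byte per
  window); configuration travels in a JSON sidecar.  MIDI export fixes
  tempo at 120 bpm so a 250 ms window is an eighth note; other window
  sizes scale the tick count proportionally.
* Degenerate inputs: records shorter than one window produce an empty
  transcript with a warning; all-zero records transcribe to all rests; an
  all-zero record passes the gate unchanged (`A_max = 0`).

## Known limitations

* Monophonic by construction: windows containing two comparable sources
  (e.g. a pulse straddling a window boundary next to another pulse) are
  labelled by whichever dominates the gated spectrum.
* Severely gated slivers of a pulse can present a near-DC spectrum whose
  dominant bin lifts to an unresolved sub-trigger estimate; such windows
  are flagged and quantized from the last estimate — both the pipeline and
  the truth treat them identically.
* The streaming path emulates real-time processing in software; it does
  not model fixed-point arithmetic or hardware latency.
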