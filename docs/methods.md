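# Methods

## Filter model

The feed-forward comb (FFC) filter is the two-tap FIR
`y(k) = x(k) + α·x(k−N)`.  For `α = ±1` its minima are true nulls:

* `α = −1`: `|H(f_n)| = 2|sin(π N f_n)|`, nulls at `k·fs/N` (DC
  included), −3 dB crossings at `(1/4 + k)·fs/N` and `(3/4 + k)·fs/N`;
* `α = +1`: `|H(f_n)| = 2|cos(π N f_n)|`, nulls at odd multiples of
  `fs/(2N)` — this variant leaves even harmonics untouched and is kept
  only for response analysis.

Setting `N = fs/f_pli` (an exact integer: 20 at 1 kHz for 50 Hz, 20 at
1.2 kHz for 60 Hz) places nulls on the mains fundamental and every
harmonic, while the zero DC gain and the 12.5 Hz (resp. 15 Hz) lower
cutoff suppress offsets and baseline wander.  A non-integer `fs/f_pli`
is a hard error rather than a rounding: a rounded delay moves the nulls
off the harmonics and silently destroys cancellation, so the error
message names the nearest admissible sampling frequencies instead.
`ffc_apply` accepts arbitrary real `α` (the general difference
equation) but the closed-form analysis is restricted to ±1.

Initial state is zero-padded: the first `N` outputs pass the input
through unchanged (`α = −1`), exactly as a streaming implementation
with a cleared delay buffer behaves.  Evaluation discards a start-up
transient anyway (below).

## Envelope extraction

The linear envelope is full-wave rectification followed by a causal
moving average with zero-padded history (not centered — this matches
the streaming implementation; offline comparisons re-align by
cross-correlation, so the group delay is immaterial).  The −3 dB cutoff
of a W-sample mean solves `|sin(πWf/fs)/(W sin(πf/fs))| = 1/√2`,
bracketed in `(0, fs/W)` and solved by Brent's method to 1e−6 Hz.  The
offline window of 88 samples at 1 kHz gives 5.03 Hz ("the 5 Hz
setting"); the real-time window of 128 samples gives 3.46 Hz, commonly
quoted as "about 4 Hz" — the package always reports the computed value.
Block mode averages non-overlapping power-of-two windows (one output
per window, rate `fs/window` ≈ 7.8 Hz at 1 kHz/128), which is what lets
the integer pipeline divide by shifting.

## Comparison denoisers

*FilterDxN*: `y(k) = x(k) − (1/Nf)·Σ_{i<Nf} x(k − i·D)` — subtraction
of a comb-spaced Nf-point mean.  The original publication's exact
difference equation is not reprinted here; this form is adopted because
it is the unique simple integer-coefficient comb that exhibits zeros at
every multiple of `fs/D` *and* reproduces the published per-sample
costs (17 additions = 16 for the sum + 1 subtraction, 1 division,
`D·(Nf−1)+1 = 321` stored samples for the 20×17 configuration).

*FFT block filter*: non-overlapping blocks of `fs/resolution` samples
(40 at 1 kHz for 25 Hz bins) are transformed with the real FFT; DC, the
bins covering the 0–25 Hz artifact band, and every bin on a 50 Hz
harmonic are zeroed (conjugate symmetry is implicit in the real FFT, so
the output is real to machine precision); the block is inverse
transformed.  Block processing, rather than a sliding transform, is the
variant whose latency motivates the small 40-sample design.  A trailing
partial block cannot be transformed at the design resolution and is
passed through unfiltered with a logged warning.

Resource accounting is analytic per output sample: FFC (1, 0, 0,
memory N), DxN (Nf, 0, 1, memory `D(Nf−1)+1`), FFT (the
`(block/2)·log₂(block)` complex-multiply lower bound ≈ 106 for a
40-sample block, reported for both additions and multiplications;
memory = block).  The integer streaming pipeline is additionally
instrumented so the zero-multiplication, zero-division claim is
counted, not asserted.

## Synthetic data

Real sEMG recordings are not redistributable, so the evaluation runs on
surrogates that reproduce the features a comb filter interacts with:

* **EMG** — zero-mean Gaussian noise band-passed to 20–450 Hz
  (4th-order Butterworth, forward-backward), amplitude-modulated by
  alternating rest/contraction segments: durations uniform in 0.5–2 s,
  plateau amplitudes uniform in 0.5–1 (relative), rest level 0.05,
  raised-cosine ramps of 0.2 s.  Sampling below 1 kHz is rejected
  (Nyquist would clip the EMG band).
* **PLI** — harmonics of 50 (or 60) Hz up to 500 Hz with 1/h amplitude
  decay and seeded uniform phases (measured mains spectra fall roughly
  inversely with harmonic order; the true amplitudes/phases of any
  particular lab are unknowable, so they are configurable).  Modulated
  PLI multiplies by `1 + depth·sin(2π f_mod t)` with defaults
  f_mod = 0.5 Hz, depth = 0.5 — a "slow sinewave" of substantial depth.
* **Motion artifacts** — Gaussian noise low-passed at 4 Hz (4th-order
  Butterworth, forward-backward): baseline wander concentrated well
  below the comb's 12.5 Hz cutoff, configurable up to 30 Hz for stress
  tests.

SNR is the linear mean-square power ratio over the whole record, and
mixing is exact: the noise is scaled so the post-mix ratio equals the
request to machine precision.

What the surrogates do **not** model: motor-unit action-potential
structure, electrode-skin impedance, non-stationary contraction
spectra, brisk artifact transients with energy inside the comb
pass-bands, and any specific laboratory's harmonic profile.  Passing
recovery bounds on these surrogates therefore demonstrates the filter's
behavior under the modeled noise classes, not third-decimal agreement
with any particular real recording.

## Evaluation protocol

For each (corruption kind, SNR, seed): generate 30 s of clean EMG at
1 kHz, mix noise at the target SNR, filter, compute 88-sample envelopes
of clean and processed signals, discard the first
`max(filter memory, window) + 1000` samples (start-up bias), re-align
at the lag of the full cross-correlation maximum, and take the Pearson
correlation of the overlap.  The SNR grid is
{0.05, 0.1, 0.2, 0.5, 1, 2, 5, 7, 10}; each point is replicated over
five seeds to quantify surrogate variability.  "Correlation gain" is
the ratio of filtered to noisy correlation; on heavily
artifact-corrupted records the noisy correlation can reach zero (the
noisy envelope becomes uncorrelated with the truth), where the ratio is
numerically meaningless — tests therefore assert the equivalent bound
`r_filtered ≥ 2·r_noisy` instead of dividing.

## Real-time emulation

The streaming pipeline consumes 10-bit unipolar ADC codes: per sample,
comb difference from an N-slot ring buffer, absolute value,
accumulation; every 128 samples, emit `accumulator >> 7`.  The shift
truncates toward zero (the accumulator is nonnegative, so truncation
equals floor), which bounds the divergence from exact arithmetic at one
code per envelope sample.  The accumulator must hold
`128 · 1023 < 2¹⁷`, so 20-bit intermediates suffice on a
microcontroller; Python integers satisfy this trivially.  Transport,
timers and board I/O are out of scope: the contract is a strictly
uniformly sampled code stream.

## Numerical choices and limitations

* Frequency boundary comparisons (nulls/cutoffs at `f_max`) use a
  1e−9 Hz tolerance; boundary values are included.
* Problem sizes in the shipped experiments (30 s records, five seeds)
  keep the full protocol in the low seconds while leaving the minima
  stable to the third decimal across seed sets.
* The package filters single channels; multi-channel, adaptive PLI
  tracking, phase-response analysis and RMS-window envelopes are out of
  scope.
* The comb is unsuitable as a general biosignal denoiser (ECG/EEG
  fundamentals fall inside its high-pass stopband) and for diagnostic
  EMG, where its wide stop-bands distort waveform morphology; its claim
  is envelope preservation only.
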