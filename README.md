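# emgcomb

Feed-forward comb filtering and multiplication-free linear-envelope
extraction for surface electromyography (sEMG).

## The problem

Human–machine interfaces driven by muscle activity rarely use the raw
EMG waveform; they use its **linear envelope** (EMG-LE): full-wave
rectification followed by low-pass filtering at a few hertz.  Raw sEMG,
however, is corrupted by **powerline interference** (a 50/60 Hz sinewave
plus higher harmonics, often larger than the signal itself) and by
**motion artifacts** (baseline wander below ~20–30 Hz from
electrode–skin motion).  Both leak straight into the envelope and
produce spurious "contractions".  Sophisticated denoisers exist, but
battery-powered wearables built on small microcontrollers cannot afford
them.

## The method

A single **feed-forward comb (FFC) filter**,

```
y(k) = x(k) + α·x(k − N),        α = −1,  N = fs / f_pli
```

has amplitude response `|H(f)| = 2·|sin(π N f / fs)|`: nulls at DC and
at **every** integer multiple of `fs/N = f_pli`.  One subtraction per
sample therefore removes, jointly:

* the powerline fundamental and all its harmonics,
* any DC offset (e.g. the mid-scale bias of a unipolar ADC),
* the low-frequency motion-artifact band (−3 dB below `f_pli/4`,
  i.e. 12.5 Hz for 50 Hz mains at 1 kHz).

The comb's stop-bands distort the EMG *waveform*, but the *envelope* —
the quantity an HMI consumes — survives almost untouched.  Downstream,
rectification plus a moving average of power-of-two length turns the
normalizing division into a bit shift, so the whole pipeline runs with
integer additions, absolute values and shifts only: zero
multiplications, zero divisions.

The package provides:

* `comb` — the FFC filter and its closed-form response, nulls and
  −3 dB cutoffs;
* `envelope` — rectify + moving average (sliding, or block-decimated
  with shift division), plus the exact MA cutoff solver;
* `baselines` — two comparison denoisers (the high-Q integer comb
  *FilterDxN* and a block-FFT bin-zeroing filter) with analytic
  per-sample resource accounting;
* `synth` — seeded generators for surrogate EMG, harmonic-rich
  (optionally amplitude-modulated) powerline interference, motion
  artifacts, exact linear-SNR mixing, and 10-bit unipolar ADC emulation;
* `evaluate` — the envelope-fidelity protocol (cross-correlation
  re-alignment + Pearson correlation) and SNR-sweep experiments;
* `realtime` — an integer-only streaming emulation of the
  microcontroller pipeline with an arithmetic audit;
* `emgcomb` CLI — `simulate`, `filter`, `envelope`, `stream`,
  `evaluate` subcommands over single-channel CSV files
  (header `# fs=<Hz>`, one sample per line).

## Worked example

Corrupt 10 s of surrogate EMG with amplitude-modulated powerline
interference at a linear SNR of 0.05 (noise power 20× signal power),
filter with the matched comb, and score the recovered envelope:

```python
from emgcomb import *

clean = synth_emg(10.0, 1000.0, seed=1)
pli = synth_pli(10.0, 1000.0, PLISpec.default(50.0, seed=1, modulation=(0.5, 0.5)))
noisy, scale = mix_at_snr(clean, pli, 0.05)
filtered = ffc_apply(noisy, FFCParams(N=ffc_delay(1000, 50), alpha=-1, fs=1000))

print(f"envelope correlation, noisy    : {envelope_fidelity(clean, noisy):.4f}")
print(f"envelope correlation, filtered : {envelope_fidelity(clean, filtered, filter_memory=20):.4f}")
```

prints

```
envelope correlation, noisy    : 0.3313
envelope correlation, filtered : 0.9917
```

Under noise twenty times stronger than the signal, the noisy envelope
correlates with the true envelope at only r = 0.33, while one
subtraction per sample recovers it to r = 0.99.

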