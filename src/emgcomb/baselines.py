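"""Comparison denoisers and per-algorithm resource accounting.

Two literature baselines are provided for benchmarking against the FFC
filter:

* ``FilterDxN`` — a high-Q integer-coefficient comb: the input minus the
  mean of ``Nf`` samples spaced ``D`` apart.  With ``D = fs / f_pli`` its
  zeros fall on DC and every multiple of ``f_pli``; the narrow teeth
  (quality factor grows with ``Nf``) preserve more EMG bandwidth than the
  FFC at the price of ``Nf`` additions, one division and
  ``D*(Nf-1)+1`` stored samples per output.
* FFT block filter — non-overlapping blocks of ``fs / resolution``
  samples are transformed, the bins on the powerline harmonics and in
  the low-frequency artifact band are zeroed (with their conjugate
  partners), and the block is inverse-transformed.

``resource_profile`` returns the analytic per-output-sample operation
and memory counts for every algorithm in the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .signal import Signal

__all__ = [
    "DxNParams",
    "FFTFilterParams",
    "ResourceProfile",
    "filter_dxn",
    "fft_block_filter",
    "default_zero_bins",
    "fft_block_size",
    "resource_profile",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DxNParams:
    """FilterDxN configuration: tooth spacing D (= fs/f_pli) and tap count Nf."""

    D: int = 20
    Nf: int = 17

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("D must be >= 1")
        if self.Nf < 2:
            raise ValueError("Nf must be >= 2")

    @property
    def memory_samples(self) -> int:
        """Input samples that must be held: D*(Nf-1)+1 (321 for 20x17)."""
        return self.D * (self.Nf - 1) + 1


@dataclass(frozen=True)
class FFTFilterParams:
    """Block-FFT filter configuration.

    block : samples per transform (``fs / resolution``; 40 gives 25 Hz
    bins at 1 kHz).  zero_bins : non-negative bin indices to cancel;
    conjugate-symmetric partners are cancelled implicitly so the output
    stays real.
    """

    block: int = 40
    zero_bins: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.block < 2:
            raise ValueError("block must be >= 2")
        bins = frozenset(int(b) for b in self.zero_bins)
        if any(b < 0 or b > self.block // 2 for b in bins):
            raise ValueError("zero_bins must lie in {0 .. block/2}")
        object.__setattr__(self, "zero_bins", bins)


@dataclass(frozen=True)
class ResourceProfile:
    """Per-output-sample arithmetic counts and memory footprint in samples."""

    additions: int
    multiplications: int
    divisions: int
    memory: int

    def __post_init__(self) -> None:
        if min(self.additions, self.multiplications, self.divisions, self.memory) < 0:
            raise ValueError("resource counts must be nonnegative")


def filter_dxn(x: Signal, p: DxNParams = DxNParams()) -> Signal:
    """Apply FilterDxN: ``y(k) = x(k) - (1/Nf) * sum_i x(k - i*D)``.

    History is zero-padded; the transient lasts ``D*(Nf-1)`` samples.
    """
    b = np.zeros(p.memory_samples)
    b[:: p.D] -= 1.0 / p.Nf
    b[0] += 1.0
    y = lfilter(b, [1.0], np.asarray(x.samples, dtype=float))
    return x.with_samples(y)


def default_zero_bins(block: int, fs: float, f_pli: float = 50.0,
                      artifact_max_hz: float | None = None) -> frozenset:
    """Bins to cancel: the low-frequency artifact band plus every PLI harmonic.

    With the default ``artifact_max_hz`` of one bin width (25 Hz for a
    40-sample block at 1 kHz) this zeroes DC, the first bin, and bins
    2, 4, ..., block/2 — i.e. the 0–25 Hz range and all 50 Hz harmonics
    up to Nyquist.
    """
    resolution = fs / block
    if artifact_max_hz is None:
        artifact_max_hz = resolution
    bins = {b for b in range(block // 2 + 1) if b * resolution <= artifact_max_hz + 1e-9}
    h = 1
    while h * f_pli <= fs / 2 + 1e-9:
        ratio = h * f_pli / resolution
        if abs(ratio - round(ratio)) < 1e-9:
            bins.add(round(ratio))
        h += 1
    return frozenset(bins)


def fft_block_size(fs: float, resolution: float = 25.0) -> int:
    """Samples per transform for a requested bin width: ``fs / resolution``."""
    block = fs / resolution
    if abs(block - round(block)) > 1e-9 or block < 2:
        raise ValueError(f"fs/resolution = {block:.6g} is not an integer block size")
    return round(block)


def fft_block_filter(x: Signal, p: FFTFilterParams) -> Signal:
    """Spectral-zeroing block filter.

    Consecutive non-overlapping blocks are FFT'd, the configured bins
    (plus conjugate partners, via the real FFT) are set to zero, and the
    block is inverse-transformed.  A trailing partial block is passed
    through unfiltered with a logged warning.
    """
    samples = np.asarray(x.samples, dtype=float)
    if len(samples) < p.block:
        raise ValueError(f"signal shorter than one block ({len(samples)} < {p.block})")
    n_blocks = len(samples) // p.block
    head = samples[: n_blocks * p.block].reshape(n_blocks, p.block)
    spec = np.fft.rfft(head, axis=1)
    spec[:, sorted(p.zero_bins)] = 0.0
    out = np.fft.irfft(spec, n=p.block, axis=1).ravel()
    tail = samples[n_blocks * p.block:]
    if tail.size:
        logger.warning(
            "trailing partial block of %d samples passed through unfiltered", tail.size
        )
        out = np.concatenate([out, tail])
    return x.with_samples(out)


def resource_profile(algorithm: str, params=None) -> ResourceProfile:
    """Analytic per-output-sample resource counts.

    * ``ffc``: one subtraction, no multiplications/divisions, N stored
      samples (20 for 50 Hz PLI at 1 kHz).
    * ``dxn``: Nf additions (Nf-1 for the comb sum plus the final
      subtraction), one division, ``D*(Nf-1)+1`` stored samples
      (17 / 1 / 321 for Filter20x17).
    * ``fft``: superlinear — the (block/2)*log2(block) complex-multiply
      lower bound of an FFT is reported for both additions and
      multiplications; memory equals the block length.
    * ``ma-envelope``: running-sum update (add newest, drop oldest) and
      either one division (sliding) or a shift (power-of-2 block mode,
      counted as zero divisions).
    """
    from .comb import FFCParams
    from .envelope import EnvelopeConfig

    if algorithm == "ffc":
        p = params if params is not None else FFCParams(N=20)
        return ResourceProfile(additions=1, multiplications=0, divisions=0, memory=p.N)
    if algorithm == "dxn":
        p = params if params is not None else DxNParams()
        return ResourceProfile(
            additions=p.Nf, multiplications=0, divisions=1, memory=p.memory_samples
        )
    if algorithm == "fft":
        p = params if params is not None else FFTFilterParams()
        bound = math.floor(p.block / 2 * math.log2(p.block))
        return ResourceProfile(
            additions=bound, multiplications=bound, divisions=0, memory=p.block
        )
    if algorithm == "ma-envelope":
        p = params if params is not None else EnvelopeConfig()
        divisions = 0 if p.mode == "block" else 1
        return ResourceProfile(
            additions=2, multiplications=0, divisions=divisions, memory=p.window
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")
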