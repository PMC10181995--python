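"""Feed-forward comb (FFC) filter and its closed-form frequency analysis.

The FFC filter is the two-tap FIR

    y(k) = x(k) + alpha * x(k - N)

With ``alpha = -1`` its amplitude response is ``2|sin(pi N f / fs)|``:
nulls fall on DC and on every integer multiple of ``fs / N``.  Choosing
``N = fs / f_pli`` therefore cancels the powerline fundamental and all
its harmonics while simultaneously suppressing DC offsets and the
low-frequency band where motion artifacts live — at the cost of a single
subtraction per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .signal import Signal

__all__ = [
    "FFCParams",
    "ffc_delay",
    "ffc_apply",
    "amplitude_response",
    "null_frequencies",
    "cutoff_frequencies",
]

#: absolute tolerance (Hz) for frequency boundary comparisons
_F_TOL = 1e-9


@dataclass(frozen=True)
class FFCParams:
    """FFC filter configuration.

    Parameters
    ----------
    N : int
        Delay in samples (>= 1).  For powerline cancellation use
        ``N = fs / f_pli`` exactly (see :func:`ffc_delay`).
    alpha : float
        Feed-forward coefficient.  The canonical choices are -1
        (nulls at multiples of ``fs/N``, including DC) and +1
        (nulls at odd multiples of ``fs/(2N)``).
    fs : float
        Sampling frequency in Hz.
    """

    N: int
    alpha: float = -1.0
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"delay N must be a positive integer, got {self.N}")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be finite and > 0, got {self.fs}")
        object.__setattr__(self, "N", int(self.N))
        object.__setattr__(self, "fs", float(self.fs))


def ffc_delay(fs: float, f_pli: float) -> int:
    """Delay ``N = fs / f_pli`` that places FFC nulls on every PLI harmonic.

    Parameters
    ----------
    fs : float
        Sampling frequency in Hz.
    f_pli : float
        Powerline fundamental in Hz (50 or 60 in practice).

    Returns
    -------
    int
        The exact integer ratio ``fs / f_pli``.

    Raises
    ------
    ValueError
        If the ratio is not an integer (within 1e-9).  Rounding N would
        shift the nulls off the powerline harmonics and silently degrade
        cancellation, so nearby admissible sampling frequencies are
        suggested instead.
    """
    if fs <= 0 or f_pli <= 0:
        raise ValueError("fs and f_pli must be positive")
    ratio = fs / f_pli
    n = round(ratio)
    if n < 1 or abs(ratio - n) > 1e-9:
        lo = int(np.floor(ratio)) * f_pli
        hi = int(np.ceil(ratio)) * f_pli
        raise ValueError(
            f"fs/f_pli = {ratio:.6g} is not an integer; an FFC filter cannot "
            f"null {f_pli:g} Hz at fs = {fs:g} Hz. Nearest admissible sampling "
            f"frequencies are {lo:g} Hz and {hi:g} Hz."
        )
    return int(n)


def ffc_apply(x: Signal, params: FFCParams) -> Signal:
    """Run the FFC difference equation over a signal.

    Uses zero initial state: for ``k < N`` the delayed term is taken as 0,
    matching a streaming implementation with a cleared delay buffer.
    Output length and sampling frequency equal the input's.
    """
    b = np.zeros(params.N + 1)
    b[0] = 1.0
    b[params.N] = params.alpha
    y = lfilter(b, [1.0], np.asarray(x.samples, dtype=float))
    return Signal(y, x.fs)


def amplitude_response(f_norm, N: int, alpha: int):
    """FFC amplitude response at normalized frequency ``f_norm = f / fs``.

    ``2|sin(pi N f_n)|`` for ``alpha = -1`` and ``2|cos(pi N f_n)|`` for
    ``alpha = +1``; the peak gain is exactly 2 in both cases.  Accepts
    scalars or arrays in [0, 0.5].
    """
    f_n = np.asarray(f_norm, dtype=float)
    if np.any(f_n < -_F_TOL) or np.any(f_n > 0.5 + _F_TOL):
        raise ValueError("normalized frequency must lie in [0, 0.5]")
    if alpha == -1:
        h = 2.0 * np.abs(np.sin(np.pi * N * f_n))
    elif alpha == 1:
        h = 2.0 * np.abs(np.cos(np.pi * N * f_n))
    else:
        raise ValueError("closed-form response is only provided for alpha = ±1")
    return h if h.ndim else float(h)


def null_frequencies(params: FFCParams, f_max: float) -> np.ndarray:
    """All response nulls in ``[0, f_max]``, ascending.

    alpha = -1: ``k * fs / N`` (DC included); alpha = +1: odd multiples of
    ``fs / (2N)``.  A null exactly at ``f_max`` is included (tolerance 1e-9 Hz).
    """
    if f_max > params.fs / 2 + _F_TOL:
        raise ValueError("f_max must not exceed the Nyquist frequency")
    spacing = params.fs / params.N
    if params.alpha == -1:
        k_max = int(np.floor((f_max + _F_TOL) / spacing))
        nulls = spacing * np.arange(k_max + 1)
    elif params.alpha == 1:
        half = spacing / 2.0
        k_max = int(np.floor((f_max + _F_TOL - half) / spacing))
        if f_max + _F_TOL < half:
            return np.array([])
        nulls = half + spacing * np.arange(k_max + 1)
    else:
        raise ValueError("null analysis is only provided for alpha = ±1")
    return nulls[nulls <= f_max + _F_TOL]


def cutoff_frequencies(params: FFCParams, f_max: float) -> np.ndarray:
    """All −3 dB frequencies of the alpha = −1 response in ``[0, f_max]``.

    Solutions of ``|sin(pi N f / fs)| = 1/sqrt(2)``: the two families
    ``(1/4 + k) fs/N`` and ``(3/4 + k) fs/N``.  Each cutoff sits exactly
    ``fs/(4N)`` away from its nearest null.
    """
    if params.alpha != -1:
        raise ValueError("cutoff analysis is only provided for alpha = -1")
    if f_max > params.fs / 2 + _F_TOL:
        raise ValueError("f_max must not exceed the Nyquist frequency")
    spacing = params.fs / params.N
    cutoffs = []
    for offset in (0.25, 0.75):
        k_max = int(np.floor((f_max + _F_TOL) / spacing - offset))
        if f_max + _F_TOL >= offset * spacing:
            cutoffs.append(spacing * (offset + np.arange(k_max + 1)))
    out = np.sort(np.concatenate(cutoffs)) if cutoffs else np.array([])
    return out[out <= f_max + _F_TOL]
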