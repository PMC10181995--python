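"""Uniformly sampled single-channel signal container.

The one carrier type shared by every stage of the package: raw EMG,
filtered EMG, envelopes and synthetic noise are all ``Signal`` objects
(a 1-D sample array plus a sampling frequency in Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Signal"]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued series.

    Parameters
    ----------
    samples : array-like of float
        Sample values; index ``k`` corresponds to time ``k / fs``.
    fs : float
        Sampling frequency in Hz, finite and strictly positive.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples)
        if arr.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {arr.shape}")
        if arr.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling frequency must be finite and > 0, got {self.fs}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample instants in seconds."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Signal":
        """A new signal with the same fs and different samples."""
        return Signal(samples, self.fs)
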