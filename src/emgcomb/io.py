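"""Signal readers and writers.

The canonical interchange format is a single-channel CSV: a header line
``# fs=<Hz>`` followed by one sample value per line.  Every experiment
in the package can be reproduced from such files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .signal import Signal

__all__ = ["read_signal", "write_signal"]


def read_signal(path) -> Signal:
    """Read a single-channel CSV signal.

    The first non-empty line must declare the sampling rate as
    ``# fs=<Hz>``; subsequent lines hold one sample each.
    """
    path = Path(path)
    with path.open() as fh:
        fs = None
        values = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("fs"):
                    _, _, rhs = body.partition("=")
                    fs = float(rhs.strip())
                continue
            values.append(float(line))
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=<Hz>' header; sampling rate unknown")
    return Signal(np.asarray(values), fs)


def write_signal(path, signal: Signal) -> None:
    """Write a signal in the CSV dialect read by :func:`read_signal`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={signal.fs:.10g}\n")
        for v in signal.samples:
            fh.write(f"{v:.12g}\n")
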