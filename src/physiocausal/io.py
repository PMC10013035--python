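"""Plain-text I/O: CSV signals, event-time lists and hypnogram files."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .physio import EventSeries, Hypnogram
from .signals import Signal

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_event_times",
    "read_hypnogram",
    "write_hypnogram",
]


def read_signal_csv(path, label: str = "") -> Signal:
    """Read a signal from a CSV with ``time_s`` and ``value`` columns.

    The sampling interval is inferred from the time column (which must be
    uniform); a single-column file is treated as values at 1 Hz.
    """
    df = pd.read_csv(path)
    if "value" in df.columns:
        values = df["value"].to_numpy(dtype=float)
    else:
        values = df.iloc[:, -1].to_numpy(dtype=float)
    dt = 1.0
    if "time_s" in df.columns and len(df) > 1:
        steps = np.diff(df["time_s"].to_numpy(dtype=float))
        if not np.allclose(steps, steps[0]):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        dt = float(steps[0])
    return Signal(values, dt=dt, label=label or str(path))


def write_signal_csv(signal: Signal, path) -> None:
    t = np.arange(signal.n) * signal.dt
    pd.DataFrame({"time_s": t, "value": signal.values}).to_csv(path, index=False)


def read_event_times(path) -> EventSeries:
    """Event times in seconds, one float per line."""
    times = np.loadtxt(path, dtype=float, ndmin=1)
    return EventSeries(times)


def read_hypnogram(path, rk: bool = False) -> Hypnogram:
    """One stage code per 30 s epoch per line; ``rk=True`` maps R&K numerals."""
    with open(path) as fh:
        codes = [line.strip() for line in fh if line.strip()]
    return Hypnogram.from_codes(codes, rk=rk)


def write_hypnogram(stages, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(stages) + "\n")
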