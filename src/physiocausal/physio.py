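"""Preprocessing of physiological recordings into 1 Hz node series.

Three channels form the node triple of the sleep network: instantaneous
heart rate H (inverse RR interval), instantaneous breathing rate B (inverse
interval between respiration extrema) and EEG alpha-band amplitude E.  Event
times (heart beats, breath extrema) are inputs — this module does no QRS or
extremum detection.  The 1 Hz series are then block-averaged to coarser
resolutions and partitioned into continuous same-sleep-stage patches, each
standardized to zero mean and unit variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import EPOCH_SECONDS, SLEEP_STAGES, Signal

__all__ = [
    "EventSeries",
    "Hypnogram",
    "StagePatch",
    "rate_from_events",
    "eeg_alpha_amplitude",
    "coarse_grain",
    "partition_by_stage",
]

logger = logging.getLogger(__name__)

ALPHA_BAND = (7.8, 15.6)  # EEG alpha frequency band, Hz

# Rechtschaffen-Kales numeric stages -> coarse codes: 1-2 light, 3-4 deep
RK_STAGE_MAP = {"0": "W", "1": "LS", "2": "LS", "3": "DS", "4": "DS", "5": "REM", "R": "REM", "W": "W"}


@dataclass(frozen=True)
class EventSeries:
    """Strictly increasing event times in seconds (>= 2 events)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2:
            raise ValueError("need at least two events")
        if np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")
        object.__setattr__(self, "times", t)


@dataclass(frozen=True)
class Hypnogram:
    """Sleep-stage codes, one per 30 s epoch."""

    stages: tuple

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        if not stages:
            raise ValueError("hypnogram is empty")
        bad = set(stages) - set(SLEEP_STAGES)
        if bad:
            raise ValueError(f"unknown stage codes: {sorted(bad)}")
        object.__setattr__(self, "stages", stages)

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> int:
        return len(self.stages) * EPOCH_SECONDS

    @classmethod
    def from_codes(cls, codes, rk: bool = False) -> "Hypnogram":
        """Build from raw codes; with ``rk=True`` maps R&K numerals 0-5/R/W."""
        codes = [str(c).strip() for c in codes if str(c).strip()]
        if rk:
            codes = [RK_STAGE_MAP[c] for c in codes]
        return cls(tuple(codes))


def rate_from_events(
    events: EventSeries | np.ndarray, label: str = "rate", kind: str = "linear"
) -> Signal:
    """Instantaneous event rate interpolated onto a 1 Hz grid.

    Each inter-event interval contributes a rate sample ``1/dt`` placed at
    the interval's closing event time; these are interpolated onto the
    integer-second grid spanned by the rate samples.  ``kind`` selects
    ``"linear"`` interpolation (default) or ``"previous"`` (zero-order
    hold).
    """
    if not isinstance(events, EventSeries):
        events = EventSeries(np.asarray(events, dtype=float))
    t = events.times
    rate_times = t[1:]
    rates = 1.0 / np.diff(t)
    grid = np.arange(np.ceil(rate_times[0]), np.floor(rate_times[-1]) + 1.0)
    if grid.size == 0:
        raise ValueError("events span less than one second of the 1 Hz grid")
    if kind == "linear":
        values = np.interp(grid, rate_times, rates)
    elif kind == "previous":
        idx = np.searchsorted(rate_times, grid, side="right") - 1
        values = rates[np.clip(idx, 0, rates.size - 1)]
    else:
        raise ValueError("kind must be 'linear' or 'previous'")
    return Signal(values, dt=1.0, label=label)


def eeg_alpha_amplitude(
    raw: Signal,
    fs: float | None = None,
    band: tuple[float, float] = ALPHA_BAND,
    method: str = "envelope",
    label: str = "E",
) -> Signal:
    """EEG alpha-band instantaneous amplitude averaged to 1 Hz.

    The raw EEG is band-passed (4th-order Butterworth, zero-phase
    forward-backward) to ``band``; the instantaneous amplitude is either the
    analytic-signal envelope (``method="envelope"``, default) or the
    rectified mean scaled by pi/2 (``method="rectified"``, which equals the
    amplitude for an in-band sinusoid); amplitudes are then averaged over
    non-overlapping 1 s windows.  The first and last output seconds carry
    filter edge effects.
    """
    if fs is None:
        fs = 1.0 / raw.dt
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for band {band}")
    n_sec = int(raw.n // fs)
    if n_sec < 2:
        raise ValueError("need at least two seconds of EEG")
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, raw.values)
    if method == "envelope":
        amplitude = np.abs(sps.hilbert(filtered))
    elif method == "rectified":
        amplitude = np.abs(filtered) * (np.pi / 2.0)
    else:
        raise ValueError("method must be 'envelope' or 'rectified'")
    per_sample = int(round(fs))
    usable = n_sec * per_sample
    values = amplitude[:usable].reshape(n_sec, per_sample).mean(axis=1)
    return Signal(values, dt=1.0, label=label)


def coarse_grain(x: Signal, factor: int) -> Signal:
    """Non-overlapping block means; the trailing remainder is dropped."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return x
    n_out = x.n // factor
    if n_out == 0:
        raise ValueError("series shorter than one block")
    values = x.values[: n_out * factor].reshape(n_out, factor).mean(axis=1)
    return Signal(values, dt=x.dt * factor, label=x.label)


@dataclass(frozen=True)
class StagePatch:
    """A maximal same-stage run with its standardized channel triple."""

    stage: str
    start: int  # sample index at the patch resolution
    end: int
    channels: tuple  # three Signals, standardized to mean 0 / variance 1

    @property
    def n(self) -> int:
        return self.end - self.start


def partition_by_stage(
    triple, hypnogram: Hypnogram, resolution: float = 1.0
) -> list[StagePatch]:
    """Cut a channel triple into continuous same-stage patches.

    Each maximal run of identical hypnogram stages becomes one patch; wake
    runs are excluded.  Within a patch every channel is standardized to zero
    mean and unit variance; a patch with a zero-variance channel is dropped
    with a warning.  ``resolution`` is seconds per sample of the triple
    (epochs are 30 s, so a run of k epochs spans ``30 k / resolution``
    samples).
    """
    signals = [s if isinstance(s, Signal) else Signal(np.asarray(s, float)) for s in triple]
    if len(signals) != 3:
        raise ValueError("expected a triple of three channels")
    n = signals[0].n
    if any(s.n != n for s in signals):
        raise ValueError("channels must have equal length")
    samples_per_epoch = EPOCH_SECONDS / resolution
    if n * resolution > hypnogram.duration:
        raise ValueError("hypnogram does not cover the series")
    patches: list[StagePatch] = []
    stages = hypnogram.stages
    run_start = 0
    for i in range(1, len(stages) + 1):
        if i < len(stages) and stages[i] == stages[run_start]:
            continue
        stage = stages[run_start]
        a = int(round(run_start * samples_per_epoch))
        b = min(int(round(i * samples_per_epoch)), n)
        run_start = i
        if stage == "W" or b <= a:
            continue
        chans = []
        for s in signals:
            seg = s.values[a:b]
            sd = seg.std()
            if sd == 0:
                logger.warning(
                    "dropping %s patch [%d:%d): zero variance in channel %s",
                    stage, a, b, s.label,
                )
                chans = None
                break
            chans.append(Signal((seg - seg.mean()) / sd, dt=resolution, label=s.label))
        if chans is not None:
            patches.append(StagePatch(stage, a, b, tuple(chans)))
    return patches
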