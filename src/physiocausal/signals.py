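"""Synthetic signal generators: 1/f^alpha noise and coupled benchmark systems.

The benchmark systems mix independent unit-variance 1/f^alpha noises with
time-lagged copies of a driver signal, so that the strength and direction of
every causal link is known by construction.  They are the ground truth against
which the Granger and BPRSA detectors are calibrated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Signal",
    "PairwiseSystemConfig",
    "CommonDriverConfig",
    "SleeperConfig",
    "StageParams",
    "fourier_filtered_noise",
    "pairwise_system",
    "common_driver_system",
    "synthetic_sleeper",
]

SLEEP_STAGES = ("W", "LS", "DS", "REM")
EPOCH_SECONDS = 30


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled time series.

    Parameters
    ----------
    values : ndarray
        Sample values; must be finite.
    dt : float
        Sampling interval in seconds (> 0).
    label : str
        Channel name, e.g. ``"H"`` for heart rate.
    """

    values: np.ndarray
    dt: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("Signal requires a 1-d array with at least one sample")
        if not np.all(np.isfinite(values)):
            raise ValueError("Signal values must be finite")
        if not self.dt > 0:
            raise ValueError("sampling interval dt must be positive")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    def with_values(self, values: np.ndarray) -> "Signal":
        return Signal(np.asarray(values, dtype=float), self.dt, self.label)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant series")
    return x / sd


def fourier_filtered_noise(
    n: int, alpha: float = 0.5, seed=None, label: str = "noise"
) -> Signal:
    """Gaussian 1/f^alpha noise generated by Fourier filtering.

    White Gaussian noise is transformed to the frequency domain, its spectral
    amplitudes are multiplied by ``f**(-alpha/2)`` (so the power spectrum
    follows ``1/f**alpha``), the zero-frequency component is set to zero, and
    the inverse transform is standardized to zero mean and unit sample
    variance.

    Parameters
    ----------
    n : int
        Number of samples (>= 2).
    alpha : float
        Spectral exponent (>= 0); ``alpha=0`` gives white noise.
    seed : int, SeedSequence or Generator, optional
        Source of randomness.
    """
    if n < 2:
        raise ValueError("need at least two samples")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.empty_like(freqs)
    scale[0] = 0.0  # no DC component
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    return Signal(_standardize(x), dt=1.0, label=label)


@dataclass(frozen=True)
class PairwiseSystemConfig:
    """Two-node benchmark: ``z`` drives ``x`` with strength ``q`` at a lag.

    ``z = o1`` and ``x_t = q * z_{t-lag} + (1-q) * o2_t`` with ``o1``, ``o2``
    independent unit-variance 1/f^alpha noises.
    """

    n: int
    q: float
    lag: int = 3
    alpha: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("coupling strength q must lie in [0, 1]")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if self.n <= self.lag:
            raise ValueError("series length must exceed the lag")


def _spawn_rngs(seed, k: int) -> list[np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(k)]


def pairwise_system(cfg: PairwiseSystemConfig) -> tuple[Signal, Signal]:
    """Simulate the two-node system; returns ``(z, x)`` of length ``cfg.n``.

    Both noises are generated with ``cfg.lag`` extra samples and the leading
    samples (where the lagged driver is undefined) are trimmed, so the
    returned series share one time grid and ``x[t] == z[t-lag]`` exactly when
    ``q == 1``.
    """
    rng_z, rng_x = _spawn_rngs(cfg.seed, 2)
    m = cfg.n + cfg.lag
    o1 = fourier_filtered_noise(m, cfg.alpha, rng_z, label="o1").values
    o2 = fourier_filtered_noise(m, cfg.alpha, rng_x, label="o2").values
    x_full = np.empty(m)
    x_full[cfg.lag:] = cfg.q * o1[: m - cfg.lag] + (1.0 - cfg.q) * o2[cfg.lag:]
    z = Signal(o1[cfg.lag:], label="z")
    x = Signal(x_full[cfg.lag:], label="x")
    return z, x


@dataclass(frozen=True)
class CommonDriverConfig:
    """Three-node benchmark: hidden driver ``y`` feeds ``z`` and ``x``.

    ``y = o2``; ``z_t = q_yz * y_{t-lag_yz} + (1-q_yz) * o1_t``;
    ``x_t = q_yx * y_{t-lag_yx} + (1-q_yx) * o3_t``.  There is no direct
    ``z -> x`` term: any apparent pairwise ``z -> x`` causality is indirect.
    The canonical setup uses ``lag_yx > lag_yz`` so the induced indirect link
    points from ``z`` to ``x``.
    """

    n: int
    q_yz: float
    q_yx: float
    lag_yz: int = 2
    lag_yx: int = 4
    alpha: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        for q in (self.q_yz, self.q_yx):
            if not 0.0 <= q <= 1.0:
                raise ValueError("coupling strengths must lie in [0, 1]")
        if min(self.lag_yz, self.lag_yx) < 0:
            raise ValueError("lags must be non-negative")
        if self.n <= max(self.lag_yz, self.lag_yx):
            raise ValueError("series length must exceed the largest lag")


def common_driver_system(cfg: CommonDriverConfig) -> tuple[Signal, Signal, Signal]:
    """Simulate the common-driver system; returns ``(x, y, z)`` of length n."""
    rng1, rng2, rng3 = _spawn_rngs(cfg.seed, 3)
    lag_max = max(cfg.lag_yz, cfg.lag_yx)
    m = cfg.n + lag_max
    o1 = fourier_filtered_noise(m, cfg.alpha, rng1, label="o1").values
    o2 = fourier_filtered_noise(m, cfg.alpha, rng2, label="o2").values
    o3 = fourier_filtered_noise(m, cfg.alpha, rng3, label="o3").values
    y = o2
    z = np.full(m, np.nan)
    x = np.full(m, np.nan)
    z[cfg.lag_yz:] = cfg.q_yz * y[: m - cfg.lag_yz] + (1.0 - cfg.q_yz) * o1[cfg.lag_yz:]
    x[cfg.lag_yx:] = cfg.q_yx * y[: m - cfg.lag_yx] + (1.0 - cfg.q_yx) * o3[cfg.lag_yx:]
    return (
        Signal(x[lag_max:], label="x"),
        Signal(y[lag_max:], label="y"),
        Signal(z[lag_max:], label="z"),
    )


# ---------------------------------------------------------------------------
# Synthetic "sleeper": three 1 Hz physiological-like channels with a
# stage-dependent coupling structure and piecewise-stationary segments.
# ---------------------------------------------------------------------------

CHANNELS = ("H", "B", "E")


@dataclass(frozen=True)
class StageParams:
    """Per-stage generative parameters for one synthetic sleeper.

    couplings maps a directed pair ``(source, target)`` over the channels
    H (heart rate), B (breathing rate), E (EEG alpha amplitude) to a
    ``(strength, lag)`` tuple; strengths into any one target must sum to at
    most 1, and the coupling graph must be acyclic.  ``mean`` and ``scale``
    offset and stretch each channel within the stage, so stage transitions
    introduce the mean/variance jumps that a stationarity splitter has to
    handle.
    """

    couplings: dict = field(default_factory=dict)
    mean: dict = field(default_factory=dict)
    scale: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SleeperConfig:
    stage_sequence: tuple = (("LS", 40), ("DS", 20), ("REM", 20), ("LS", 40))
    stage_params: dict = field(default_factory=dict)
    alpha: dict = field(default_factory=lambda: {c: 0.5 for c in CHANNELS})
    seed: int | None = None

    def __post_init__(self) -> None:
        for stage, n_epochs in self.stage_sequence:
            if stage not in SLEEP_STAGES:
                raise ValueError(f"unknown sleep stage code {stage!r}")
            if n_epochs < 1:
                raise ValueError("each stage segment needs at least one epoch")
        for stage, params in self.stage_params.items():
            total_in: dict = {}
            for (src, dst), (q, lag) in params.couplings.items():
                if src not in CHANNELS or dst not in CHANNELS or src == dst:
                    raise ValueError(f"invalid directed pair {(src, dst)!r}")
                if not 0.0 <= q <= 1.0 or lag < 0:
                    raise ValueError("coupling strength in [0,1], lag >= 0")
                total_in[dst] = total_in.get(dst, 0.0) + q
            if any(v > 1.0 + 1e-12 for v in total_in.values()):
                raise ValueError("incoming coupling strengths must sum to <= 1")

    @property
    def duration(self) -> int:
        return EPOCH_SECONDS * sum(n for _, n in self.stage_sequence)


def _topo_order(couplings: dict) -> list[str]:
    """Channels ordered so every coupling source precedes its target."""
    order: list[str] = []
    remaining = set(CHANNELS)
    while remaining:
        progressed = False
        for ch in sorted(remaining):
            if all(src in order for (src, dst) in couplings if dst == ch):
                order.append(ch)
                remaining.discard(ch)
                progressed = True
        if not progressed:
            raise ValueError("coupling graph contains a cycle")
    return order


def synthetic_sleeper(cfg: SleeperConfig) -> tuple[Signal, Signal, Signal, list[str]]:
    """Generate three coupled 1 Hz channels plus a 30 s-epoch hypnogram.

    Within each stage segment the channels follow the same lagged mixing form
    as the two-node benchmark: a target channel is ``q`` parts delayed source
    plus ``1-q`` parts own 1/f^alpha noise, with stage-specific strengths,
    then shifted/scaled by the stage's mean/scale offsets.  Couplings are
    rebuilt per segment from fresh noise, so causal structure is piecewise
    constant and segment boundaries carry distribution shifts.

    Returns ``(H, B, E, hypnogram)`` where the hypnogram holds one stage code
    per 30 s epoch.
    """
    ss = (
        cfg.seed
        if isinstance(cfg.seed, np.random.SeedSequence)
        else np.random.SeedSequence(cfg.seed)
    )
    seg_seeds = ss.spawn(len(cfg.stage_sequence))
    out = {c: [] for c in CHANNELS}
    hypnogram: list[str] = []
    for (stage, n_epochs), seg_ss in zip(cfg.stage_sequence, seg_seeds):
        n = n_epochs * EPOCH_SECONDS
        params = cfg.stage_params.get(stage, StageParams())
        lag_max = max((lag for (_, lag) in params.couplings.values()), default=0)
        rngs = dict(zip(CHANNELS, _spawn_rngs(seg_ss, len(CHANNELS))))
        noise = {
            c: fourier_filtered_noise(n + lag_max, cfg.alpha.get(c, 0.5), rngs[c]).values
            for c in CHANNELS
        }
        series: dict[str, np.ndarray] = {}
        for ch in _topo_order(params.couplings):
            incoming = [
                (src, q, lag)
                for (src, dst), (q, lag) in params.couplings.items()
                if dst == ch
            ]
            own = 1.0 - sum(q for _, q, _ in incoming)
            vals = own * noise[ch]
            for src, q, lag in incoming:
                shifted = np.empty_like(vals)
                if lag:
                    shifted[:lag] = series[src][:lag]  # pre-history padding
                    shifted[lag:] = series[src][:-lag]
                else:
                    shifted[:] = series[src]
                vals = vals + q * shifted
            series[ch] = vals
        for ch in CHANNELS:
            seg = series[ch][lag_max:]
            seg = params.mean.get(ch, 0.0) + params.scale.get(ch, 1.0) * seg
            out[ch].append(seg)
        hypnogram.extend([stage] * n_epochs)
    return (
        Signal(np.concatenate(out["H"]), dt=1.0, label="H"),
        Signal(np.concatenate(out["B"]), dt=1.0, label="B"),
        Signal(np.concatenate(out["E"]), dt=1.0, label="E"),
        hypnogram,
    )
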