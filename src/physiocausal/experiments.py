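"""Benchmark experiments: detection limits and region classification.

Two studies calibrate the detectors on systems with known ground truth:

* **Critical-coupling isolines** — on the two-node benchmark, for each
  series length N the smallest coupling strength q at which a detector's
  mean p-value (over realizations) drops below 0.05.  Detection succeeds
  above the isoline; a lower isoline means a more sensitive detector.
* **Region map** — on the common-driver system, each (q_yz, q_yx) cell is
  classified by the pairwise and conditional Granger F-tests: neither
  rejects (Region 1, couplings too weak), pairwise only (Region 2, the
  correct "indirect link" answer), both (Region 3, the indirect link is
  mistaken for a direct one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bprsa import bprsa_curve, bprsa_test, find_triggers
from .granger import g_conditional, g_pairwise
from .signals import CommonDriverConfig, PairwiseSystemConfig, common_driver_system, pairwise_system

__all__ = [
    "DETECTORS",
    "IsolineResult",
    "RegionMap",
    "pairwise_pvalues",
    "critical_q_from_pvalues",
    "isoline_study",
    "critical_isoline",
    "classify_realization",
    "region_map",
    "region2_boundary",
    "DEFAULT_Q_GRID",
]

DETECTORS = ("granger_f", "bprsa_ks1", "bprsa_ks2", "bprsa_ad", "bprsa_sw")
DEFAULT_Q_GRID = np.geomspace(0.005, 0.95, 24)
DEFAULT_ORDER = 5  # AR order; covers the benchmark lags up to 4
DEFAULT_L = 15  # BPRSA half-width (2L = 30)

REGION_LABELS = {1: "region1", 2: "region2", 3: "region3", 0: "inconsistent"}


def _cell_seed(master: int, *key: int) -> np.random.SeedSequence:
    """Independent, reproducible seed for one (N, q, realization) cell."""
    return np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))


def pairwise_pvalues(
    detectors,
    n: int,
    q: float,
    seed: np.random.SeedSequence,
    order: int = DEFAULT_ORDER,
    L: int = DEFAULT_L,
    lag: int = 3,
    alpha: float = 0.5,
) -> dict[str, float]:
    """p-values of the requested detectors on one two-node realization.

    All detectors see the same realization; the BPRSA curve is computed once
    and shared between its tests.
    """
    sim_seed, test_seed = seed.spawn(2)
    z, x = pairwise_system(PairwiseSystemConfig(n=n, q=q, lag=lag, alpha=alpha, seed=sim_seed))
    out: dict[str, float] = {}
    bprsa_wanted = [d for d in detectors if d.startswith("bprsa_")]
    if "granger_f" in detectors:
        out["granger_f"] = g_pairwise(x, z, p=order).p_value
    if bprsa_wanted:
        curve = bprsa_curve(x, find_triggers(z), L=L, trigger_label="z")
        rng = np.random.default_rng(test_seed)
        for d in bprsa_wanted:
            out[d] = bprsa_test(curve, d.removeprefix("bprsa_"), rng=rng, target=x).p_value
    return out


def critical_q_from_pvalues(
    q_grid: np.ndarray, mean_p: np.ndarray, level: float = 0.05
) -> float | None:
    """Smallest q with mean p below the level, log-interpolated in q.

    Returns None when the detector never rejects on the grid.
    """
    below = np.flatnonzero(mean_p < level)
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        return float(q_grid[0])
    lo, hi = np.log(q_grid[i - 1]), np.log(q_grid[i])
    frac = (level - mean_p[i - 1]) / (mean_p[i] - mean_p[i - 1])
    return float(np.exp(lo + frac * (hi - lo)))


@dataclass(frozen=True)
class IsolineResult:
    """p = 0.05 isoline of one detector: critical q per series length."""

    detector: str
    lengths: tuple
    critical_q: dict  # N -> critical q or None
    ci_low: dict  # N -> bootstrap 5th percentile (or None)
    ci_high: dict  # N -> bootstrap 95th percentile (or None)
    n_real: int
    q_grid: np.ndarray = field(repr=False, default=None)


def isoline_study(
    detectors=DETECTORS,
    lengths=tuple(2**k for k in range(6, 17)),
    q_grid=None,
    n_real: int = 20,
    n_boot: int = 100,
    level: float = 0.05,
    seed: int = 0,
    order: int = DEFAULT_ORDER,
    L: int = DEFAULT_L,
) -> dict[str, IsolineResult]:
    """Critical-coupling isolines for several detectors on shared realizations.

    For each length N and grid coupling q, ``n_real`` independent systems are
    simulated and every detector's p-value recorded; the critical q is the
    level crossing of the mean p-value.  A bootstrap over the realizations
    (resampled with replacement, ``n_boot`` samples) gives the 5th/95th
    percentile band of the critical q.
    """
    q_grid = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    results = {
        d: IsolineResult(d, tuple(lengths), {}, {}, {}, n_real, q_grid) for d in detectors
    }
    for n in lengths:
        # pvals[d] has shape (len(q_grid), n_real)
        pvals = {d: np.empty((q_grid.size, n_real)) for d in detectors}
        for i, q in enumerate(q_grid):
            for r in range(n_real):
                p = pairwise_pvalues(
                    detectors, n, q, _cell_seed(seed, n, i, r), order=order, L=L
                )
                for d in detectors:
                    pvals[d][i, r] = p[d]
        boot_rng = np.random.default_rng(_cell_seed(seed, n, q_grid.size, n_real))
        boot_idx = boot_rng.integers(0, n_real, size=(n_boot, n_real))
        for d in detectors:
            res = results[d]
            res.critical_q[n] = critical_q_from_pvalues(
                q_grid, pvals[d].mean(axis=1), level
            )
            boot_q = np.array(
                [
                    np.nan
                    if (c := critical_q_from_pvalues(q_grid, pvals[d][:, idx].mean(axis=1), level))
                    is None
                    else c
                    for idx in boot_idx
                ]
            )
            if np.all(np.isnan(boot_q)):
                res.ci_low[n] = res.ci_high[n] = None
            else:
                res.ci_low[n] = float(np.nanpercentile(boot_q, 5))
                res.ci_high[n] = float(np.nanpercentile(boot_q, 95))
    return results


def critical_isoline(detector: str, **kwargs) -> IsolineResult:
    """Isoline of a single detector (see :func:`isoline_study`)."""
    if detector not in DETECTORS:
        raise ValueError(f"unknown detector {detector!r}")
    return isoline_study(detectors=(detector,), **kwargs)[detector]


def classify_realization(
    q_yz: float,
    q_yx: float,
    n: int,
    seed,
    order: int = DEFAULT_ORDER,
    level: float = 0.05,
) -> int:
    """Region of one common-driver realization from the two F-tests.

    1: neither test rejects; 2: pairwise only (correct: indirect link);
    3: both reject; 0: conditional only (inconsistent).
    """
    x, y, z = common_driver_system(
        CommonDriverConfig(n=n, q_yz=q_yz, q_yx=q_yx, seed=seed)
    )
    pair_rej = g_pairwise(x, z, p=order).p_value < level
    cond_rej = g_conditional(x, z, [y], p=order).p_value < level
    if pair_rej and cond_rej:
        return 3
    if pair_rej:
        return 2
    if cond_rej:
        return 0
    return 1


@dataclass(frozen=True)
class RegionMap:
    """Majority region per (q_yz, q_yx) grid cell."""

    q_yz: np.ndarray
    q_yx: np.ndarray
    regions: np.ndarray  # int grid, shape (len(q_yz), len(q_yx))
    n: int
    n_real: int

    def region(self, i: int, j: int) -> str:
        return REGION_LABELS[int(self.regions[i, j])]


def _majority(labels: np.ndarray) -> int:
    vals, counts = np.unique(labels, return_counts=True)
    return int(vals[np.argmax(counts)])


def region_map(
    q_yz_grid,
    q_yx_grid,
    n: int = 2**15,
    n_real: int = 20,
    level: float = 0.05,
    order: int = DEFAULT_ORDER,
    seed: int = 0,
) -> RegionMap:
    """Classify every grid cell by the majority region over realizations."""
    q_yz_grid = np.asarray(q_yz_grid, dtype=float)
    q_yx_grid = np.asarray(q_yx_grid, dtype=float)
    regions = np.empty((q_yz_grid.size, q_yx_grid.size), dtype=int)
    for i, qz in enumerate(q_yz_grid):
        for j, qx in enumerate(q_yx_grid):
            labels = np.array(
                [
                    classify_realization(
                        qz, qx, n, _cell_seed(seed, n, i, j, r), order, level
                    )
                    for r in range(n_real)
                ]
            )
            regions[i, j] = _majority(labels)
    return RegionMap(q_yz_grid, q_yx_grid, regions, n, n_real)


def region2_boundary(
    q_diag_grid,
    n: int = 2**15,
    n_real: int = 20,
    level: float = 0.05,
    order: int = DEFAULT_ORDER,
    seed: int = 0,
) -> tuple[float | None, np.ndarray]:
    """Smallest coupling product on the diagonal whose majority is Region 2.

    Simulates common-driver systems with q_yz = q_yx = q along the supplied
    grid and returns ``(product, regions)`` where product = q**2 at the first
    Region-2 cell (None if Region 2 never appears) and ``regions`` is the
    per-cell majority label vector.
    """
    q_diag_grid = np.asarray(q_diag_grid, dtype=float)
    regions = np.empty(q_diag_grid.size, dtype=int)
    for i, q in enumerate(q_diag_grid):
        labels = np.array(
            [
                classify_realization(q, q, n, _cell_seed(seed, n, i, i, r), order, level)
                for r in range(n_real)
            ]
        )
        regions[i] = _majority(labels)
    hits = np.flatnonzero(regions == 2)
    if hits.size == 0:
        return None, regions
    q2 = float(q_diag_grid[hits[0]] ** 2)
    return q2, regions
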