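"""Stationarity testing and recursive patch splitting.

Granger analysis requires stationary data, so each candidate patch (all
three channels jointly) is screened with the Augmented Dickey-Fuller test —
rejection of the unit-root null is taken as evidence of stationarity.  A
patch is first probed at model order 5, then 4, then 3; the first order at
which *all* channels pass is accepted (and later reused as the AR order of
the G-fit).  If order 3 still fails, the patch is split in half and the
procedure recurses; pieces shorter than six samples are discarded as
non-stationary.  At 15 s resolution this makes 90 s the shortest usable
patch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import adfuller

from .signals import Signal

__all__ = ["StationaryPatch", "adf_stationary", "split_patches", "stationary_fraction"]

MIN_PATCH_SAMPLES = 6
DEFAULT_ORDERS = (5, 4, 3)


@dataclass(frozen=True)
class StationaryPatch:
    """Accepted patch: half-open sample range plus the accepted model order."""

    start: int
    end: int
    order: int
    resolution: float = 1.0

    def __post_init__(self) -> None:
        if self.end - self.start < MIN_PATCH_SAMPLES:
            raise ValueError(f"patch shorter than {MIN_PATCH_SAMPLES} samples")

    @property
    def n(self) -> int:
        return self.end - self.start

    @property
    def duration(self) -> float:
        return self.n * self.resolution


def adf_stationary(x, order: int = 5, alpha: float = 0.05) -> tuple[bool, float]:
    """ADF unit-root test with ``order`` lagged differences.

    Returns ``(is_stationary, p_value)``; stationary means the unit-root
    null is rejected at level ``alpha``.  The test regression includes a
    constant but no trend term (patches are normalized to zero mean, and a
    deterministic trend should cause rejection rather than be absorbed).
    Degenerate inputs — constant series, or series too short to estimate the
    test regression — are reported as non-stationary with p-value 1.
    """
    vals = x.values if isinstance(x, Signal) else np.asarray(x, dtype=float)
    if vals.size <= order + 2:
        raise ValueError(f"series too short (n={vals.size}) for ADF with {order} lags")
    if np.ptp(vals) == 0:
        return False, 1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_value = adfuller(vals, maxlag=order, autolag=None, regression="c")[1]
    except (ValueError, np.linalg.LinAlgError):
        return False, 1.0
    if not np.isfinite(p_value):
        return False, 1.0
    return bool(p_value < alpha), float(p_value)


def _accept_order(channels, orders, alpha) -> int | None:
    """First order at which every channel passes the ADF test, else None."""
    n = channels[0].size
    for order in orders:
        if n <= order + 2:
            continue
        if all(adf_stationary(ch, order=order, alpha=alpha)[0] for ch in channels):
            return order
    return None


def split_patches(
    triple,
    resolution: float = 1.0,
    orders=DEFAULT_ORDERS,
    alpha: float = 0.05,
    offset: int = 0,
) -> list[StationaryPatch]:
    """Recursively split a channel triple into stationary patches.

    Parameters
    ----------
    triple : sequence of three Signal or arrays
        Equal-length, aligned channels.
    resolution : float
        Seconds per sample (stored on the returned patches).
    orders : tuple of int
        Model orders to try, most complex first.
    alpha : float
        ADF significance level.
    offset : int
        Index of the triple's first sample in the parent series (used by the
        recursion; patches are reported in parent coordinates).

    Returns
    -------
    list of StationaryPatch
        Disjoint accepted patches in temporal order; possibly empty.
    Halving an odd-length patch puts the extra sample in the left half.
    """
    channels = [
        (s.values if isinstance(s, Signal) else np.asarray(s, dtype=float))
        for s in triple
    ]
    if len(channels) != 3:
        raise ValueError("expected a triple of three channels")
    n = channels[0].size
    if any(ch.size != n for ch in channels):
        raise ValueError("channels must have equal length")
    if n < MIN_PATCH_SAMPLES:
        return []
    order = _accept_order(channels, orders, alpha)
    if order is not None:
        return [StationaryPatch(offset, offset + n, order, resolution)]
    left = (n + 1) // 2
    return split_patches(
        [ch[:left] for ch in channels], resolution, orders, alpha, offset
    ) + split_patches(
        [ch[left:] for ch in channels], resolution, orders, alpha, offset + left
    )


def stationary_fraction(patches, total_length: int) -> float:
    """Fraction of the input covered by accepted patches."""
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    covered = sum(p.n for p in patches)
    if covered > total_length:
        raise ValueError("patches exceed the input range")
    return covered / total_length
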