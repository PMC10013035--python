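"""Granger causality via nested autoregressive models.

A target series is regressed on lags 1..p of itself (restricted model) and
additionally on lags 1..p of a candidate source (unrestricted model).  The
G-value is the log ratio of the residual standard deviations,
``G = ln(sigma_restricted / sigma_unrestricted) >= 0``; whether the source's
coefficients are jointly zero is decided with an F-test (or the chi-squared
large-sample variant).  The conditional variant adds lags of one or more
conditioning series to *both* models, so only information beyond what the
conditioning signals already provide counts — this separates direct links
from indirect or common-driver links.

Conventions: no intercept (series are assumed standardized to zero mean);
both nested models are fitted on the identical observation rows t = p..n-1
so their residual sums of squares are comparable; sigma uses the 1/n_obs
normalization (the convention cancels in the ratio).  Lag-0 regressor terms
are never included: couplings between physiological systems act with delays
of at least one sampling step, so "instantaneous causality" is excluded by
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .signals import Signal

__all__ = ["ARFit", "GrangerResult", "GrangerCausality", "fit_ar", "g_pairwise", "g_conditional"]


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, Signal) else np.asarray(x, dtype=float)


@dataclass(frozen=True)
class ARFit:
    """Least-squares fit of a lagged multivariate regression.

    coefficients maps each regressor label to its vector of p lag
    coefficients (lag 1 first).  ``sigma = sqrt(rss / n_obs)`` with
    ``n_obs = n - p`` usable rows.
    """

    order: int
    coefficients: dict[str, np.ndarray]
    sigma: float
    rss: float
    n_obs: int
    collinear: bool = False

    @property
    def n_params(self) -> int:
        return self.order * len(self.coefficients)


def _lag_matrix(x: np.ndarray, p: int) -> np.ndarray:
    """Columns are lags 1..p of x, rows t = p..n-1."""
    n = x.size
    return np.column_stack([x[p - i : n - i] for i in range(1, p + 1)])


def fit_ar(target, regressors=(), p: int = 5, labels=None) -> ARFit:
    """Fit the target on lags 1..p of itself and of each extra regressor.

    The target's own past is always the first regressor block.  Rows
    t = p..n-1 are used, so ``n_obs = n - p`` regardless of how many blocks
    enter — nested fits therefore share identical observations.

    A rank-deficient design (e.g. a constant or duplicated series) is not an
    error: the minimum-norm solution is returned with ``collinear=True``.
    """
    y = _values(target)
    blocks = [y] + [_values(r) for r in regressors]
    n = y.size
    if any(b.size != n for b in blocks):
        raise ValueError("all series must have equal length")
    if p < 1:
        raise ValueError("model order must be >= 1")
    if n < 2 * p + 2:
        raise ValueError(f"series too short (n={n}) for order p={p}")
    if labels is None:
        labels = [getattr(target, "label", "") or "target"] + [
            getattr(r, "label", "") or f"reg{i}" for i, r in enumerate(regressors)
        ]
    design = np.hstack([_lag_matrix(b, p) for b in blocks])
    response = y[p:]
    coef, _, rank, _ = np.linalg.lstsq(design, response, rcond=None)
    resid = response - design @ coef
    rss = float(resid @ resid)
    n_obs = n - p
    coefficients = {
        lab: coef[i * p : (i + 1) * p].copy() for i, lab in enumerate(labels)
    }
    return ARFit(
        order=p,
        coefficients=coefficients,
        sigma=float(np.sqrt(rss / n_obs)),
        rss=rss,
        n_obs=n_obs,
        collinear=rank < design.shape[1],
    )


@dataclass(frozen=True)
class GrangerResult:
    """G-value with its significance test.

    ``g_value = ln(sigma_restricted / sigma_unrestricted)``; a perfect
    unrestricted fit is reported as ``g_value = inf`` with ``p_value = 0``.
    """

    g_value: float
    p_value: float
    statistic: float
    test: str
    order: int
    restricted: ARFit
    unrestricted: ARFit
    conditional: bool = False
    conditioning: tuple[str, ...] = ()
    source: str = ""
    target: str = ""

    @property
    def df(self) -> tuple[int, int]:
        """(numerator, denominator) degrees of freedom of the F-test."""
        return (self.order, self.unrestricted.n_obs - self.unrestricted.n_params)

    def summary(self) -> str:
        kind = "conditional" if self.conditional else "pairwise"
        cond = f" | {','.join(self.conditioning)}" if self.conditioning else ""
        lines = [
            f"Granger causality ({kind}): {self.source} -> {self.target}{cond}",
            f"  model order p      : {self.order}",
            f"  n_obs              : {self.restricted.n_obs}",
            f"  sigma restricted   : {self.restricted.sigma:.6g}",
            f"  sigma unrestricted : {self.unrestricted.sigma:.6g}",
            f"  G-value            : {self.g_value:.6g}",
            f"  {self.test}-statistic (df={self.df[0]},{self.df[1]})"
            f" : {self.statistic:.6g}",
            f"  p-value            : {self.p_value:.6g}",
        ]
        return "\n".join(lines)


class GrangerCausality:
    """Model object testing whether ``source`` G-causes ``target``.

    Parameters
    ----------
    target, source : Signal or array
        Equal-length series; standardize them (zero mean) beforehand, the
        regression carries no intercept.
    conditioning : sequence of Signal or array, optional
        Series whose past enters both nested models (conditional analysis).
    order : int
        AR model order p (number of past terms per block).

    Examples
    --------
    >>> res = GrangerCausality(x, z, order=5).fit()
    >>> res.g_value, res.p_value
    """

    def __init__(self, target, source, conditioning=(), order: int = 5):
        self.target = target
        self.source = source
        self.conditioning = tuple(conditioning)
        self.order = int(order)
        self.target_label = getattr(target, "label", "") or "x"
        self.source_label = getattr(source, "label", "") or "z"
        self.cond_labels = tuple(
            getattr(c, "label", "") or f"y{i}" for i, c in enumerate(self.conditioning)
        )

    def fit(self, test: str = "f") -> GrangerResult:
        """Fit both nested models and test the source's coefficients.

        test : {"f", "chi2"} — F-test by default; the chi-squared variant
        uses p*F with p degrees of freedom.
        """
        if test not in ("f", "chi2"):
            raise ValueError("test must be 'f' or 'chi2'")
        p = self.order
        base_labels = [self.target_label] + list(self.cond_labels)
        restricted = fit_ar(self.target, self.conditioning, p, labels=base_labels)
        unrestricted = fit_ar(
            self.target,
            list(self.conditioning) + [self.source],
            p,
            labels=base_labels + [self.source_label],
        )
        n_obs = unrestricted.n_obs
        dfd = n_obs - unrestricted.n_params
        rss1, rss2 = restricted.rss, unrestricted.rss
        common = dict(
            test=test,
            order=p,
            restricted=restricted,
            unrestricted=unrestricted,
            conditional=bool(self.conditioning),
            conditioning=self.cond_labels,
            source=self.source_label,
            target=self.target_label,
        )
        if restricted.collinear and unrestricted.collinear and rss1 <= 0:
            # degenerate input (e.g. constant target): nothing to test
            return GrangerResult(g_value=0.0, p_value=1.0, statistic=0.0, **common)
        if rss2 <= max(rss1 * 1e-20, 0.0):  # numerically perfect fit
            return GrangerResult(
                g_value=np.inf, p_value=0.0, statistic=np.inf, **common
            )
        # numerical noise can make rss2 marginally exceed rss1 in exact ties
        g = max(0.0, float(np.log(restricted.sigma / unrestricted.sigma)))
        fstat = max(0.0, ((rss1 - rss2) / p) / (rss2 / dfd))
        if test == "f":
            p_value = float(stats.f.sf(fstat, p, dfd))
            statistic = fstat
        else:
            statistic = p * fstat
            p_value = float(stats.chi2.sf(statistic, p))
        return GrangerResult(g_value=g, p_value=p_value, statistic=statistic, **common)


def g_pairwise(x, z, p: int = 5, test: str = "f") -> GrangerResult:
    """Pairwise G-causality z -> x: does z's past improve the forecast of x?"""
    return GrangerCausality(x, z, order=p).fit(test=test)


def g_conditional(x, z, cond, p: int = 5, test: str = "f") -> GrangerResult:
    """Conditional G-causality z -> x given cond (one series or a sequence)."""
    if isinstance(cond, (Signal, np.ndarray)) or (
        hasattr(cond, "__len__") and len(cond) and np.isscalar(cond[0])
    ):
        cond = [cond]
    if not len(cond):
        raise ValueError("conditional analysis needs at least one conditioning series")
    return GrangerCausality(x, z, conditioning=cond, order=p).fit(test=test)
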