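"""Null multinomial model and classical pattern tests.

High peaks of a smooth null statistic field form a homogeneous Poisson
process in resel space (Poisson clumping heuristic).  Conditional on the
total event count k, the regional counts d are therefore multinomial with
cell probabilities equal to the relative regional resel counts a.  This
module holds that likelihood, the Pearson chi-square pattern test, the
exact binomial small-volume p-value for a two-region partition, and the
Dirichlet-multinomial predictive variance that drives Bayesian Occam's
razor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats


@dataclass(frozen=True)
class EventCounts:
    """Per-region event counts for one subject (or pooled)."""

    d: np.ndarray
    subject_id: object = None

    def __post_init__(self):
        d = np.asarray(self.d)
        if d.ndim != 1:
            raise ValueError("d must be a 1D count vector")
        if not np.issubdtype(d.dtype, np.integer):
            if not np.allclose(d, np.round(d)):
                raise ValueError("counts must be integers")
            d = np.round(d).astype(np.int64)
        if np.any(d < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "d", d.astype(np.int64))

    @property
    def k(self) -> int:
        """Total event count."""
        return int(self.d.sum())

    @property
    def n_regions(self) -> int:
        return self.d.size


@dataclass(frozen=True)
class NullPattern:
    """Relative statistical volumes a_j defining the null pattern."""

    a: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("a must be a 1D probability vector")
        if np.any(a <= 0):
            raise ValueError("all a_j must be > 0 (merge degenerate regions)")
        if abs(a.sum() - 1.0) > 1e-12:
            raise ValueError("a must sum to 1 within 1e-12")
        object.__setattr__(self, "a", a)

    @property
    def n_regions(self) -> int:
        return self.a.size


@dataclass(frozen=True)
class DirichletParams:
    """Dirichlet written as mean m and concentration c; alpha = c * m."""

    m: np.ndarray
    c: float

    def __post_init__(self):
        m = np.asarray(self.m, dtype=float)
        if abs(m.sum() - 1.0) > 1e-10 or np.any(m <= 0):
            raise ValueError("m must be a strictly positive simplex vector")
        if not self.c > 0:
            raise ValueError("c must be > 0")
        object.__setattr__(self, "m", m)

    @property
    def alpha(self) -> np.ndarray:
        return self.c * self.m


def _counts(d) -> np.ndarray:
    if isinstance(d, EventCounts):
        return d.d
    return EventCounts(d=np.asarray(d)).d


def multinomial_log_pmf(d, theta) -> float:
    """Log multinomial probability of counts d under cell probabilities theta.

    Computed with log-gamma; a zero-probability cell with a positive count
    gives -inf.
    """
    d = _counts(d)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != d.shape:
        raise ValueError("d and theta must have the same length")
    if np.any(theta < 0) or abs(theta.sum() - 1.0) > 1e-9:
        raise ValueError("theta must be a probability vector")
    if np.any((theta == 0) & (d > 0)):
        return -np.inf
    log_coeff = special.gammaln(d.sum() + 1) - special.gammaln(d + 1).sum()
    with np.errstate(divide="ignore"):
        log_theta = np.where(d > 0, np.log(np.where(theta > 0, theta, 1.0)), 0.0)
    return float(log_coeff + (d * log_theta).sum())


def chisq_pattern_test(d, null: NullPattern):
    """Pearson chi-square test of the observed pattern against the null.

    Returns (statistic, df, p).  Warns when any expected count k*a_j < 5:
    the asymptotic reference requires a moderate number of events per
    region (use a lower threshold or larger regions).
    """
    d = _counts(d)
    a = null.a if isinstance(null, NullPattern) else NullPattern(np.asarray(null)).a
    if a.shape != d.shape:
        raise ValueError("d and a must have the same length")
    k = d.sum()
    if k == 0:
        raise ValueError("no events to test (k = 0)")
    expected = k * a
    if np.any(expected < 5):
        warnings.warn(
            "expected count k*a_j < 5 in some region; the chi-square "
            "approximation needs a moderate number of events per region",
            stacklevel=2)
    stat = float(((d - expected) ** 2 / expected).sum())
    df = d.size - 1
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def binomial_svc_pvalue(d1: int, k: int, a1: float) -> float:
    """Exact small-volume p-value for a two-region partition.

    Upper binomial tail P(D >= d1 | k, a1), inclusive of the observed
    count, for the event count in a small pre-specified volume of relative
    statistical size a1 given k events in the whole search volume.
    """
    d1, k = int(d1), int(k)
    if not (0 <= d1 <= k):
        raise ValueError("require 0 <= d1 <= k")
    if not (0 < a1 < 1):
        raise ValueError("require 0 < a1 < 1")
    if d1 == 0:
        return 1.0
    return float(stats.binom.sf(d1 - 1, k, a1))


def dirmult_predictive_variance(k: int, a: float, c: float) -> float:
    """Predictive variance of a regional count under a Dirichlet prior.

    For a two-region partition with prior mean a and concentration c the
    prior-predictive count variance is k a (1-a) [1 + (k-1)/(c+1)]; the
    c -> inf limit is the binomial variance of the point-null model.  The
    monotone decrease in c is the mechanism of Bayesian Occam's razor: the
    concentrated (null) model puts more mass on data near a.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0 < a < 1):
        raise ValueError("a must be in (0, 1)")
    base = k * a * (1 - a)
    if np.isinf(c):
        return float(base)
    if not c > 0:
        raise ValueError("c must be > 0")
    return float(base * (1 + (k - 1) / (c + 1)))


def dirmult_log_pmf(d, alpha) -> float:
    """Log Dirichlet-multinomial pmf (multinomial marginalised over a
    Dirichlet with parameter vector alpha)."""
    d = _counts(d)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != d.shape:
        raise ValueError("d and alpha must have the same length")
    if np.any(alpha <= 0):
        raise ValueError("alpha must be strictly positive")
    k = d.sum()
    a0 = alpha.sum()
    return float(
        special.gammaln(k + 1) - special.gammaln(d + 1).sum()
        + special.gammaln(a0) - special.gammaln(a0 + k)
        + (special.gammaln(alpha + d) - special.gammaln(alpha)).sum()
    )
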