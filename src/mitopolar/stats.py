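"""Inferential toolbox: exact two-sample Mann-Whitney, rank correlation,
circular summaries, and hierarchical mean ± SD reports.

The two-sample comparisons in this package are run at the scale of a handful
of embryos (typically 3–10 per genotype), where the normal approximation to
the Mann-Whitney null is poor and published p-values are exact-enumeration
values.  ``mann_whitney`` therefore computes the exact null distribution of
the U statistic by the standard count recursion whenever the data are
tie-free and small enough, and falls back to the tie- and
continuity-corrected normal approximation otherwise.  ``spearman`` does the
same with full permutation enumeration of the rank-correlation null.

Two-sided p-values are defined as twice the smaller tail probability, capped
at 1.  Under complete separation of the two groups this yields
``p = 2 / C(n1 + n2, n1)``, the minimal attainable two-sided value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.stats as sps

__all__ = [
    "StatResult",
    "CorrelationResult",
    "CircularSummary",
    "mann_whitney",
    "spearman",
    "pearson_r2",
    "circular_mean",
    "group_summary",
    "two_level_summary",
]


@dataclass(frozen=True)
class StatResult:
    """Result of a two-sample rank test."""

    U: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    tie_corrected: bool

    def __post_init__(self) -> None:
        if not 0 <= self.U <= self.n1 * self.n2:
            raise ValueError(f"U={self.U} outside [0, n1*n2]")
        if not 0 < self.p_two_sided <= 1:
            raise ValueError(f"p={self.p_two_sided} outside (0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation of two paired samples against the null r = 0."""

    n: int
    p_two_sided: float
    method: str
    spearman_rho: float | None = None
    pearson_r: float | None = None
    r_squared: float | None = None


@dataclass(frozen=True)
class CircularSummary:
    """Mean direction and mean resultant length of a sample of angles."""

    circular_mean: float  # degrees
    resultant_length: float  # in [0, 1]
    n: int


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


@lru_cache(maxsize=256)
def _mw_null_counts(n1: int, n2: int) -> tuple[np.ndarray, int]:
    """Null frequencies of U over all C(n1+n2, n1) group labelings.

    Uses the recursion c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u),
    i.e. the coefficients of the Gaussian binomial [n1+n2 choose n1]_q.
    Returns (counts array of length n1*n2+1, total number of labelings).
    """
    # table[j] = counts array for (i, j) at current i
    counts = {(0, j): np.ones(1, dtype=np.float64) for j in range(n2 + 1)}
    for i in range(1, n1 + 1):
        counts[(i, 0)] = np.ones(1, dtype=np.float64)
        for j in range(1, n2 + 1):
            c = np.zeros(i * j + 1, dtype=np.float64)
            a = counts[(i - 1, j)]  # shifted by j
            c[j : j + a.size] += a
            b = counts[(i, j - 1)]
            c[: b.size] += b
            counts[(i, j)] = c
        # free the previous row
        for j in range(n2 + 1):
            counts.pop((i - 1, j), None)
    total = math.comb(n1 + n2, n1)
    return counts[(n1, n2)], total


def mann_whitney(x, y, exact_threshold: int = 20) -> StatResult:
    """Two-sample two-sided Mann-Whitney (Wilcoxon rank-sum) test.

    Exact enumeration of the null distribution of U is used when the pooled
    data contain no ties and ``max(n1, n2) <= exact_threshold``; otherwise
    the normal approximation with continuity and tie correction.  The
    two-sided p is ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires two non-empty samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and max(n1, n2) <= exact_threshold:
        counts, total = _mw_null_counts(n1, n2)
        ui = int(round(u))
        cdf = counts[: ui + 1].sum() / total
        sf = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return StatResult(u, n1, n2, p, "exact", False)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all pooled values identical
        return StatResult(u, n1, n2, 1.0, "normal_approx", True)
    # continuity correction toward the mean
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    p = max(p, np.finfo(float).tiny)
    return StatResult(u, n1, n2, p, "normal_approx", bool(tie_counts.max() > 1))


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _spearman_null_sums(n: int) -> np.ndarray:
    """Sum_i i * pi(i) over all n! permutations pi of 1..n (sorted)."""
    base = np.arange(1, n + 1)
    sums = np.fromiter(
        (int(np.dot(base, p)) for p in itertools.permutations(base)),
        dtype=np.int64,
        count=math.factorial(n),
    )
    return sums


def _rho_from_sum(s, n: int):
    """Spearman rho from S = sum of rank products, tie-free ranks 1..n."""
    return (12.0 * s - 3.0 * n * (n + 1) ** 2) / (n * (n * n - 1))


def spearman(x, y, exact_threshold: int = 9) -> CorrelationResult:
    """Spearman rank correlation with two-sided p against rho = 0.

    For tie-free samples of size ``n <= exact_threshold`` the p-value is the
    exact permutation probability P(|rho*| >= |rho|); otherwise the
    t-approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant sample: rank correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    has_ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if not has_ties and n <= exact_threshold:
        sums = _spearman_null_sums(n)
        rhos = _rho_from_sum(sums, n)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return CorrelationResult(n=n, p_two_sided=p, method="exact", spearman_rho=rho)

    if abs(rho) >= 1.0:
        p = np.finfo(float).tiny
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = max(2.0 * sps.t.sf(abs(t), df=n - 2), np.finfo(float).tiny)
    return CorrelationResult(n=n, p_two_sided=min(1.0, p), method="t_approx", spearman_rho=rho)


def pearson_r2(x, y) -> CorrelationResult:
    """Pearson product-moment correlation r and the coefficient R^2 = r^2."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson_r2 requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    p = float(res.pvalue) if res.pvalue > 0 else np.finfo(float).tiny
    return CorrelationResult(
        n=x.size,
        p_two_sided=min(1.0, p),
        method="t_approx",
        pearson_r=r,
        r_squared=r * r,
    )


# ---------------------------------------------------------------------------
# Circular and hierarchical summaries
# ---------------------------------------------------------------------------


def circular_mean(angles_deg, period: float = 360.0) -> CircularSummary:
    """Mean direction of angles (degrees) with the given period.

    ``period=180`` treats angles as axial (undirected lines): each angle is
    doubled before averaging and the mean is halved back, the standard
    construction for orientation data.  The mean is reported in
    ``(-period/2, period/2]``.
    """
    a = np.asarray(angles_deg, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("circular_mean requires at least one angle")
    f = 360.0 / period
    z = np.exp(1j * np.deg2rad(a * f))
    zbar = z.mean()
    r = float(np.abs(zbar))
    mean = float(np.rad2deg(np.angle(zbar)) / f)
    # map into (-period/2, period/2]
    half = period / 2.0
    mean = -((-mean + half) % period - half)
    if mean <= -half:
        mean += period
    return CircularSummary(circular_mean=mean, resultant_length=r, n=a.size)


def group_summary(df, value: str, by) -> "pd.DataFrame":
    """Mean ± sample SD (ddof=1) of ``value`` per group.

    Groups of size 1 get ``sd = NaN`` and ``sd_defined = False``.
    """
    import pandas as pd  # local import keeps module import light

    g = df.groupby(by, sort=True)[value]
    out = g.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    out["sd_defined"] = out["n"] > 1
    return pd.DataFrame(out)


def two_level_summary(df, value: str, embryo: str = "embryo_id") -> "pd.DataFrame":
    """Mean ± SD at the cell level (pooled) and the embryo level.

    The embryo-level row summarizes per-embryo means, matching the
    per-embryo averaging used for between-group comparisons; the cell-level
    row pools all cells.  Both are reported because published mean ± SD
    values do not always state the aggregation level.
    """
    import pandas as pd

    v = df[value].astype(float)
    cell = {"level": "cells", "n": int(v.size), "mean": v.mean(), "sd": v.std(ddof=1)}
    em = df.groupby(embryo)[value].mean()
    embryo_row = {
        "level": "embryos",
        "n": int(em.size),
        "mean": em.mean(),
        "sd": em.std(ddof=1) if em.size > 1 else float("nan"),
    }
    return pd.DataFrame([cell, embryo_row])
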