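"""Descriptive and nonparametric cohort statistics.

The per-subject summary rows feed group descriptives (mean, median, SD,
coefficient of variation), a Mann-Whitney comparison of the two groups
(normal approximation with midranks and tie-corrected variance, reported
as a z statistic), Spearman rank correlation with its t conversion
``t = rho * sqrt((n-2) / (1-rho^2))``, and the Pearson chi-square test of
independence on 2x2 frequency tables. Significance is two-sided at
alpha = 0.05 throughout, with no multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class DescriptiveStats:
    n: int
    min: float
    max: float
    mean: float
    median: float
    sd: float | None        # sample SD (n-1); None for n < 2
    cv: float | None        # 100 * SD / mean (%); None when undefined


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    estimate: float | None = None   # rho for correlations, U for Mann-Whitney


def describe(values) -> DescriptiveStats:
    """Descriptives in the cohort-table convention (x, Me, SD, CV%)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("describe needs at least one value")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else None
    cv = 100.0 * sd / mean if sd is not None and mean != 0 else None
    return DescriptiveStats(
        n=int(x.size),
        min=float(np.min(x)),
        max=float(np.max(x)),
        mean=mean,
        median=float(np.median(x)),
        sd=sd,
        cv=cv,
    )


def mann_whitney(group_a, group_b) -> TestResult:
    """Mann-Whitney U via the normal approximation, midranks for ties and
    tie-corrected variance, no continuity correction; two-sided p.

    U is reported for the first group; z = (U - n_a n_b / 2) / sigma.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u_a = float(np.sum(ranks[:na]) - na * (na + 1) / 2.0)
    n = na + nb
    mu = na * nb / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every pooled value identical
        return TestResult(0.0, 1.0, "mann-whitney-z", (na, nb), estimate=u_a)
    z = (u_a - mu) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(float(z), float(min(p, 1.0)), "mann-whitney-z", (na, nb), estimate=u_a)


def spearman_t(rho: float, n: int) -> float:
    """t conversion of a Spearman coefficient: rho*sqrt((n-2)/(1-rho^2))."""
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if abs(rho) >= 1.0:
        return math.copysign(math.inf, rho)
    return rho * math.sqrt((n - 2) / (1.0 - rho * rho))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation: Pearson correlation of midranks, with the
    t reference distribution on n-2 degrees of freedom (two-sided)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must pair up")
    n = xa.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    rx, ry = sps.rankdata(xa), sps.rankdata(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in a variable; rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    t = spearman_t(rho, n)
    p = 0.0 if math.isinf(t) else float(2.0 * sps.t.sf(abs(t), n - 2))
    return TestResult(t, p, "spearman-t", (n,), estimate=rho)


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square of independence on a 2x2 table, df = 1, no
    continuity correction; requires all expected counts positive."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin: expected counts must be positive")
    expected = np.outer(row, col) / total
    stat = float(np.sum((obs - expected) ** 2 / expected))
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(stat, p, "chi-square", (int(total),))
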