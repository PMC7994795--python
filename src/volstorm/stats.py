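"""Nonparametric summary statistics and rank tests.

Cluster metrics in SMLM are heavily right-skewed, so distributions are
reported as median with 25th/75th percentiles (mean and SD are included
for comparability with mean-based literature values) and compared with
rank tests: Mann-Whitney for two groups, Kruskal-Wallis for several,
Spearman for monotone association.  Quartiles use linear interpolation
between order statistics (type-7); published quartiles computed under a
different convention may differ in the last decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError, ParameterError


@dataclass
class SummaryRow:
    label: str
    n: int
    median: float
    q25: float
    q75: float
    mean: float
    sd: float


def summarize(values, label: str = "") -> SummaryRow:
    """Median +/- quartile summary of one numeric sample."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DataError("cannot summarize an empty sample")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return SummaryRow(label=label, n=int(arr.size), median=float(med),
                      q25=float(q25), q75=float(q75),
                      mean=float(arr.mean()),
                      sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0)


def rank_tests(groups, kind: str = "mann_whitney"):
    """Tie-corrected rank test across groups; returns (statistic, p).

    ``mann_whitney`` requires exactly two groups and uses the exact
    small-sample distribution up to n = 20 per group, the normal
    approximation above; ``kruskal_wallis`` takes two or more groups and
    uses the chi-square approximation.  Identical groups give p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise DataError("rank test received an empty group")
    if kind == "mann_whitney":
        if len(groups) != 2:
            raise ParameterError("mann_whitney needs exactly 2 groups")
        a, b = groups
        method = "exact" if (len(a) <= 20 and len(b) <= 20
                             and not _has_ties(a, b)) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(min(res.pvalue, 1.0))
    if kind == "kruskal_wallis":
        if len(groups) < 2:
            raise ParameterError("kruskal_wallis needs >= 2 groups")
        if all(np.array_equal(groups[0], g) for g in groups[1:]):
            return 0.0, 1.0
        res = sps.kruskal(*groups)
        return float(res.statistic), float(res.pvalue)
    raise ParameterError(f"unknown test kind {kind!r}")


def _has_ties(a, b) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def spearman_correlation(x, y):
    """Spearman rank correlation with average ranks for ties; two-tailed
    p from the t approximation.  Returns (r, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 3:
        raise ParameterError("spearman needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("correlation undefined for constant input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Conventional star mapping: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
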