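"""Statistical primitives shared by all pipeline stages.

Conventions are pinned here once so every stage tests and compares identically:

* two-sample Kolmogorov-Smirnov with the asymptotic Kolmogorov distribution at
  effective size ``n1*n2/(n1+n2)`` (sample sizes in this pipeline are hundreds
  of alleles/boundaries, where the asymptotic p is adequate);
* Mann-Whitney U with the tie-corrected normal approximation and no continuity
  correction;
* two-sided Fisher's exact test by the probability-mass method (sum of
  hypergeometric probabilities no larger than the observed table's);
* Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    n1: int
    n2: int


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"empty sample '{name}'")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in sample '{name}'")
    return arr


def ks_two_sample(x, y) -> TestResult:
    """Two-sided two-sample KS test.

    D is the supremum over all pooled points of |ECDF_x - ECDF_y|; the p-value
    comes from the asymptotic Kolmogorov distribution evaluated at
    sqrt(n1*n2/(n1+n2)) * D.
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    n1, n2 = x.size, y.size
    xs, ys = np.sort(x), np.sort(y)
    pooled = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, pooled, side="right") / n1
    cdf_y = np.searchsorted(ys, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    ne = n1 * n2 / (n1 + n2)
    p = float(np.clip(special.kolmogorov(np.sqrt(ne) * d), 0.0, 1.0))
    return TestResult(statistic=d, pvalue=p, n1=n1, n2=n2)


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U (rank-sum), tie-corrected normal approximation.

    ``alternative='less'`` tests whether x tends to be smaller than y.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative '{alternative}'")
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0))) if n > 1 else 0.0
    if var <= 0:
        # all values tied: no evidence either way
        return TestResult(statistic=float(u1), pvalue=1.0, n1=n1, n2=n2)
    z = (u1 - mu) / np.sqrt(var)
    if alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        p = sps.norm.sf(z)
    else:
        p = sps.norm.cdf(z)
    return TestResult(statistic=float(u1), pvalue=float(min(1.0, p)), n1=n1, n2=n2)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("Fisher table counts must be non-negative integers")
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(statistic=float(odds), pvalue=float(p), n1=a + b, n2=c + d)


def pearson_r(x, y) -> float:
    """Pearson correlation; raises on constant input (undefined correlation)."""
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    if x.size != y.size:
        raise ValueError("pearson_r needs equal-length samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values, q_(i) = min_{j>=i} m * p_(j) / j, capped at 1."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
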