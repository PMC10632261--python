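"""Small-sample nonparametric tests and helpers.

* :func:`mann_whitney_exact` — two-sided Mann-Whitney U with midranks; the
  exact permutation distribution of the rank sum is computed by dynamic
  programming for small samples (n1 + n2 <= 25 by default), with a
  tie-corrected normal approximation beyond that (no continuity
  correction).
* :func:`fisher_exact_2x2` — two-sided Fisher's exact test by the
  point-probability method: the p-value sums hypergeometric probabilities
  no larger than that of the observed table (with a small relative
  tolerance on the comparison); an empty margin gives p = 1 by convention.
* :func:`pearson_correlation` — product-moment r with the two-sided p from
  the t transform on n - 2 df.
* :func:`bonferroni_adjust` — adjusted p = min(1, m * p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

EXACT_LIMIT = 25


@dataclass
class GroupComparisonResult:
    statistic: float
    p_value: float
    method: str
    descriptives: dict = field(default_factory=dict)


def _rank_sum_distribution(ranks2: np.ndarray, n1: int) -> np.ndarray:
    """Counts of subsets of size n1 by doubled-rank sum (index = sum)."""
    total = int(ranks2.sum())
    f = np.zeros((n1 + 1, total + 1))
    f[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(n1, 0, -1):
            f[k, r:] += f[k - 1, : total + 1 - r]
    return f[n1]


def mann_whitney_exact(x, y) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test; exact for n1 + n2 <= 25.

    The reported statistic is U for the first sample; the exact two-sided
    p doubles the smaller tail of the permutation distribution of the rank
    sum (capped at 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    desc = {
        "n1": n1, "n2": n2,
        "median1": float(np.median(x)), "median2": float(np.median(y)),
        "iqr1": tuple(np.percentile(x, [25, 75])),
        "iqr2": tuple(np.percentile(y, [25, 75])),
    }

    if n1 + n2 <= EXACT_LIMIT:
        ranks2 = np.rint(2 * ranks).astype(int)
        dist = _rank_sum_distribution(ranks2, n1)
        total = dist.sum()
        s_obs = int(round(2 * r1))
        lo = dist[: s_obs + 1].sum() / total
        hi = dist[s_obs:].sum() / total
        p = min(1.0, 2.0 * min(lo, hi))
        method = "mann-whitney exact"
    else:
        mu = n1 * n2 / 2.0
        _, counts = np.unique(combined, return_counts=True)
        n = n1 + n2
        tie = (counts**3 - counts).sum()
        var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (u1 - mu) / np.sqrt(var)
            p = 2.0 * sps.norm.sf(abs(z))
        method = "mann-whitney normal approximation"
    return GroupComparisonResult(statistic=u1, p_value=float(p), method=method,
                                 descriptives=desc)


def fisher_exact_2x2(table, rel_tol: float = 1e-7) -> GroupComparisonResult:
    """Two-sided Fisher's exact test on a 2x2 count table."""
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab = np.rint(tab).astype(int)
        if np.any(tab < 0):
            raise ValueError("counts must be nonnegative integers")
    a, b = int(tab[0, 0]), int(tab[0, 1])
    c, d = int(tab[1, 0]), int(tab[1, 1])
    row1, col1, N = a + b, a + c, a + b + c + d
    desc = {"table": [[a, b], [c, d]]}
    if row1 == 0 or col1 == 0 or row1 == N or col1 == N:
        log.info("degenerate margin in Fisher table; p = 1 by convention")
        return GroupComparisonResult(np.nan, 1.0, "fisher exact", desc)
    kmin = max(0, row1 + col1 - N)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = sps.hypergeom.pmf(support, N, col1, row1)
    p_obs = pmf[support == a][0]
    mask = pmf <= p_obs * (1.0 + rel_tol)
    p = 1.0 if mask.all() else float(pmf[mask].sum())
    return GroupComparisonResult(float(p_obs), min(1.0, p), "fisher exact", desc)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p via the t
    transform t = r sqrt(n-2)/sqrt(1-r^2) on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    xm, ym = x - x.mean(), y - y.mean()
    r = float(xm @ ym / np.sqrt((xm @ xm) * (ym @ ym)))
    n = len(x)
    p = pearson_p(r, n)
    return r, p


def pearson_p(r: float, n: int) -> float:
    """Two-sided p for a given r and sample size."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)
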