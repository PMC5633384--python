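"""Statistical primitives shared by every analysis stage.

All two-sample comparisons return a :class:`TestResult` so downstream report
code can treat Wilcoxon, KS, chi-square and t-test results uniformly.  The
Wilcoxon test switches to exhaustive enumeration on small samples, where its
p-values are exact; the hypergeometric tail is delegated to scipy's
log-space implementation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps

__all__ = [
    "TestResult",
    "fisher_z",
    "pearson_r",
    "wilcoxon_rank_sum",
    "ks_two_sample",
    "hypergeom_tail",
    "chi_square_2x2",
    "t_test_two_sample",
    "bonferroni",
    "roc_auc",
]

#: n1 + n2 at or below which the Wilcoxon test enumerates all rank
#: assignments instead of using the normal approximation.
WILCOXON_EXACT_THRESHOLD = 12

_ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample test.

    ``statistic`` is the test's natural statistic (rank sum W, KS D,
    chi-square, Welch t).  ``degenerate`` marks inputs on which the test is
    vacuous (e.g. all values tied); such results carry p_value 1.
    """

    statistic: float
    p_value: float
    method: str
    alternative: str = "two_sided"
    n1: int = 0
    n2: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def fisher_z(r):
    """Variance-stabilising Fisher transform z = ½·ln((1+r)/(1−r)).

    Accepts scalars or arrays; every value must satisfy \\|r\\| < 1.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        bad = arr[np.abs(arr) >= 1.0]
        raise ValueError(f"correlation outside (-1, 1): {np.atleast_1d(bad)[0]!r}")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def pearson_r(x, y) -> float:
    """Pearson correlation of two equal-length vectors (n >= 3).

    A zero-variance input makes the correlation undefined; it is returned
    as NaN (missing) so callers can skip it, never silently coerced to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sx = x - x.mean()
    sy = y - y.mean()
    denom = math.sqrt(float(sx @ sx) * float(sy @ sy))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((sx @ sy) / denom, -1.0, 1.0))


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def wilcoxon_rank_sum(
    x,
    y,
    alternative: str = "two_sided",
    exact_threshold: int = WILCOXON_EXACT_THRESHOLD,
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test on two samples.

    The statistic is W, the sum of midranks of ``x`` in the pooled sample.
    For ``n1 + n2 <= exact_threshold`` the p-value is computed by exhaustive
    enumeration of all C(n1+n2, n1) rank assignments (exact even with ties);
    otherwise by the normal approximation with tie-corrected variance and a
    0.5 continuity correction.  ``alternative='greater'`` means x tends to
    exceed y.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    if np.all(pooled == pooled[0]):
        return TestResult(w, 1.0, "wilcoxon", alternative, n1, n2, degenerate=True)

    n = n1 + n2
    if n <= exact_threshold:
        # Midranks are multiples of 1/2: double to integers for exact sums.
        r2 = np.rint(2 * ranks).astype(np.int64)
        w2 = int(round(2 * w))
        ge = le = total = 0
        for comb in itertools.combinations(range(n), n1):
            s = int(r2[list(comb)].sum())
            total += 1
            if s >= w2:
                ge += 1
            if s <= w2:
                le += 1
        p_greater = ge / total
        p_less = le / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return TestResult(w, p, "wilcoxon", alternative, n1, n2)

    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie_term / (12.0 * n * (n - 1))
    if var <= 0:
        return TestResult(w, 1.0, "wilcoxon", alternative, n1, n2, degenerate=True)
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (w - mu - 0.5) / sd
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        z = (w - mu + 0.5) / sd
        p = float(sps.norm.cdf(z))
    else:
        z = max(0.0, abs(w - mu) - 0.5) / sd
        p = float(2.0 * sps.norm.sf(z))
    return TestResult(w, min(p, 1.0), "wilcoxon", alternative, n1, n2)


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum over observed points of the ECDF difference; the
    p-value uses the asymptotic Kolmogorov distribution evaluated at
    sqrt(n_eff)·D with n_eff = n1·n2/(n1+n2).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / n1
    cdf_y = np.searchsorted(y, grid, side="right") / n2
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = n1 * n2 / (n1 + n2)
    p = float(np.clip(special.kolmogorov(math.sqrt(en) * d), 0.0, 1.0))
    return TestResult(d, p, "ks", "two_sided", n1, n2, degenerate=(d == 0.0))


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeom(N, K, n).

    N: universe size, K: annotated in universe, n: draw (e.g. cluster)
    size, k: annotated observed in the draw.  Computed in log space via
    scipy for numerical stability.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N:
        raise ValueError(f"K ({K}) and n ({n}) must not exceed N ({N})")
    if k > min(K, n):
        raise ValueError(f"k ({k}) exceeds min(K, n) = {min(K, n)}")
    if k == 0:
        return 1.0
    return float(np.clip(sps.hypergeom.sf(k - 1, N, K, n), 0.0, 1.0))


def chi_square_2x2(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 count table.

    No continuity correction by default; pass ``correction=True`` for
    Yates.  Both margins must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    for axis, sums in (("row", rows), ("column", cols)):
        for i, s in enumerate(sums):
            if s == 0:
                raise ValueError(f"empty {axis} margin at index {i}")
    expected = np.outer(rows, cols) / t.sum()
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(stat, p, "chi2", "two_sided", int(rows[0]), int(rows[1]))


def t_test_two_sample(x, y, alternative: str = "two_sided") -> TestResult:
    """Welch's unequal-variance two-sample t-test."""
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 observations")
    v1 = float(x.var(ddof=1))
    v2 = float(y.var(ddof=1))
    if v1 == 0.0 and v2 == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "ttest", alternative, n1, n2, degenerate=True)
        stat = math.inf if x.mean() > y.mean() else -math.inf
        return TestResult(stat, 0.0, "ttest", alternative, n1, n2, degenerate=True)
    se2 = v1 / n1 + v2 / n2
    stat = float((x.mean() - y.mean()) / math.sqrt(se2))
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    if alternative == "greater":
        p = float(sps.t.sf(stat, df))
    elif alternative == "less":
        p = float(sps.t.cdf(stat, df))
    else:
        p = float(2.0 * sps.t.sf(abs(stat), df))
    return TestResult(stat, min(p, 1.0), "ttest", alternative, n1, n2)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m·p) per value.

    ``m`` defaults to the number of p-values and must be at least that.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p_values must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m ({m}) smaller than number of p-values ({p.size})")
    return np.minimum(1.0, m * p)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank-based (Mann-Whitney) estimator.

    Equals the probability that a random positive outscores a random
    negative, with ties counting one half.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if s.shape != lab.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d vectors")
    pos = lab == 1
    neg = lab == 0
    if not np.any(pos) or not np.any(neg):
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s, method="average")
    n1 = int(pos.sum())
    n0 = int(neg.sum())
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
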