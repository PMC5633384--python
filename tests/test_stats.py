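"""Unit and property tests for the statistical primitives.

The Wilcoxon and hypergeometric implementations are checked against
exact-arithmetic enumeration oracles built with fractions.Fraction, fully
independent of the implementation's code paths.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trgkit.stats import (bonferroni, chi_square_2x2, fisher_z, hypergeom_tail,
                          ks_two_sample, pearson_r, roc_auc,
                          t_test_two_sample, wilcoxon_rank_sum)

# ---------------------------------------------------------------- oracles


def wilcoxon_oracle(x, y, alternative):
    """Exact rank-sum p by enumeration with Fraction arithmetic."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = Fraction(i + j + 2, 2)  # 1-based midrank
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    n1 = len(x)
    w_obs = sum(ranks[:n1])
    ge = le = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in comb)
        total += 1
        ge += w >= w_obs
        le += w <= w_obs
    p_g, p_l = Fraction(ge, total), Fraction(le, total)
    if alternative == "greater":
        return float(p_g)
    if alternative == "less":
        return float(p_l)
    return float(min(1, 2 * min(p_g, p_l)))


def hypergeom_oracle(N, K, n, k):
    """Exact upper tail by Fraction summation over the support."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


# ---------------------------------------------------------------- fisher_z


def test_fisher_z_values_and_symmetry():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3), abs=1e-12)
    for r in (0.1, 0.37, 0.99):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-15)


def test_fisher_z_roundtrip_bijection():
    rs = np.linspace(-0.999, 0.999, 41)
    back = np.tanh(fisher_z(rs))
    assert np.max(np.abs(back - rs)) < 1e-12


@pytest.mark.parametrize("bad", [1.0, -1.0, 1.5])
def test_fisher_z_domain_error(bad):
    with pytest.raises(ValueError, match="correlation"):
        fisher_z(bad)


# ---------------------------------------------------------------- pearson


def test_pearson_identity_and_flip():
    x = [1.0, 4.0, 2.0, 7.0]
    assert pearson_r(x, x) == pytest.approx(1.0)
    assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)
    assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.981981, abs=1e-6)


def test_pearson_zero_variance_is_missing():
    assert math.isnan(pearson_r([1, 1, 1], [1, 2, 3]))


# ---------------------------------------------------------------- wilcoxon


def test_wilcoxon_identical_multisets_p_one():
    res = wilcoxon_rank_sum([1, 2, 2, 5], [2, 5, 1, 2])
    assert res.p_value == pytest.approx(1.0)


def test_wilcoxon_exact_example():
    res = wilcoxon_rank_sum([4, 5, 6], [1, 2, 3], alternative="greater")
    assert res.p_value == pytest.approx(1 / 20, abs=1e-15)


def test_wilcoxon_all_tied_degenerate():
    res = wilcoxon_rank_sum([3, 3], [3, 3, 3])
    assert res.degenerate and res.p_value == 1.0


@pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
def test_wilcoxon_exact_matches_enumeration_oracle(alternative):
    rng = np.random.default_rng(7)
    for _ in range(40):
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, 10 - n1 + 1))
        x = rng.integers(0, 5, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        got = wilcoxon_rank_sum(x, y, alternative).p_value
        want = wilcoxon_oracle(x, y, alternative)
        assert got == pytest.approx(want, abs=1e-12)


def test_wilcoxon_asymptotic_two_sided_symmetry():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    y = rng.normal(0.5, 1, size=25)
    assert (wilcoxon_rank_sum(x, y).p_value
            == pytest.approx(wilcoxon_rank_sum(y, x).p_value, abs=1e-12))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.integers(0, 6), min_size=1, max_size=5),
       st.lists(st.integers(0, 6), min_size=1, max_size=5))
def test_wilcoxon_p_valid_and_exact(x, y):
    res = wilcoxon_rank_sum(x, y)
    assert 0.0 <= res.p_value <= 1.0
    if not res.degenerate:
        assert res.p_value == pytest.approx(
            wilcoxon_oracle(x, y, "two_sided"), abs=1e-12)


# ---------------------------------------------------------------- KS


def test_ks_trivial_cases():
    assert ks_two_sample([1, 2, 3], [1, 2, 3]).statistic == 0.0
    assert ks_two_sample([1, 2], [5, 6, 7]).statistic == 1.0
    assert ks_two_sample([1, 2], [1.5, 3]).statistic == pytest.approx(0.5)


def test_ks_ecdf_walk_oracle():
    """D from an independent dense-grid ECDF sweep."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        x = rng.normal(size=int(rng.integers(2, 30)))
        y = rng.normal(0.3, 1.2, size=int(rng.integers(2, 30)))
        grid = np.union1d(x, y)
        diffs = [abs((x <= g).mean() - (y <= g).mean()) for g in grid]
        assert ks_two_sample(x, y).statistic == pytest.approx(max(diffs),
                                                              abs=1e-12)


# ---------------------------------------------------------------- hypergeom


def test_hypergeom_examples():
    assert hypergeom_tail(10, 5, 5, 0) == 1.0
    assert hypergeom_tail(10, 5, 5, 5) == pytest.approx(1 / 252, abs=1e-15)


def test_hypergeom_matches_fraction_oracle_small_universe():
    for N in range(1, 13):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeom_tail(N, K, n, k) == pytest.approx(
                        hypergeom_oracle(N, K, n, k), abs=1e-12)


def test_hypergeom_argument_errors():
    with pytest.raises(ValueError):
        hypergeom_tail(10, 12, 5, 2)
    with pytest.raises(ValueError):
        hypergeom_tail(10, 5, 5, 6)


# ---------------------------------------------------------------- chi2 / t


def test_chi2_independence_and_example():
    assert chi_square_2x2([[10, 10], [10, 10]]).statistic == 0.0
    assert chi_square_2x2([[7, 3], [7, 3]]).statistic == pytest.approx(0.0)
    res = chi_square_2x2([[20, 5], [10, 15]])
    assert res.statistic == pytest.approx(25 / 3, abs=1e-9)


def test_chi2_zero_margin_error():
    with pytest.raises(ValueError, match="margin"):
        chi_square_2x2([[0, 0], [5, 5]])


def test_welch_t_example_and_antisymmetry():
    res = t_test_two_sample([1, 2, 3], [4, 5, 6])
    assert res.statistic == pytest.approx(-3.674234614, abs=1e-6)
    swapped = t_test_two_sample([4, 5, 6], [1, 2, 3])
    assert swapped.statistic == pytest.approx(-res.statistic)
    assert swapped.p_value == pytest.approx(res.p_value)
    same = t_test_two_sample([1, 2, 3], [1, 2, 3])
    assert same.statistic == 0.0 and same.p_value == pytest.approx(1.0)


# ---------------------------------------------------------------- bonferroni


def test_bonferroni_arithmetic_and_order():
    out = bonferroni([0.3, 0.01], m=5)
    assert out.tolist() == [1.0, 0.05]
    assert bonferroni([0.5], m=1).tolist() == [0.5]
    p = np.linspace(0, 1, 11)
    adj = bonferroni(p, m=20)
    assert np.all(adj >= p) and np.all(adj <= 1)
    assert np.all(np.diff(adj) >= 0)  # order preserved


def test_bonferroni_errors():
    with pytest.raises(ValueError):
        bonferroni([1.2])
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], m=1)


# ---------------------------------------------------------------- roc auc


def test_roc_auc_examples():
    assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75
    assert roc_auc([3, 2, 1], [1, 1, 0]) == 1.0
    assert roc_auc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5


def test_roc_auc_complement_and_sklearn_crosscheck():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(4, 40))
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        auc = roc_auc(scores, labels)
        assert auc + roc_auc(scores, 1 - labels) == pytest.approx(1.0)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_roc_auc_single_class_error():
    with pytest.raises(ValueError):
        roc_auc([1, 2], [1, 1])


# ---------------------------------------------------------------- null sizes


def test_null_rejection_rates_near_nominal():
    """Two-sample tests reject at ~alpha under the null (n=30 per arm)."""
    rng = np.random.default_rng(42)
    hits = {"wilcoxon": 0, "ks": 0, "ttest": 0}
    B = 2000
    for _ in range(B):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        hits["wilcoxon"] += wilcoxon_rank_sum(x, y).p_value < 0.05
        hits["ks"] += ks_two_sample(x, y).p_value < 0.05
        hits["ttest"] += t_test_two_sample(x, y).p_value < 0.05
    for name, count in hits.items():
        assert abs(count / B - 0.05) <= 0.02, (name, count / B)
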