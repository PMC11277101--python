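"""Statistical battery: printed-value checks and independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as ss

from cohortdemog import (exact_binomial, levene_test, mann_whitney_u,
                         pearson_chi2_2x2, pooled_t_test, shapiro_normality)


# ---------------------------------------------------------------------------
# Pearson chi-square

def test_chi2_reported_survival_counts():
    """Immature survival 37/38 vs 35/37 gives the uncorrected Pearson
    statistic 0.3756 with p = 0.5400."""
    res = pearson_chi2_2x2(37, 1, 35, 2)
    assert round(res.statistic, 4) == 0.3756
    assert round(res.p, 4) == 0.5400
    assert res.df == 1


def test_chi2_identical_proportions_is_zero():
    assert pearson_chi2_2x2(10, 10, 20, 20).statistic == pytest.approx(0.0)


@pytest.mark.parametrize("seed", range(5))
def test_chi2_textbook_formula_oracle(seed):
    rng = np.random.default_rng(seed)
    a, b, c, d = rng.integers(1, 40, 4)
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert pearson_chi2_2x2(a, b, c, d).statistic == pytest.approx(expected)


def test_chi2_invariance_under_transpose_and_row_swap():
    res = pearson_chi2_2x2(5, 9, 12, 3)
    assert pearson_chi2_2x2(5, 12, 9, 3).statistic == pytest.approx(res.statistic)
    assert pearson_chi2_2x2(12, 3, 5, 9).statistic == pytest.approx(res.statistic)


def test_chi2_zero_margin_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        pearson_chi2_2x2(0, 0, 5, 5)


# ---------------------------------------------------------------------------
# Exact binomial

def test_binomial_reported_sex_ratios():
    res_a = exact_binomial(12, 37)
    assert round(res_a.p, 4) == 0.0470
    assert (round(100 * res_a.ci[0]), round(100 * res_a.ci[1])) == (18, 50)
    res_b = exact_binomial(16, 35)
    assert round(res_b.p, 4) == 0.7359
    assert (round(100 * res_b.ci[0]), round(100 * res_b.ci[1])) == (29, 63)


def test_binomial_symmetric_center_p_is_one():
    assert exact_binomial(10, 20).p == pytest.approx(1.0)


@pytest.mark.parametrize("n", [1, 2, 5, 13, 24, 37, 50])
@pytest.mark.parametrize("p0", [0.5, 0.3])
def test_binomial_matches_pmf_enumeration(n, p0):
    """Two-sided p equals the sum of all outcome probabilities no more
    likely than the observed count (exact enumeration oracle)."""
    for k in range(n + 1):
        pk = ss.binom.pmf(k, n, p0)
        oracle = float(sum(ss.binom.pmf(i, n, p0) for i in range(n + 1)
                           if ss.binom.pmf(i, n, p0) <= pk * (1 + 1e-10)))
        assert exact_binomial(k, n, p0).p == pytest.approx(min(1.0, oracle))


def test_binomial_half_null_equals_doubled_smaller_tail():
    for k, n in [(3, 10), (12, 37), (16, 35), (0, 6)]:
        doubled = min(1.0, 2 * min(ss.binom.cdf(k, n, 0.5),
                                   ss.binom.sf(k - 1, n, 0.5)))
        assert exact_binomial(k, n).p == pytest.approx(doubled)


# ---------------------------------------------------------------------------
# Pooled t-test

def test_t_df_contract_for_ten_per_group():
    rng = np.random.default_rng(1)
    res = pooled_t_test(rng.normal(size=10), rng.normal(size=10))
    assert res.df == 18


def test_t_identical_samples_null():
    x = [1.0, 2.0, 3.0]
    res = pooled_t_test(x, x)
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_t_formula_oracle():
    x = np.array([3.1, 4.5, 2.2, 5.0, 3.3])
    y = np.array([6.0, 5.1, 7.2, 6.6])
    sp2 = (((len(x) - 1) * np.var(x, ddof=1) + (len(y) - 1) * np.var(y, ddof=1))
           / (len(x) + len(y) - 2))
    t_manual = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
    assert pooled_t_test(x, y).statistic == pytest.approx(t_manual, abs=1e-12)


def test_t_zero_variance_cases():
    res_eq = pooled_t_test([2.0, 2.0], [2.0, 2.0])
    assert (res_eq.statistic, res_eq.p) == (0.0, 1.0)
    res_ne = pooled_t_test([2.0, 2.0], [3.0, 3.0])
    assert math.isinf(res_ne.statistic)
    assert "unequal means" in res_ne.note


# ---------------------------------------------------------------------------
# Levene

def test_levene_identical_samples():
    x = [1.0, 2.0, 5.0]
    res = levene_test(x, x)
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_levene_constant_groups_flagged():
    res = levene_test([2.0, 2.0], [5.0, 5.0])
    assert res.statistic == 0.0
    assert "no within-group variation" in res.note


def test_levene_reduces_to_anova_on_absolute_deviations():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 8)
    y = rng.normal(0, 3, 11)
    res = levene_test(x, y)
    f, p = ss.f_oneway(np.abs(x - x.mean()), np.abs(y - y.mean()))
    assert res.statistic == pytest.approx(f)
    assert res.p == pytest.approx(p)


# ---------------------------------------------------------------------------
# Mann-Whitney

def test_mw_complete_separation_u_zero():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0


def test_mw_identical_samples_u_half():
    res = mann_whitney_u([1.0, 2.5, 3.5], [2.0, 3.0, 4.0])
    # U1 + U2 = 9; no assertion on p here, just the U convention
    assert 0 <= res.statistic <= 4.5


def test_mw_exact_p_equals_enumeration():
    """n1 = n2 = 4, no ties: the exact two-sided p equals enumeration over
    all C(8,4) assignments of ranks to group 1."""
    x = [1.3, 2.9, 5.1, 7.7]
    y = [2.0, 4.4, 6.8, 9.9]
    combined = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(combined)}

    def u_of(group_ranks):
        r1 = sum(group_ranks)
        u1 = r1 - len(group_ranks) * (len(group_ranks) + 1) / 2
        return min(u1, 16 - u1)

    observed = u_of([ranks[v] for v in x])
    us = [u_of(c) for c in itertools.combinations(range(1, 9), 4)]
    p_exact = sum(1 for u in us if u <= observed) / len(us)
    res = mann_whitney_u(x, y)
    assert res.statistic == observed
    assert res.p == pytest.approx(p_exact)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=15),
       st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=15))
def test_mw_u1_plus_u2_is_n1n2(x, y):
    res = mann_whitney_u(x, y)
    u1 = float(ss.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").statistic)
    assert res.statistic == pytest.approx(min(u1, len(x) * len(y) - u1))
    assert 0 <= res.statistic <= len(x) * len(y) / 2


# ---------------------------------------------------------------------------

def test_shapiro_gate_handles_degenerate_input():
    res = shapiro_normality([1.0, 1.0, 1.0])
    assert math.isnan(res.p)
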