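"""Kaplan-Meier curves, restricted mean lifespan, log-rank test."""

import math

import numpy as np
import pytest

from cohortdemog import (SyntheticConfig, cohort_durations, generate_cohort,
                         km_fit, log_rank, mean_lifespan)


def test_uncensored_km_equals_empirical_survival():
    curve = km_fit([2, 4, 4, 7], [1, 1, 1, 1])
    assert list(curve.times) == [2, 4, 7]
    assert list(curve.surv) == pytest.approx([0.75, 0.25, 0.0])


def test_km_hand_worked_with_censoring():
    """Deaths at 2, 4, 5, 5, 7 with a censoring at 3: the product-limit
    table is S(2)=5/6, S(4)=5/6*3/4, S(5)=that*1/3, S(7)=0."""
    durations = [2, 3, 4, 5, 5, 7]
    events = [1, 0, 1, 1, 1, 1]
    curve = km_fit(durations, events)
    s = dict(zip(curve.times, curve.surv))
    assert s[2] == pytest.approx(5 / 6)
    assert s[4] == pytest.approx(5 / 6 * 3 / 4)
    assert s[5] == pytest.approx(5 / 6 * 3 / 4 * 1 / 3)
    assert s[7] == pytest.approx(0.0)


def test_all_censored_curve_stays_at_one():
    curve = km_fit([3, 6, 9], [0, 0, 0])
    assert np.all(curve.surv == 1.0)


def test_km_confidence_band_brackets_curve(gen_cohort):
    d, e = cohort_durations(gen_cohort)
    curve = km_fit(d, e)
    inner = curve.surv[curve.surv > 0]
    assert np.all(curve.ci_low[curve.surv > 0] <= inner + 1e-12)
    assert np.all(curve.ci_high >= curve.surv - 1e-12)


def test_km_cll_interval_hand_formula():
    """The pointwise band matches the complementary log-log (exponential
    Greenwood) formula computed directly for the 4-death example."""
    durations = np.array([2.0, 4, 4, 7])
    events = np.array([1, 1, 1, 1])
    curve = km_fit(durations, events)
    # at t=2: S=0.75, Greenwood sum = d/(n(n-d)) = 1/(4*3)
    s = 0.75
    gw = 1 / (4 * 3)
    se_cll = math.sqrt(gw) / abs(math.log(s))
    z = 1.959963984540054
    lo = s ** math.exp(z * se_cll)
    hi = s ** math.exp(-z * se_cll)
    assert curve.ci_low[0] == pytest.approx(lo, abs=1e-9)
    assert curve.ci_high[0] == pytest.approx(hi, abs=1e-9)


def test_rmst_uncensored_is_arithmetic_mean():
    assert mean_lifespan([2, 4, 4, 7], [1, 1, 1, 1]) == pytest.approx(4.25)
    assert mean_lifespan([10], [1]) == pytest.approx(10.0)


def test_rmst_generator_cohort_equals_mean_death_day(gen_cohort):
    d, e = cohort_durations(gen_cohort)
    assert np.all(e == 1)
    assert mean_lifespan(d, e) == pytest.approx(float(np.mean(d)))


def test_generator_lifespan_matches_configured_expectation():
    """Cohort mean death day vs the closed-form expectation from the
    configured incubation/development/lifespan laws (Monte-Carlo check)."""
    from scipy import stats as ss
    cfg = SyntheticConfig(seed=13, n_eggs=800, immature_survival=1.0)
    ds = generate_cohort(cfg, "d")
    d, e = cohort_durations(ds)

    def disc_mean(mean, sd):
        kmax = max(2, int(np.ceil(mean + 6 * sd)))
        ks = np.arange(1, kmax + 1)
        pmf = ss.norm.cdf(ks + 0.5, mean, sd) - ss.norm.cdf(ks - 0.5, mean, sd)
        pmf[0] = ss.norm.cdf(1.5, mean, sd)
        pmf[-1] += ss.norm.sf(kmax + 0.5, mean, sd)
        return float((ks * pmf).sum())

    kmax = 600
    sf = np.exp(-(np.arange(kmax) / cfg.adult_lifespan_scale)
                ** cfg.adult_lifespan_shape)
    mean_lifespan_days = float(sf.sum())   # E[ceil(L)] = sum_{k>=0} SF(k)
    expected = (disc_mean(cfg.incubation_mean, cfg.incubation_sd)
                + disc_mean(cfg.development_mean, cfg.development_sd)
                + mean_lifespan_days)
    assert float(np.mean(d)) == pytest.approx(expected, rel=0.03)


def test_log_rank_identical_groups_is_null():
    d = [3.0, 5, 8, 13]
    e = [1, 1, 0, 1]
    res = log_rank(d, e, d, e)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_log_rank_label_swap_symmetry(gen_pair):
    a, b = gen_pair
    da, ea = cohort_durations(a)
    db, eb = cohort_durations(b)
    r1 = log_rank(da, ea, db, eb)
    r2 = log_rank(db, eb, da, ea)
    assert r1.statistic == pytest.approx(r2.statistic)


def test_log_rank_hand_computed_small_example():
    """Two groups of 3, all deaths: O-E and hypergeometric variance terms
    accumulated by hand over the shared event grid."""
    da, db = [1.0, 3, 5], [2.0, 4, 6]
    times = sorted(da + db)
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n1 = sum(1 for v in da if v >= t)
        n2 = sum(1 for v in db if v >= t)
        d1 = da.count(t)
        d2 = db.count(t)
        n, d = n1 + n2, d1 + d2
        if n == 0 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2_hand = o_minus_e ** 2 / var
    res = log_rank(da, [1] * 3, db, [1] * 3)
    assert res.statistic == pytest.approx(chi2_hand, abs=1e-9)


def test_log_rank_invariant_under_monotone_time_transform(gen_pair):
    a, b = gen_pair
    da, ea = cohort_durations(a)
    db, eb = cohort_durations(b)
    base = log_rank(da, ea, db, eb)
    warped = log_rank(da ** 2, ea, db ** 2, eb)
    assert warped.statistic == pytest.approx(base.statistic)


def test_km_zero_censoring_equals_one_minus_ecdf():
    rng = np.random.default_rng(21)
    d = rng.integers(1, 40, 25).astype(float)
    curve = km_fit(d, np.ones_like(d))
    for t, s in zip(curve.times, curve.surv):
        assert s == pytest.approx(np.mean(d > t))


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        km_fit([], [])
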