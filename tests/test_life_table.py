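"""Survivorship/maternity schedules and trait summaries."""

import math

import numpy as np
import pytest

from cohortdemog import (CohortDataset, SyntheticConfig, build_schedule,
                         generate_cohort, read_schedule_tsv, summarize_traits,
                         write_schedule_tsv)

from conftest import make_individual


def test_no_mortality_schedule_hand_example():
    """Four eggs all alive past day 10; one female lays 10 hatched larvae
    on day 9: lx stays 1 and mx[9] = 10 * 0.5 / 1 living female."""
    recs = [make_individual("e1", emerged=None, died=12),
            make_individual("e2", emerged=None, died=12),
            make_individual("m", sex="male", emerged=8, died=12),
            make_individual("f", sex="female", emerged=8, died=12,
                            clutches=[(9, 10, 10, 0, 0)])]
    ds = CohortDataset(diet="d", records=recs, parental_sex_ratio=0.5)
    sched = build_schedule(ds, sex_ratio=0.5)
    assert np.all(sched.lx[:11] == 1.0)
    assert sched.mx[9] == pytest.approx(10 * 0.5 / 1)
    assert np.all(sched.mx[:8] == 0.0)


def test_everyone_dies_immature_gives_zero_maternity():
    recs = [make_individual(f"x{i}", emerged=None, died=6 + i)
            for i in range(4)]
    ds = CohortDataset(diet="d", records=recs, parental_sex_ratio=0.5)
    sched = build_schedule(ds)
    assert np.all(sched.mx == 0.0)
    assert sched.R0 == 0.0
    assert sched.warnings


def test_product_limit_hand_values(toy3_cohort):
    sched = build_schedule(toy3_cohort)
    assert list(sched.lx[:6]) == [1, 1, 1, 1, 1, pytest.approx(2 / 3)]
    assert sched.lx[6] == pytest.approx(2 / 3)


@pytest.mark.parametrize("seed", [0, 3, 9])
def test_product_limit_equals_simple_fraction_without_censoring(seed):
    ds = generate_cohort(SyntheticConfig(seed=seed), "d")
    pl = build_schedule(ds, product_limit=True)
    frac = build_schedule(ds, product_limit=False)
    assert np.allclose(pl.lx, frac.lx)


def test_censored_individual_handled_actuarially():
    """Censoring removes an individual from the risk set without an event:
    death 1/2 among those still at risk after the censoring."""
    recs = [make_individual("a", emerged=None, died=10),
            make_individual("b", died=None, censored=True),  # censored early
            make_individual("c", emerged=None, died=10)]
    # give the censored record a last-observation day of 4 via stage entry
    recs[1].day_hatched = 4
    recs[1].day_emerged_adult = None
    ds = CohortDataset(diet="d", records=recs, parental_sex_ratio=0.5)
    sched = build_schedule(ds)
    # at day 10: at risk 2, deaths 2 -> lx 0; before that lx = 1
    assert sched.lx[9] == 1.0
    assert sched.lx[10] == 0.0
    # simple-fraction handling differs (2/3 alive never hits 0 denominator)
    frac = build_schedule(ds, product_limit=False)
    assert frac.lx[10] == pytest.approx(0.0)


@pytest.mark.parametrize("ratio", [0.2, 0.45])
def test_mx_scales_linearly_in_sex_ratio(gen_cohort, ratio):
    base = build_schedule(gen_cohort, sex_ratio=ratio)
    doubled = build_schedule(gen_cohort, sex_ratio=2 * ratio)
    assert np.allclose(doubled.mx, 2 * base.mx)


def test_net_maternity_sum_equals_R0_downstream(gen_cohort):
    from cohortdemog import derive_params, solve_euler_lotka
    sched = build_schedule(gen_cohort)
    rm = solve_euler_lotka(sched)
    params = derive_params(rm, sched)
    assert params.R0 == pytest.approx(float(np.sum(sched.lx * sched.mx)))


def test_immature_survival_proportion_37_of_38():
    recs = [make_individual(f"i{i}", emerged=15 if i < 37 else None,
                            died=None if i < 37 else 10, censored=i < 37)
            for i in range(38)]
    ds = CohortDataset(diet="d", records=recs, parental_sex_ratio=0.5)
    traits = {t.trait: t for t in summarize_traits(ds)}
    surv = traits["immature_survival"]
    assert round(surv.mean, 2) == 0.97
    assert surv.extra == (37, 38)


def test_single_female_five_day_laying():
    clutches = [(20 + d, 10, 8, 1, 1) for d in range(5)]
    recs = [make_individual("f", sex="female", died=40, clutches=clutches)]
    ds = CohortDataset(diet="d", records=recs, parental_sex_ratio=0.5)
    traits = {t.trait: t for t in summarize_traits(ds)}
    assert traits["fecundity"].mean == 50
    assert traits["oviposition_period"].mean == 5
    assert traits["oviposition_rate"].mean == 10
    assert traits["fertility"].mean == 45  # hatched + embryonated
    assert traits["preoviposition_time"].mean == 5  # emerged day 15, first egg 20


def test_generator_fecundity_matches_configured_expectation():
    """Mean fecundity of a large monitored cohort agrees with the
    closed-form expectation of the configured laying curve within
    Monte-Carlo error (the oracle integrates curve x lifespan pmfs)."""
    from scipy import stats as ss
    cfg = SyntheticConfig(seed=7, n_eggs=600, n_pairs=None)
    ds = generate_cohort(cfg, "d")
    traits = {t.trait: t for t in summarize_traits(ds)}
    fec = traits["fecundity"]

    # independent expectation: E[sum_{u=0}^{L-p-1} e(u)]
    def curve(u):
        rise, peak = cfg.fecundity_rise_days, cfg.fecundity_peak_rate
        if u < rise:
            return peak * (u + 1) / rise
        return peak * (1 - cfg.fecundity_decay) ** (u - rise + 1)

    kmax = 400
    sf = np.exp(-(np.arange(kmax + 1) / cfg.adult_lifespan_scale)
                ** cfg.adult_lifespan_shape)
    pL = sf[:-1] - sf[1:]                      # death after k full adult days
    pmax = int(cfg.preovi_mean + 6 * cfg.preovi_sd)
    expected = 0.0
    for p in range(1, pmax + 1):
        wp = (ss.norm.cdf(p + .5, cfg.preovi_mean, cfg.preovi_sd)
              - ss.norm.cdf(p - .5, cfg.preovi_mean, cfg.preovi_sd))
        if p == 1:
            wp = ss.norm.cdf(1.5, cfg.preovi_mean, cfg.preovi_sd)
        cum = np.cumsum([curve(u) for u in range(kmax)])
        # lifespan of j adult days -> lays on the j - p days before death
        for j in range(1, kmax + 1):
            ndays = j - p
            if ndays > 0:
                expected += wp * pL[j - 1] * cum[ndays - 1]
    assert fec.mean == pytest.approx(expected, rel=0.05)


def test_schedule_tsv_round_trip(tmp_path, gen_cohort):
    sched = build_schedule(gen_cohort)
    path = tmp_path / "lt.tsv"
    write_schedule_tsv(sched, path)
    back = read_schedule_tsv(path)
    assert np.allclose(back.lx, sched.lx)
    assert np.allclose(back.mx, sched.mx)
    assert np.array_equal(back.ages, sched.ages)
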