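"""Synthetic two-diet rearing cohorts with known demographic ground truth.

The generator emulates the structure of a daily-census ladybird rearing
study: a batch of eggs laid on day 0, discretized-normal incubation and
immature development times, Bernoulli survival to adult emergence, sex
assigned at emergence from the parental sex ratio, a fixed number of
females paired and followed daily, and a triangular age-fecundity
curve — linear rise to a single peak followed by slow geometric
decay — with each egg hatching independently.  Adult lifespan follows a
discretized Weibull law calibrated so that most eggs are laid within
about 90 days of adult life.

``true_schedule`` returns the *expected* survivorship and maternity
schedules implied by the configured distributions (computed by direct
summation over the discrete supports, no sampling), so the intrinsic
rate of increase of the configuration is known exactly and parameter
recovery can be tested.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import stats

from .life_table import LifeTableSchedule
from .records import ClutchRecord, CohortDataset, IndividualRecord, FEMALE, MALE

__all__ = ["SyntheticConfig", "generate_cohort", "true_schedule",
           "fecundity_curve", "default_configs"]


@dataclass
class SyntheticConfig:
    """Generator parameters (all durations in days, rates in eggs/day).

    Defaults describe a cohort of 38 eggs with ~96% immature survival, a
    female-biased sex ratio, ten monitored pairs, and a fecundity curve
    rising over 10 days to 25 eggs/day then declining 2% per day —
    totalling roughly a thousand eggs over a ~75-day adult life.
    """

    n_eggs: int = 38
    incubation_mean: float = 4.2
    incubation_sd: float = 0.7
    development_mean: float = 11.3
    development_sd: float = 0.8
    immature_survival: float = 0.96
    sex_ratio: float = 0.675
    preovi_mean: float = 4.2
    preovi_sd: float = 1.2
    n_pairs: Optional[int] = 10          # None: follow every female
    fecundity_peak_rate: float = 25.0
    fecundity_rise_days: int = 10
    fecundity_decay: float = 0.02        # fractional decline per day after peak
    hatch_prob: float = 0.78
    embryonated_prob: float = 0.04
    adult_lifespan_shape: float = 2.2
    adult_lifespan_scale: float = 85.0
    female_weight_mean: float = 1.21
    male_weight_mean: float = 0.97
    weight_sd: float = 0.08
    seed: int = 0

    @property
    def fecundity_peak_day(self) -> int:
        """Adult age (days since emergence) of the oviposition peak."""
        return int(round(self.preovi_mean)) + self.fecundity_rise_days - 1

    def validate(self) -> None:
        for name in ("immature_survival", "hatch_prob", "embryonated_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} not in [0,1]")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValueError("sex_ratio must be in (0,1)")
        if not 0.0 <= self.fecundity_decay < 1.0:
            raise ValueError("fecundity_decay must be in [0,1)")
        positives = ("n_eggs", "incubation_mean", "development_mean",
                     "preovi_mean", "fecundity_peak_rate",
                     "fecundity_rise_days", "adult_lifespan_shape",
                     "adult_lifespan_scale")
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)


def fecundity_curve(config: SyntheticConfig, u) -> np.ndarray:
    """Expected eggs/day at oviposition age ``u`` (u = 0 on the first
    laying day): linear rise to the peak, then geometric decay."""
    u = np.asarray(u, dtype=float)
    rise = config.fecundity_rise_days
    peak = config.fecundity_peak_rate
    rising = peak * (u + 1.0) / rise
    falling = peak * (1.0 - config.fecundity_decay) ** (u - rise + 1.0)
    return np.where(u < rise, rising, falling) * (u >= 0)


# ---------------------------------------------------------------------------
# Discretized distributions (shared by the sampler and the expectation code)

def _disc_normal_pmf(mean: float, sd: float) -> np.ndarray:
    """pmf over integer days k >= 1 for round(Normal) clipped to >= 1.

    Index k of the returned array is P(K = k); index 0 is zero.
    """
    kmax = max(2, int(math.ceil(mean + 6 * sd)))
    pmf = np.zeros(kmax + 1)
    pmf[1] = stats.norm.cdf(1.5, mean, sd)
    for k in range(2, kmax + 1):
        pmf[k] = (stats.norm.cdf(k + 0.5, mean, sd)
                  - stats.norm.cdf(k - 0.5, mean, sd))
    pmf[kmax] += stats.norm.sf(kmax + 0.5, mean, sd)
    return pmf


def _sample_disc_normal(rng, mean: float, sd: float, size=None):
    x = rng.normal(mean, sd, size=size)
    k = np.floor(x + 0.5).astype(int)
    kmax = max(2, int(math.ceil(mean + 6 * sd)))
    return np.clip(k, 1, kmax)


def _weibull_sf(config: SyntheticConfig, k) -> np.ndarray:
    """P(adult survives more than k further days), k may be negative."""
    k = np.asarray(k, dtype=float)
    shape, scale = config.adult_lifespan_shape, config.adult_lifespan_scale
    with np.errstate(over="ignore"):
        return np.where(k <= 0, 1.0,
                        np.exp(-(np.maximum(k, 0) / scale) ** shape))


def _sample_lifespan_days(rng, config: SyntheticConfig) -> int:
    L = config.adult_lifespan_scale * rng.weibull(config.adult_lifespan_shape)
    return max(1, int(math.ceil(L)))


# ---------------------------------------------------------------------------

def generate_cohort(config: SyntheticConfig, diet: str) -> CohortDataset:
    """Simulate one diet's rearing cohort.

    Deterministic given (config.seed, diet): the diet label is folded
    into the random stream so two diets generated from one config differ.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(diet.encode())]))
    records: list[IndividualRecord] = []
    females: list[IndividualRecord] = []
    for i in range(config.n_eggs):
        rec = IndividualRecord(individual_id=f"{diet}-{i:03d}", diet=diet)
        inc = int(_sample_disc_normal(rng, config.incubation_mean,
                                      config.incubation_sd))
        dev = int(_sample_disc_normal(rng, config.development_mean,
                                      config.development_sd))
        rec.day_hatched = inc
        rec.stage_transitions = [("egg", 0), ("larva", inc)]
        if rng.random() < config.immature_survival:
            emerge = inc + dev
            rec.day_emerged_adult = emerge
            rec.stage_transitions.append(("adult", emerge))
            female = rng.random() < config.sex_ratio
            rec.sex = FEMALE if female else MALE
            mean_w = (config.female_weight_mean if female
                      else config.male_weight_mean)
            rec.adult_weight_mg = float(max(0.1, rng.normal(mean_w,
                                                            config.weight_sd)))
            rec.day_died = emerge + _sample_lifespan_days(rng, config)
            if female:
                females.append(rec)
        else:
            rec.day_died = inc + int(rng.integers(1, dev + 1))
        records.append(rec)

    if config.n_pairs is None or config.n_pairs >= len(females):
        monitored = females
    else:
        idx = rng.choice(len(females), size=config.n_pairs, replace=False)
        monitored = [females[k] for k in sorted(idx)]

    p_h = config.hatch_prob
    p_e = min(config.embryonated_prob, 1.0 - p_h)
    for f in monitored:
        preovi = int(_sample_disc_normal(rng, config.preovi_mean,
                                         config.preovi_sd))
        start = f.day_emerged_adult + preovi
        for day in range(start, f.day_died):          # lays until death
            u = day - start
            mean_eggs = float(fecundity_curve(config, u))
            n_eggs = int(rng.poisson(mean_eggs))
            if n_eggs == 0:
                continue
            hatched, embryonated, infertile = rng.multinomial(
                n_eggs, [p_h, p_e, 1.0 - p_h - p_e])
            f.reproduction.append(ClutchRecord(
                day_observed=day, eggs_laid=n_eggs, hatched=int(hatched),
                embryonated=int(embryonated), infertile=int(infertile)))

    dataset = CohortDataset(diet=diet, records=records,
                            parental_sex_ratio=config.sex_ratio,
                            sex_ratio_source="generator configuration")
    dataset.validate()
    return dataset


def true_schedule(config: SyntheticConfig,
                  tail_prob: float = 1e-7) -> LifeTableSchedule:
    """Expected (lx, mx) schedule implied by the configuration.

    Computed by summation over the discrete supports of incubation,
    development, pre-oviposition and lifespan; no random sampling.  The
    maternity schedule is the expectation of the empirical estimator:
    hatched larvae per fertile female alive at age x, thinned by the
    configured sex ratio, with "fertile" approximated as surviving past
    the pre-oviposition delay (the probability that a surviving female
    lays no eggs at all is negligible at the configured rates).
    """
    config.validate()
    pI = _disc_normal_pmf(config.incubation_mean, config.incubation_sd)
    pD = _disc_normal_pmf(config.development_mean, config.development_sd)
    pP = _disc_normal_pmf(config.preovi_mean, config.preovi_sd)
    s = config.immature_survival

    # horizon: emergence support + adult lifespan quantile
    l_max = int(math.ceil(config.adult_lifespan_scale
                          * (-math.log(tail_prob)) ** (1.0 / config.adult_lifespan_shape)))
    x_max = (len(pI) - 1) + (len(pD) - 1) + max(len(pP) - 1, l_max) + 1
    ages = np.arange(x_max + 1)

    lx = np.zeros_like(ages, dtype=float)
    num = np.zeros_like(ages, dtype=float)   # expected eggs/day, fertile female
    den = np.zeros_like(ages, dtype=float)   # P(fertile female alive at x)
    for i in range(1, len(pI)):
        if pI[i] == 0:
            continue
        for d in range(1, len(pD)):
            w = pI[i] * pD[d]
            if w == 0:
                continue
            emerge = i + d
            # immature-death branch: dies at i+u, u uniform on 1..d
            alive_imm = np.clip((i + d - ages) / d, 0.0, 1.0)
            alive_imm[ages < i + 1] = 1.0
            # adult branch: dies at emerge + L
            alive_adult = _weibull_sf(config, ages - emerge)
            lx += w * ((1.0 - s) * alive_imm + s * alive_adult)
            for p in range(1, len(pP)):
                wp = w * pP[p]
                if wp == 0:
                    continue
                start = emerge + p
                u = ages - start
                lay = fecundity_curve(config, np.maximum(u, 0)) * (u >= 0)
                num += wp * lay * alive_adult
                den += wp * _weibull_sf(config,
                                        np.maximum(ages - emerge, p))
    lx /= lx[0]          # == 1 up to rounding: everything alive at day 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(den > 1e-300,
                      config.sex_ratio * config.hatch_prob * num / den, 0.0)
    n_risk = np.rint(config.n_eggs * lx).astype(int)
    return LifeTableSchedule(ages, lx, mx, n_risk)


def default_configs(seed: int = 0) -> dict[str, SyntheticConfig]:
    """Two study-condition configurations: a higher-quality diet (larger
    fecundity, faster development, longer life) and a lower-quality one,
    with the fecundity ratio of roughly 1.6 between them."""
    diet_a = SyntheticConfig(seed=seed)
    diet_b = SyntheticConfig(
        seed=seed, development_mean=12.1, immature_survival=0.95,
        sex_ratio=0.543, preovi_mean=3.6, fecundity_peak_rate=16.0,
        adult_lifespan_scale=70.0)
    return {"diet_a": diet_a, "diet_b": diet_b}
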