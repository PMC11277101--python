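"""Age-specific survivorship and maternity schedules, and trait summaries.

The schedule follows the discrete life-table convention for a daily-census
rearing study:

* ``lx`` — probability that a newborn (an egg laid on cohort day 0) is
  alive at age ``x`` days, estimated by the product-limit method so that
  individuals censored alive leave the denominator at their censoring
  day.  With no censoring this reduces to the simple fraction alive.
* ``mx`` — expected female offspring per female alive at age ``x``:
  (hatched larvae recorded on day ``x``, summed over fertile females
  alive that day) / (fertile females alive that day) x (proportion of
  offspring assumed female).  The female proportion comes from the
  parental population, since progeny are not reared to adulthood.

An individual with death day ``d`` is counted alive through day ``d-1``.
``lx * mx`` is then the expected number of daughters produced on day
``x`` per newborn, and its sum over ages is the net reproductive rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import CohortDataset, IndividualRecord, FEMALE, MALE

__all__ = [
    "LifeTableSchedule",
    "TraitSummary",
    "build_schedule",
    "summarize_traits",
    "observation_span",
    "write_schedule_tsv",
    "read_schedule_tsv",
    "plot_schedule",
]


@dataclass
class LifeTableSchedule:
    """Daily ages with survivorship, maternity and at-risk counts."""

    ages: np.ndarray          # integer days, contiguous from 0
    lx: np.ndarray            # survivorship, lx[0] == 1, nonincreasing
    mx: np.ndarray            # female offspring per living female per day
    n_risk: np.ndarray        # individuals at risk at each age
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.lx = np.asarray(self.lx, dtype=float)
        self.mx = np.asarray(self.mx, dtype=float)
        self.n_risk = np.asarray(self.n_risk)
        n = len(self.ages)
        if not (len(self.lx) == len(self.mx) == len(self.n_risk) == n):
            raise ValueError("schedule arrays must have equal length")

    def net_maternity(self) -> np.ndarray:
        """Daily per-newborn daughter production, lx * mx."""
        return self.lx * self.mx

    @property
    def R0(self) -> float:
        """Net reproductive rate, sum of lx*mx."""
        return float(np.sum(self.net_maternity()))


@dataclass
class TraitSummary:
    """One summary row: mean +/- SE over n individuals (counts for ratios)."""

    trait: str
    mean: float
    se: Optional[float]
    n: int
    unit: str = ""
    extra: Optional[tuple[int, int]] = None   # e.g. (n_success, n_total)
    values: Optional[list[float]] = None      # raw per-individual values


def observation_span(rec: IndividualRecord) -> int:
    """Last day the individual is known to exist (death or censoring day).

    For a censored record the censoring day is the last day carrying any
    observation: the latest of the life-history milestones and clutch days,
    plus one (alive through that day).
    """
    if rec.day_died is not None:
        return rec.day_died
    days = [rec.day_laid]
    for d in (rec.day_hatched, rec.day_emerged_adult):
        if d is not None:
            days.append(d)
    days.extend(d for _, d in rec.stage_transitions)
    days.extend(c.day_observed for c in rec.reproduction)
    return max(days) + 1


def _product_limit(times: np.ndarray, events: np.ndarray,
                   ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier survivorship evaluated on an integer age grid.

    ``times`` are death/censoring days; a death at day t removes the
    individual from the living on day t, so S(x) = P(T > x - 1)... in
    grid terms lx[x] is the product over event days <= x.
    """
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = len(times)
    n_risk = n - np.searchsorted(times, ages, side="left")
    event_days = np.unique(times)
    at_risk = n - np.searchsorted(times, event_days, side="left")
    deaths = np.array([np.sum((times == t) & (events == 1))
                       for t in event_days])
    factors = np.where(at_risk > 0, 1.0 - deaths / np.maximum(at_risk, 1), 1.0)
    surv_after = np.cumprod(factors)
    # lx[x] = product over event days <= x; ages before the first event keep 1
    idx = np.searchsorted(event_days, ages, side="right")
    lx = np.concatenate([[1.0], surv_after])[idx]
    return lx, n_risk.astype(int)


def build_schedule(dataset: CohortDataset,
                   sex_ratio: Optional[float] = None,
                   product_limit: bool = True) -> LifeTableSchedule:
    """Construct the (lx, mx) schedule for one cohort.

    Parameters
    ----------
    dataset : CohortDataset
        Validated cohort; ages run on the cohort clock (egg laid = day 0).
    sex_ratio : float, optional
        Proportion of offspring assumed female; defaults to the dataset's
        parental sex ratio.
    product_limit : bool
        If True (default) lx is the product-limit estimate (censoring
        handled actuarially); if False, the simple fraction of the
        initial cohort alive (censored individuals treated as alive
        through their censoring day only).
    """
    if not dataset.records:
        raise ValueError("cannot build a schedule from an empty cohort")
    if sex_ratio is None:
        sex_ratio = dataset.parental_sex_ratio
    if not 0.0 < sex_ratio < 1.0:
        raise ValueError(f"sex_ratio {sex_ratio} not in (0,1)")

    times = np.array([observation_span(r) for r in dataset.records])
    events = np.array([0 if r.censored and r.day_died is None else 1
                       for r in dataset.records])
    max_age = int(times.max())
    ages = np.arange(max_age + 1)

    if product_limit:
        lx, n_risk = _product_limit(times, events, ages)
    else:
        lx = np.array([np.sum(times > x) / len(times) for x in ages])
        lx[0] = 1.0
        n_risk = np.array([int(np.sum(times >= x)) for x in ages])

    warnings: list[str] = []
    females = dataset.fertile_females()
    mx = np.zeros_like(ages, dtype=float)
    if not females:
        warnings.append("no fertile females: maternity schedule is all zero")
    else:
        hatched_by_day = np.zeros_like(ages, dtype=float)
        for f in females:
            for c in f.reproduction:
                if c.day_observed <= max_age:
                    hatched_by_day[c.day_observed] += c.hatched or 0
        # alive at x: day_died > x (censored females count as alive throughout)
        female_deaths = np.sort([f.day_died if f.day_died is not None
                                 else max_age + 1 for f in females])
        alive_females = (len(females)
                         - np.searchsorted(female_deaths, ages, side="right"))
        mx = np.where(alive_females > 0,
                      hatched_by_day / np.maximum(alive_females, 1)
                      * sex_ratio, 0.0)
    return LifeTableSchedule(ages, lx, mx, n_risk, warnings)


# ---------------------------------------------------------------------------
# Trait summaries (one row per biological trait of the rearing study)

def _mean_se(values: list[float], trait: str, unit: str = "") -> Optional[TraitSummary]:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return TraitSummary(trait, float(arr.mean()), se, len(arr), unit,
                        values=[float(v) for v in values])


def summarize_traits(dataset: CohortDataset) -> list[TraitSummary]:
    """Per-cohort summaries of the standard rearing-study traits.

    Rows: incubation time, immature development time, immature survival,
    pre-oviposition time, fecundity, fertility, oviposition rate,
    oviposition period, female weight, male weight, sex ratio.  Traits
    with no eligible individuals are omitted.

    Conventions: pre-oviposition time is counted from adult emergence
    (pairs are formed at emergence); the oviposition period is the
    inclusive span between the first and last day with eggs; fertility
    counts hatched + embryonated eggs; the oviposition rate is each
    female's fecundity divided by her oviposition period, averaged.
    """
    out: list[TraitSummary] = []
    recs = dataset.records

    incubation = [r.day_hatched - r.day_laid for r in recs
                  if r.day_hatched is not None]
    out.append(_mean_se(incubation, "incubation_time", "days"))

    development = [r.day_emerged_adult - r.day_hatched for r in recs
                   if r.day_emerged_adult is not None and r.day_hatched is not None]
    out.append(_mean_se(development, "immature_development_time", "days"))

    entered = [r for r in recs if r.day_hatched is not None]
    if entered:
        emerged = sum(1 for r in entered if r.day_emerged_adult is not None)
        n = len(entered)
        p = emerged / n
        out.append(TraitSummary("immature_survival", p,
                                math.sqrt(p * (1 - p) / n), n, "proportion",
                                extra=(emerged, n)))

    females = dataset.fertile_females()
    preovi, fecundity, fertility, rate, period = [], [], [], [], []
    for f in females:
        days = f.oviposition_days()
        if not days:
            continue
        if f.day_emerged_adult is not None:
            preovi.append(days[0] - f.day_emerged_adult)
        span = days[-1] - days[0] + 1
        fecundity.append(f.total_eggs())
        fertility.append(f.total_fertile_eggs())
        period.append(span)
        rate.append(f.total_eggs() / span)
    out.append(_mean_se(preovi, "preoviposition_time", "days"))
    out.append(_mean_se(fecundity, "fecundity", "eggs"))
    out.append(_mean_se(fertility, "fertility", "fertile eggs"))
    out.append(_mean_se(rate, "oviposition_rate", "eggs/day"))
    out.append(_mean_se(period, "oviposition_period", "days"))

    fw = [r.adult_weight_mg for r in recs
          if r.sex == FEMALE and r.adult_weight_mg is not None]
    mw = [r.adult_weight_mg for r in recs
          if r.sex == MALE and r.adult_weight_mg is not None]
    out.append(_mean_se(fw, "female_weight", "mg"))
    out.append(_mean_se(mw, "male_weight", "mg"))

    from .records import observed_sex_counts
    nf, nm = observed_sex_counts(dataset)
    if nf + nm > 0:
        p = nf / (nf + nm)
        out.append(TraitSummary("sex_ratio_percent_female", 100 * p,
                                100 * math.sqrt(p * (1 - p) / (nf + nm)),
                                nf + nm, "% female", extra=(nf, nm)))
    return [t for t in out if t is not None]


# ---------------------------------------------------------------------------
# Export

def write_schedule_tsv(schedule: LifeTableSchedule, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("x\tlx\tmx\tn_risk\n")
        for x, l, m, nr in zip(schedule.ages, schedule.lx, schedule.mx,
                               schedule.n_risk):
            fh.write(f"{x}\t{l:.10g}\t{m:.10g}\t{nr}\n")


def read_schedule_tsv(path) -> LifeTableSchedule:
    ages, lx, mx, n_risk = [], [], [], []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split("\t")
        if header[:3] != ["x", "lx", "mx"]:
            raise ValueError(f"{path}: not a life-table TSV")
        for line in fh:
            parts = line.split("\t")
            ages.append(int(parts[0]))
            lx.append(float(parts[1]))
            mx.append(float(parts[2]))
            n_risk.append(int(parts[3]) if len(parts) > 3 else 0)
    return LifeTableSchedule(np.array(ages), np.array(lx), np.array(mx),
                             np.array(n_risk))


def plot_schedule(schedule: LifeTableSchedule, path, title: str = "") -> None:
    """Survivorship and daily offspring curves against age (PNG/PDF)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(7, 4))
    ax1.plot(schedule.ages, schedule.lx, color="black", label="$l_x$")
    ax1.set_xlabel("age (days)")
    ax1.set_ylabel("survivorship $l_x$")
    ax1.set_ylim(0, 1.05)
    ax2 = ax1.twinx()
    ax2.plot(schedule.ages, schedule.mx, "o-", mfc="white", color="gray",
             markersize=3, label="$m_x$")
    ax2.set_ylabel("female offspring per female ($m_x$)")
    if title:
        ax1.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
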