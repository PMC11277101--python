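"""Kaplan-Meier survival over the entire life cycle and the log-rank test.

The lifespan clock starts on the day the egg was laid, so immature
deaths are events like adult deaths; censored individuals (alive at
study end) enter at-risk sets until their censoring day.  Pointwise 95%
confidence bands use the complementary log-log (exponential Greenwood)
transform.  The restricted mean survival time — the area under the
curve up to the last observed time — is the reported mean lifespan and
equals the arithmetic mean of the death days when nothing is censored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time

from .inference import TestResult
from .life_table import observation_span
from .records import CohortDataset

__all__ = [
    "KMCurve",
    "km_fit",
    "mean_lifespan",
    "log_rank",
    "cohort_durations",
    "write_km_tsv",
]


@dataclass
class KMCurve:
    """Product-limit survival curve on the observed event-time grid."""

    times: np.ndarray
    surv: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        if np.any(np.diff(self.surv) > 1e-12):
            raise ValueError("survival curve must be nonincreasing")

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.surv[idx])


def cohort_durations(dataset: CohortDataset) -> tuple[np.ndarray, np.ndarray]:
    """(durations, events) for a cohort: death day on the cohort clock,
    or the censoring day with event = 0."""
    durations = np.array([observation_span(r) for r in dataset.records],
                         dtype=float)
    events = np.array([0 if r.censored and r.day_died is None else 1
                       for r in dataset.records], dtype=int)
    return durations, events


def km_fit(durations: Sequence[float], events: Sequence[int],
           alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier fit with pointwise (1 - alpha) confidence bands."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(durations) == 0:
        raise ValueError("empty input")
    if (durations <= 0).any():
        raise ValueError("durations must be positive")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(durations, event_observed=events)
    # drop the automatic t=0 origin row; keep observed event/censor times
    times = kmf.survival_function_.index.to_numpy()[1:]
    surv = kmf.survival_function_.iloc[1:, 0].to_numpy()
    ci = kmf.confidence_interval_.iloc[1:]
    ev_table = kmf.event_table.iloc[1:]
    return KMCurve(times=times, surv=surv,
                   ci_low=ci.iloc[:, 0].to_numpy(),
                   ci_high=ci.iloc[:, 1].to_numpy(),
                   n_risk=ev_table["at_risk"].to_numpy(),
                   n_event=ev_table["observed"].to_numpy())


def mean_lifespan(durations: Sequence[float], events: Sequence[int]) -> float:
    """Restricted mean survival time up to the largest observed time."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    return float(restricted_mean_survival_time(kmf, t=durations.max()))


def log_rank(durations_a: Sequence[float], events_a: Sequence[int],
             durations_b: Sequence[float], events_b: Sequence[int]) -> TestResult:
    """Two-group log-rank test (chi-square with 1 df)."""
    if len(durations_a) == 0 or len(durations_b) == 0:
        raise ValueError("both groups must be nonempty")
    res = logrank_test(durations_a, durations_b,
                       event_observed_A=events_a, event_observed_B=events_b)
    return TestResult("log_rank", float(res.test_statistic),
                      float(res.p_value), df=1.0,
                      n_per_group=(len(durations_a), len(durations_b)))


def write_km_tsv(curve: KMCurve, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time\tn_risk\tn_event\tsurv\tci_low\tci_high\n")
        for t, nr, ne, s, lo, hi in zip(curve.times, curve.n_risk,
                                        curve.n_event, curve.surv,
                                        curve.ci_low, curve.ci_high):
            fh.write(f"{t:g}\t{int(nr)}\t{int(ne)}\t{s:.10g}\t{lo:.10g}\t"
                     f"{hi:.10g}\n")
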