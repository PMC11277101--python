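"""Jackknife pseudo-value estimation for cohort-level statistics.

Demographic parameters are computed once from all females pooled, so a
single number per cohort exists and groups cannot be compared directly.
The delete-one jackknife produces pseudo-values

    P_j = n * E_all - (n - 1) * E_{-j},   j = 1..n

where E_all is the statistic on the full cohort and E_{-j} on the
cohort with female j removed.  Their mean and standard error give the
reported estimate, and the pseudo-value vectors feed two-group tests.

The leave-one-out unit is one fertile female (with her whole
reproduction ledger).  Immatures, males and infertile females are never
dropped: removing them could zero the net reproductive rate of a
replicate even though the cohort clearly reproduces, a known artifact
of jackknifing whole life tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .records import CohortDataset
from .demography import (PARAM_NAMES, cohort_demography, derive_params,
                         solve_euler_lotka)
from .life_table import build_schedule
from .inference import TestResult, mann_whitney_u, pooled_t_test

__all__ = [
    "JackknifeResult",
    "jackknife_statistic",
    "jackknife_demography",
    "compare_jackknife",
]


@dataclass
class JackknifeResult:
    """Full-data estimate plus pseudo-values with their mean and SE."""

    statistic: str
    estimate_all: float
    pseudo_values: np.ndarray
    n: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.pseudo_values = np.asarray(self.pseudo_values, dtype=float)
        if len(self.pseudo_values) != self.n or self.n < 2:
            raise ValueError("need n >= 2 pseudo-values")

    @property
    def mean(self) -> float:
        return float(self.pseudo_values.mean())

    @property
    def se(self) -> float:
        return float(self.pseudo_values.std(ddof=1) / math.sqrt(self.n))


def _loo_units(dataset: CohortDataset,
               units: Optional[Sequence[str]]) -> list[str]:
    if units is None:
        units = [f.individual_id for f in dataset.fertile_females()]
    units = list(units)
    if len(units) < 2:
        raise ValueError("jackknife needs at least 2 leave-one-out units")
    return units


def jackknife_statistic(dataset: CohortDataset,
                        statistic: Callable[[CohortDataset], float],
                        units: Optional[Sequence[str]] = None,
                        name: str = "statistic") -> JackknifeResult:
    """Delete-one jackknife of an arbitrary cohort statistic.

    ``units`` lists the individual_ids removed one at a time; by default
    the cohort's fertile females.  The statistic must be defined on the
    full cohort and on every leave-one-out subset; a failure is reported
    with the offending unit named.
    """
    units = _loo_units(dataset, units)
    n = len(units)
    e_all = float(statistic(dataset))
    pseudo = np.empty(n)
    for j, uid in enumerate(units):
        subset = dataset.drop_individual(uid)
        try:
            e_minus = float(statistic(subset))
        except Exception as exc:
            raise ValueError(
                f"statistic undefined after removing '{uid}': {exc}") from exc
        pseudo[j] = n * e_all - (n - 1) * e_minus
    return JackknifeResult(name, e_all, pseudo, n)


def jackknife_demography(dataset: CohortDataset,
                         sex_ratio: Optional[float] = None,
                         tol: float = 1e-10) -> dict[str, JackknifeResult]:
    """Jackknife all five growth parameters in one pass.

    Each leave-one-out replicate rebuilds the schedule and re-solves the
    Euler-Lotka equation (no linearization), so one pass yields
    pseudo-values for rm, R0, tau, lambda and DT together.  Biologically
    inconsistent pseudo-values (negative DT or tau from a replicate that
    crosses R0 = 1) are flagged, not clipped.
    """
    units = _loo_units(dataset, None)
    n = len(units)
    full = cohort_demography(dataset, sex_ratio=sex_ratio, tol=tol)
    all_vals = full.as_dict()
    pseudo = {p: np.empty(n) for p in PARAM_NAMES}
    for j, uid in enumerate(units):
        subset = dataset.drop_individual(uid)
        try:
            schedule = build_schedule(subset, sex_ratio=sex_ratio)
            rm = solve_euler_lotka(schedule, tol=tol)
            loo = derive_params(rm, schedule).as_dict()
        except Exception as exc:
            raise ValueError(
                f"demography undefined after removing '{uid}': {exc}") from exc
        for p in PARAM_NAMES:
            pseudo[p][j] = n * all_vals[p] - (n - 1) * loo[p]
    results = {}
    for p in PARAM_NAMES:
        res = JackknifeResult(p, all_vals[p], pseudo[p], n)
        if p in ("tau", "DT") and (pseudo[p] <= 0).any():
            res.flags.append(f"biologically inconsistent pseudo-values for {p}"
                             " (nonpositive); review the cohort")
        results[p] = res
    return results


def compare_jackknife(group_a: JackknifeResult, group_b: JackknifeResult,
                      method: str = "t_test") -> TestResult:
    """Two-group test on pseudo-value vectors of the same statistic."""
    if group_a.statistic != group_b.statistic:
        raise ValueError(f"mismatched statistics: '{group_a.statistic}' vs "
                         f"'{group_b.statistic}'")
    if method == "t_test":
        return pooled_t_test(group_a.pseudo_values, group_b.pseudo_values)
    if method == "mann_whitney":
        return mann_whitney_u(group_a.pseudo_values, group_b.pseudo_values)
    raise ValueError(f"unknown method '{method}'")
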