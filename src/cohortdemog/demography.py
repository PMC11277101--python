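"""Population growth parameters from a life-table schedule.

The intrinsic rate of increase r_m is the unique root of the discrete
Euler-Lotka equation

    1 = sum_x exp(-r (x+1)) l_x m_x

with x the age in days since the egg was laid.  The exponent uses x+1:
eggs recorded on day x were laid during the preceding 24 h interval and
are discounted at the end of that interval, the usual correction for a
daily census.  The left-hand side is strictly decreasing in r whenever
the net maternity schedule is nonzero, so bisection on a sign-changing
bracket converges to the unique root.

Derived quantities: net reproductive rate R0 = sum l_x m_x, mean
generation time tau = ln(R0)/r_m, finite rate of increase lambda =
exp(r_m), doubling time DT = ln(2)/r_m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .life_table import LifeTableSchedule

__all__ = [
    "DemographicParams",
    "NoRootError",
    "BracketError",
    "euler_lotka_lhs",
    "solve_euler_lotka",
    "derive_params",
    "cohort_demography",
    "PARAM_NAMES",
]

PARAM_NAMES = ("rm", "R0", "tau", "lam", "DT")


class NoRootError(ValueError):
    """The schedule has zero net maternity; the growth rate is undefined."""


class BracketError(ValueError):
    """The search interval does not bracket the Euler-Lotka root."""


@dataclass
class DemographicParams:
    """The five growth parameters of one cohort.

    Units: rm and lam in female/female/day, tau and DT in days, R0 in
    female offspring per female.  When rm = 0 (R0 = 1), tau and DT are
    infinite and ``degenerate`` is set.
    """

    rm: float
    R0: float
    tau: float
    lam: float
    DT: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {"rm": self.rm, "R0": self.R0, "tau": self.tau,
                "lam": self.lam, "DT": self.DT}


def euler_lotka_lhs(r: float, schedule: LifeTableSchedule) -> float:
    """sum exp(-r (x+1)) l_x m_x, truncated at the last reproductive age."""
    phi = schedule.net_maternity()
    nz = np.nonzero(phi)[0]
    if len(nz) == 0:
        return 0.0
    last = nz[-1] + 1
    x = schedule.ages[:last].astype(float)
    return float(np.sum(np.exp(-r * (x + 1.0)) * phi[:last]))


def solve_euler_lotka(schedule: LifeTableSchedule, tol: float = 1e-10,
                      bracket: tuple[float, float] = (-1.0, 2.0),
                      max_iter: int = 200) -> float:
    """Bisection solution of the Euler-Lotka equation.

    Returns r_m with |f(r_m)| <= tol where f(r) = sum exp(-r(x+1)) l_x m_x - 1.
    Raises NoRootError when the schedule has no reproduction (R0 = 0) and
    BracketError when f does not change sign on ``bracket``.
    """
    if schedule.R0 <= 0.0:
        raise NoRootError("net reproductive rate is zero: no Euler-Lotka root")
    lo, hi = bracket
    if not lo < hi:
        raise BracketError(f"invalid bracket {bracket}")
    f_lo = euler_lotka_lhs(lo, schedule) - 1.0
    f_hi = euler_lotka_lhs(hi, schedule) - 1.0
    if f_lo < 0.0 or f_hi > 0.0:
        raise BracketError(
            f"f({lo}) = {f_lo:.3g}, f({hi}) = {f_hi:.3g}: no sign change; "
            "widen the bracket (f is decreasing, so choose lo with f(lo) > 0 "
            "and hi with f(hi) < 0)")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = euler_lotka_lhs(mid, schedule) - 1.0
        if abs(f_mid) <= tol:
            return mid
        if f_mid > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def derive_params(rm: float, schedule: LifeTableSchedule) -> DemographicParams:
    """R0, tau, lambda and DT from a solved r_m and its schedule."""
    R0 = schedule.R0
    lam = math.exp(rm)
    if rm == 0.0:
        return DemographicParams(rm=0.0, R0=R0, tau=math.inf, lam=1.0,
                                 DT=math.inf, degenerate=True)
    tau = math.log(R0) / rm if R0 > 0 else math.nan
    DT = math.log(2.0) / rm
    return DemographicParams(rm=rm, R0=R0, tau=tau, lam=lam, DT=DT)


def cohort_demography(dataset, sex_ratio: Optional[float] = None,
                      tol: float = 1e-10) -> DemographicParams:
    """Schedule construction + Euler-Lotka solve + derived parameters."""
    from .life_table import build_schedule
    schedule = build_schedule(dataset, sex_ratio=sex_ratio)
    rm = solve_euler_lotka(schedule, tol=tol)
    return derive_params(rm, schedule)
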