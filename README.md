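# cohortdemog

Life-table demography for insect rearing cohorts: from individual-level
daily records to age-specific survivorship and maternity schedules,
Euler–Lotka population growth parameters with jackknife standard
errors, and a complete two-diet statistical comparison.

The package is aimed at researchers who rear a predator or other insect
cohort on alternative foods (e.g. a ladybird on two aphid species) and
need to decide which food better supports population growth. It
provides the whole analysis chain such studies report: the biological
trait table, the demographic parameter table with significance letters,
and Kaplan–Meier survival curves with a log-rank test — plus a
synthetic cohort generator with analytically known ground truth so the
estimators can be validated end to end.

## The model

For a cohort followed daily from the egg (age `x` in days, day 0 = day
the egg was laid), the schedules are

- `l_x` — probability a newborn is alive at age `x` (product-limit
  estimate over the whole cohort, immature mortality included);
- `m_x` — daughters per female alive at age `x`: hatched larvae
  recorded that day per living fertile female, times the parental
  proportion female.

The intrinsic rate of increase `r_m` is the unique root of the discrete
Euler–Lotka equation

```
1 = Σ_x exp(−r_m (x+1)) l_x m_x
```

solved by bisection, with the derived set `R0 = Σ l_x m_x`,
`τ = ln R0 / r_m`, `λ = exp(r_m)` and `DT = ln 2 / r_m`. Standard
errors come from delete-one-female jackknife pseudo-values
`P_j = n·E_all − (n−1)·E_−j`, and diets are compared on the
pseudo-value vectors (t-test or Mann–Whitney, selected by a
normality/homogeneity decision rule). See `docs/methods.md` for every
convention and its rationale.

## Worked example

```python
from cohortdemog import (build_schedule, derive_params, generate_cohort,
                         solve_euler_lotka, true_schedule)
from cohortdemog.synthetic import SyntheticConfig

cfg = SyntheticConfig(seed=11)          # 38 eggs, 10 monitored females
cohort = generate_cohort(cfg, "diet_a")
schedule = build_schedule(cohort)
rm = solve_euler_lotka(schedule)
print(derive_params(rm, schedule).as_dict())
print(solve_euler_lotka(true_schedule(cfg)))   # analytic ground truth
```

prints

```
{'rm': 0.1731, 'R0': 459.2993, 'tau': 35.4151, 'lam': 1.1890, 'DT': 4.0047}
0.1774
```

(rounded): the cohort's net reproductive rate is ~459 daughters per
newborn female, the population multiplies by ~1.19 per day and doubles
every ~4 days, and the estimate recovers the configuration's analytic
`r_m` of 0.1774 to within 0.005. Comparing two diets whose laying
curves differ by the factor 1.6 (`examples/03_jackknife_comparison.py`):

```
param             diet_a             diet_b   t-test
   rm     0.1775 ± 0.0037     0.1504 ± 0.0034  t =   5.36, df = 18, p = 0.0000
   R0   488.5785 ± 21.7106   220.6758 ± 9.5322  t =  11.30, df = 18, p = 0.0000
```

— the richer diet supports significantly faster population growth.

The `examples/` directory holds one short script per capability
(simulation, schedules and growth rates, jackknife comparison, survival
curves, the full report, and the published-count checks). A thin CLI
mirrors them:

```
cohortdemog simulate --seed 3 --diet dietA --out a.csv
cohortdemog analyze --diet-a-csv a.csv --diet-b-csv b.csv \
    --diet-a dietA --diet-b dietB --out report/
```

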