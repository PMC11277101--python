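"""Generate a synthetic rearing cohort and summarize its biological traits.

A cohort of 38 eggs is followed daily from laying to death; ten emerged
females are paired and their clutches inspected for hatched, embryonated
and infertile eggs.  The trait table mirrors a classic rearing-study
summary (development times, survival, fecundity, weights, sex ratio).
"""

from cohortdemog import SyntheticConfig, generate_cohort, summarize_traits

cfg = SyntheticConfig(seed=1)
cohort = generate_cohort(cfg, "diet_a")

print(f"cohort '{cohort.diet}': {len(cohort.records)} individuals, "
      f"{len(cohort.fertile_females())} fertile females\n")
for t in summarize_traits(cohort):
    se = f" ± {t.se:.2f}" if t.se else ""
    extra = f"  {t.extra}" if t.extra else ""
    print(f"  {t.trait:<28} {t.mean:8.2f}{se}  (n={t.n}, {t.unit}){extra}")

print("\nEach row is a cohort mean ± SE; counts in parentheses are the "
      "(successes, total) pairs behind proportions.")
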