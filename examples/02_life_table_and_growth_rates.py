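"""Build the lx/mx schedule, solve the Euler-Lotka equation, and compare
the estimate with the generator's analytic ground truth.

rm is the root of 1 = sum exp(-r(x+1)) lx mx; R0 = sum lx mx daughters
per newborn female; lambda = exp(rm) per-day multiplication; DT doubling
time; tau mean generation time.
"""

from cohortdemog import (SyntheticConfig, build_schedule, derive_params,
                         generate_cohort, solve_euler_lotka, true_schedule)

cfg = SyntheticConfig(seed=11)
cohort = generate_cohort(cfg, "diet_a")
schedule = build_schedule(cohort)

rm = solve_euler_lotka(schedule)
params = derive_params(rm, schedule)
print("estimated from the simulated cohort:")
for name, value in params.as_dict().items():
    print(f"  {name:>4} = {value:.4f}")

truth = true_schedule(cfg)
rm_true = solve_euler_lotka(truth)
print(f"\nanalytic ground truth of the configuration: rm = {rm_true:.4f}")
print(f"absolute recovery error: {abs(rm - rm_true):.5f} per day")
print("\nA positive rm means the population grows; at rm ~ 0.18/day it "
      "doubles every ~3.9 days under these schedules.")
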