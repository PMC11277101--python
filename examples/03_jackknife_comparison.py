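"""Jackknife the growth parameters of two diets and compare them.

Because one cohort yields a single rm, groups are compared through
delete-one-female pseudo-values P_j = n*E_all - (n-1)*E_-j; their mean
and SE give the reported estimate and the vectors feed a pooled t-test
(df = nA + nB - 2).
"""

from cohortdemog import compare_jackknife, generate_cohort, jackknife_demography
from cohortdemog.synthetic import default_configs

cfgs = default_configs(seed=2)
a = generate_cohort(cfgs["diet_a"], "diet_a")
b = generate_cohort(cfgs["diet_b"], "diet_b")

jk_a = jackknife_demography(a)
jk_b = jackknife_demography(b)

print(f"{'param':>5} {'diet_a':>18} {'diet_b':>18}   t-test")
for p in ("rm", "R0", "tau", "lam", "DT"):
    ra, rb = jk_a[p], jk_b[p]
    res = compare_jackknife(ra, rb, method="t_test")
    print(f"{p:>5} {ra.mean:10.4f} ± {ra.se:<6.4f}"
          f" {rb.mean:10.4f} ± {rb.se:<6.4f}"
          f"  t = {res.statistic:6.2f}, df = {res.df:.0f}, p = {res.p:.4f}")

print("\ndiet_a's richer fecundity curve should yield higher rm and R0; "
      "p < 0.05 marks a significant diet effect on that parameter.")
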