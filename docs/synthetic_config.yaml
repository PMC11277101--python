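# Synthetic cohort generator configuration template.
# All durations in days, rates in eggs/day. Remove any key to keep its
# default. Used by:  cohortdemog simulate --config this_file.yaml
n_eggs: 38                 # eggs starting the cohort
incubation_mean: 4.2
incubation_sd: 0.7
development_mean: 11.3     # hatch -> adult emergence
development_sd: 0.8
immature_survival: 0.96    # probability a larva reaches adulthood
sex_ratio: 0.675           # proportion female (parental population)
preovi_mean: 4.2           # emergence -> first egg
preovi_sd: 1.2
n_pairs: 10                # females followed daily (null = all)
fecundity_peak_rate: 25.0  # eggs/day at the oviposition peak
fecundity_rise_days: 10    # days from first egg to the peak
fecundity_decay: 0.02      # fractional decline per day after the peak
hatch_prob: 0.78           # egg -> hatched larva
embryonated_prob: 0.04     # egg -> fertile but unhatched
adult_lifespan_shape: 2.2  # Weibull shape
adult_lifespan_scale: 85.0 # Weibull scale (days of adult life)
female_weight_mean: 1.21   # mg at emergence
male_weight_mean: 0.97
weight_sd: 0.08
seed: 0
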