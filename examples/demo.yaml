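# Desk-scale demonstration scenario (full pipeline in ~seconds).
# The packaged subcohort/full-cohort scales are available from
# tweethood.subcohort_scenario() / full_cohort_scenario().
n_zones: 36
n_individuals: 2000
tweets_per_zone: 400.0
seed: 42
effect_bmi_tertile2: -0.65
effect_bmi_tertile3: -0.85
binary_channels:
  hypertension:
    characteristic: happy
    baseline_prevalence: 0.49
    log_pr_tertile2: -0.0834
    log_pr_tertile3: -0.0619
  diabetes:
    characteristic: happy
    baseline_prevalence: 0.126
    log_pr_tertile2: 0.0198
    log_pr_tertile3: -0.1054
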