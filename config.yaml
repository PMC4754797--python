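# Full default configuration for `naccsub run --config config.yaml`.
# Every key is optional; omitted keys fall back to these same defaults.

seed: 0
output_dir: pipeline_out
run_glm: true            # false skips BOLD simulation + GLM and clusters the
                         # directly generated response patterns instead

generator:
  n_hc: 45               # healthy controls
  n_mdd: 44              # depressed patients
  response_noise_sd: 0.08   # per-condition beta noise (percent-signal units)
  bold_noise_sd: 0.1        # BOLD white noise (percent of mean signal)
  female_proportion: 0.73
  age_range: [20.0, 55.0]
  missing_rate: 0.0         # fraction of symptom scores blanked at random
  # symptom shifts tied to latent right-ROI subtypes (raw score units);
  # omit the block entirely to keep these defaults
  symptom_effects:
    - {item: "Suicidal ideation (HAM-D)", subtype: hyperactive, shift: 1.5}
    - {item: "Suicidal ideation (HAM-D)", subtype: suppressed, shift: 1.5}
    - {item: "I would enjoy looking smart when I have made an effort with my appearance (SHAPS)",
       subtype: hyperactive, shift: 1.0}
    - {item: "I would enjoy looking smart when I have made an effort with my appearance (SHAPS)",
       subtype: suppressed, shift: 1.0}

glm:
  tr: 2.0                # repetition time, seconds
  n_vols: 272            # volumes per session
  drop_initial: 5        # pre-task volumes removed before fitting
  n_sessions: 2
  trials_per_condition: 15   # 75 trials per session

clustering:
  k_max: 8
  alpha: 0.05            # significance gate for the cluster main effect

sda:
  min_variables: 1       # RFE stops when this many items remain
  alpha: 0.05            # Bonferroni base level for correlation flags
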