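description: no aux-to-glucose couplings (Model 1 is the true model)
duration_days: 14
cgm_step_min: 15
aux_step_min: 15
glucose:
  target_half_life: 1.5
  damping: -0.5
  amplitude: 0.8
couplings: [0.0, 0.0, 0.0]
bout_rate_per_day: 0.3
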