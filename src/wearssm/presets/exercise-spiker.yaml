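description: frequent exercise bouts with aux-to-glucose couplings
duration_days: 14
cgm_step_min: 15
aux_step_min: 15
glucose:
  target_half_life: 1.5
  damping: -0.3
  amplitude: 0.5
couplings: [-0.3, 0.4, 0.0]
bout_rate_per_day: 1.5
bout_amp: 6.0
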