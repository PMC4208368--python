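# Default pipeline configuration (all values equal the built-in defaults;
# override any subset and pass via --config).
#
# Cohort design: 38 retrospective fallers + 42 non-fallers, of whom 6 are
# prospective first-time fallers; trial counts and rates follow the
# laboratory protocol the generator emulates.
cohort:
  n_fallers: 38
  n_nonfallers: 42
  n_ftf: 6
  gait_hz: 100.0        # marker sampling rate
  cop_hz: 120.0         # force-plate / CoP sampling rate
  torque_hz: 100.0
  n_walks: 6            # >= 6 walks over the 10 m walkway
  sway_reps: 3          # per eyes condition
  torque_reps: 3        # per joint x target level
  mvic_reps: 3          # best-of-three maximal contractions
  walkway_m: 10.0
  sway_duration_s: 30.0
  torque_duration_s: 15.0
  mvic_duration_s: 10.0
  # standardized faller-minus-nonfaller latent differences
  effect_sizes:
    static_balance: 0.0
    temporal_gait: 0.0
    spatial_gait: -0.85
    temporal_variability_right: 0.45
    temporal_variability_left: 0.60
    spatial_variability: 0.0
    dynamic_balance: 0.0

extraction:
  torque_trim: [7.0, 2.0]    # seconds removed from head / tail
  torque_filter: [4, 25.0]   # Butterworth order, cutoff Hz (zero phase)
  cop_trim: [2.0, 2.0]
  cop_filter: [2, 5.0]
  gait_filter: [4, 25.0]
  min_strides_per_foot: 5

msa_threshold: 0.5           # sampling-adequacy cutoff
loading_threshold: 0.4       # complex-structure loading cutoff
kaiser: 1.0                  # retain components with eigenvalue > 1
selection_alpha: 0.1         # predictor retention p-value
classification_threshold: 0.5
model_choice: reduced        # which model classifies: full | reduced
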