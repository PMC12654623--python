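# Frozen default experiment profile: the study-protocol configuration.
# Every key mirrors a PipelineConfig / SimulationConfig field; values here
# equal the library defaults, so `hybridbci run-all` without --config is
# equivalent.
sim:
  n_subjects: 15
  reps_per_class: 10
  fs: 256.0
  trial_seconds: 16.0
  warning_seconds: 3.0
  ssvep_freq: 7.0          # Hz, LED flicker
  ssvep_amp: 8.0           # uV, fundamental at the frontal sites
  harmonic_amp: 1.5        # uV, 14 Hz harmonic
  eog_amp: 40.0            # uV, peak trajectory deflection
  pink_noise_sd: 10.0      # uV, 1/f background
  white_noise_sd: 2.0      # uV, sensor noise
  motion_period: 2.0       # s per trajectory sweep (5 sweeps in 10 s)
  blink_rate: 0.15         # blinks per second, all classes
  session_shift:
    mixing_eps: 0.2        # cap-repositioning channel leakage
    gain_drift: [0.8, 1.25]  # per-channel impedance drift
    noise_sd_ratio: 1.2    # evening restlessness
    baseline_offset_sd: 1.0  # uV
  seed: 0
stage1_filter: {order: 5, band: [1.0, 15.0]}
stage2_filter: {order: 4, band: [0.5, 32.0]}
warning_seconds: 3.0
window_seconds: 3.0
stride_samples: 448        # five 768-sample windows over 2560 samples
welch_window_len: 640
welch_overlap: 639
poly_degree: 20
classifier: bagging        # 100 trees, depth 15
coral: true
coral_lam: 0.1
standardize_per_session: true
anova: false
anova_alpha: 0.05
selection_seconds: 2.5     # Wolpaw ITR selection time
n_repetitions: 10
gate_bypass: false
train_on_correct_gate: true
seed: 0
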