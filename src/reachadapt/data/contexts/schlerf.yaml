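# Slicing-movement calibration context: 13 targets from 60 to 90 deg in
# 2.5-deg steps, one chosen at random per trial; action pool 58-92 deg.
# A visuomotor rotation is introduced and removed in 5-deg steps of 16 trials
# each (multi-step phase), then abruptly in alternating 50-trial blocks
# (single-step phase).  Control parameters: learning rate 1, degradation
# 0.04, endpoint noise SD 1.05 cm.  The ataxia variant raises the
# degradation rate to 0.16 and the noise SD to 1.3 cm.  The critic variant
# replaces the fixed learning rate with critic control (thresholds 2 / 3.5,
# speeds 1.3, optimality fraction 0.2, variability estimate = noise SD).
name: schlerf
cues:
  S1: 60.0
  S2: 62.5
  S3: 65.0
  S4: 67.5
  S5: 70.0
  S6: 72.5
  S7: 75.0
  S8: 77.5
  S9: 80.0
  S10: 82.5
  S11: 85.0
  S12: 87.5
  S13: 90.0
habit:
  S1: 0.3
  S2: 0.3
  S3: 0.3
  S4: 0.3
  S5: 0.3
  S6: 0.3
  S7: 0.3
  S8: 0.3
  S9: 0.3
  S10: 0.3
  S11: 0.3
  S12: 0.3
  S13: 0.3
pool: {lo: 58.0, hi: 92.0, n: 100}
target_radius: 0.20
noise_sd: 0.0105
reward: {kind: spot, magnitude: 3.0, radius: 0.04}
initial_expectation: 3.0
cb: {lam: 1.0, gamma: 0.04}
critic: null
model: cb
phases:
  - {label: baseline, n_trials: 200, cue: &allcues [S1, S2, S3, S4, S5, S6, S7, S8, S9, S10, S11, S12, S13]}
  - {label: step_up_5, n_trials: 16, cue: *allcues, perturbation: rotation, angle: 5.0}
  - {label: step_up_10, n_trials: 16, cue: *allcues, perturbation: rotation, angle: 10.0}
  - {label: step_up_15, n_trials: 16, cue: *allcues, perturbation: rotation, angle: 15.0}
  - {label: step_up_20, n_trials: 16, cue: *allcues, perturbation: rotation, angle: 20.0}
  - {label: step_top_20, n_trials: 16, cue: *allcues, perturbation: rotation, angle: 20.0}
  - {label: step_down_15, n_trials: 16, cue: *allcues, perturbation: rotation, angle: 15.0}
  - {label: step_down_10, n_trials: 16, cue: *allcues, perturbation: rotation, angle: 10.0}
  - {label: step_down_5, n_trials: 16, cue: *allcues, perturbation: rotation, angle: 5.0}
  - {label: washout, n_trials: 72, cue: *allcues}
  - {label: pre_single, n_trials: 50, cue: *allcues}
  - {label: single_rot_1, n_trials: 50, cue: *allcues, perturbation: rotation, angle: 20.0}
  - {label: between_single, n_trials: 50, cue: *allcues}
  - {label: single_rot_2, n_trials: 50, cue: *allcues, perturbation: rotation, angle: 20.0}
  - {label: post_single, n_trials: 50, cue: *allcues}
variants:
  control: {}
  ataxia:
    noise_sd: 0.013
    cb: {gamma: 0.16}
  critic:
    model: cb+critic
    critic: {t_low: 2.0, t_high: 3.5, kappa: 0.0105, speed_up: 1.3, slow_down: 1.3, a_opt: 0.2, alpha: 0.0}
  critic_ataxia:
    model: cb+critic
    noise_sd: 0.013
    cb: {gamma: 0.16}
    critic: {t_low: 2.0, t_high: 3.5, kappa: 0.013, speed_up: 1.3, slow_down: 1.3, a_opt: 0.2, alpha: 0.0}
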