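# Memory-retention protocol: a single cue/target at 90 deg (habit 0.1),
# action pool 40-110 deg.  Six phases: 20 baseline trials; 60 trials under a
# 30-deg rotation; an 80-trial "asymptote" block (in the BE variant visual
# feedback is withheld and the critic output is forced to zero, leaving only
# the binary reward); 30 trials under a 45-deg rotation; an error-clamp
# block (60 trials, or 100 in the clamp100 variant) in which the display
# always shows a perfect hit and reward is always given; 40 washout trials.
# Explicit reward R = 2*Theta(0.028 - |e|) + 0.65 lambda; endpoint noise SD
# 8 mm; critic thresholds 2 / 3.5, speeds 1.3, optimality fraction 0.2,
# variability estimate 8 mm.
name: shmuelof
cues: {C1: 90.0}
habit: {C1: 0.1}
pool: {lo: 40.0, hi: 110.0, n: 100}
target_radius: 0.20
noise_sd: 0.008
reward: {kind: shmuelof, radius: 0.028}
initial_expectation: 0.0
cb: {lam: 1.0, gamma: 0.04}
critic: {t_low: 2.0, t_high: 3.5, kappa: 0.008, speed_up: 1.3, slow_down: 1.3, a_opt: 0.2, alpha: 0.0}
bg: {eta_bg: 0.006, eta_exp: 0.02}
model: cb+bg+critic
phases:
  - {label: baseline, n_trials: 20, cue: C1}
  - {label: adapt, n_trials: 60, cue: C1, perturbation: rotation, angle: 30.0}
  - {label: asymptote, n_trials: 80, cue: C1, perturbation: rotation, angle: 30.0}
  - {label: rot45, n_trials: 30, cue: C1, perturbation: rotation, angle: 45.0}
  - {label: clamp, n_trials: 60, cue: C1, perturbation: error_clamp}
  - {label: washout, n_trials: 40, cue: C1}
variants:
  beve: {}
  be:
    phases:
      asymptote: {visual_feedback: false, critic_zero: true}
  clamp100:
    phases:
      clamp: {n_trials: 100}
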