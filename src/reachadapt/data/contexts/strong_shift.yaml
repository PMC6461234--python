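# Three-phase test context: 90-degree visual shift for 100 trials.  Target
# perceived at 135 deg (cue C2') while the hand must reach the 45-deg target;
# the vector error is untransformed.
name: strong_shift
cues: {C1: 45.0, C2p: 135.0}
habit: {C1: 0.3, C2p: 0.3}
pool: {lo: 20.0, hi: 155.0, n: 100}
target_radius: 0.20
noise_sd: 0.005
reward: {kind: spot, magnitude: 3.0, radius: 0.04}
initial_expectation: 3.0
cb: {lam: 2.0, gamma: 0.04}
critic: {t_low: 1.0, t_high: 4.5, kappa: 0.005, speed_up: 1.3, slow_down: 2.8, a_opt: 0.6, alpha: 2.8}
bg: {eta_bg: 0.08}
model: cb+bg+critic
phases:
  - {label: baseline, n_trials: 50, cue: C1}
  - {label: adapt, n_trials: 100, cue: C2p, perturbation: shift, true_cue: C1}
  - {label: post, n_trials: 50, cue: C1}
variants: {}
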