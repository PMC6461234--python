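# Three-phase test context: 30-degree CCW visuomotor rotation for 50 trials.
# Cues C1 (45 deg) and C2 (75 deg = apparent target under the rotation);
# habitual associations of strength 0.3; action pool 20-155 deg; reward 3
# inside a 4-cm spot; initial reward expectation 3; endpoint noise SD 5 mm.
name: mild_rotation
cues: {C1: 45.0, C2: 75.0}
habit: {C1: 0.3, C2: 0.3}
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
  - {label: adapt, n_trials: 50, cue: C2, perturbation: rotation, angle: 30.0}
  - {label: post, n_trials: 50, cue: C1}
variants: {}
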