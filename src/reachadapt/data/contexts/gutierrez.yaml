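# Prism-throwing analogue with reaching movements: cues C1 (70 deg) and C2
# (110 deg) with strong pre-set habitual associations (0.55); 25 baseline
# trials on C1, 25 perturbed trials on C2 with reward still paid for reaching
# the 70-deg target, 25 washout trials on C1.  The default perturbation is
# the dove-prism x-reflection (non-error-based learning); the `shift` variant
# is the wedge prism (error-based learning).  Graded reward
# R = -22 |e|^1.5 + 0.7 lambda; initial reward expectation 0; the critic
# skips the trial right after each change of conditions (participants were
# aware of the perturbation).  PD: reinforcement learning rates scaled by
# 0.1; HD: indirect-pathway (D2) output scaled by 0.1.
name: gutierrez
cues: {C1: 70.0, C2: 110.0}
habit: {C1: 0.55, C2: 0.55}
pool: {lo: 10.0, hi: 170.0, n: 100}
target_radius: 0.20
noise_sd: 0.005
reward: {kind: gutierrez, radius: 0.04}
initial_expectation: 0.0
cb: {lam: 1.0, gamma: 0.04}
critic: {t_low: 1.9, t_high: 2.1, kappa: 0.005, speed_up: 2.0, slow_down: 2.8, a_opt: 0.8, alpha: 0.0}
bg: {eta_bg: 0.08, eta_exp: 0.02}
awareness_reset: true
model: cb+bg+critic
phases:
  - {label: baseline, n_trials: 25, cue: C1}
  - {label: adapt, n_trials: 25, cue: C2, perturbation: reflect_x}
  - {label: post, n_trials: 25, cue: C1}
variants:
  control: {}
  reflect: {}
  shift:
    phases:
      adapt: {perturbation: shift, true_cue: C1}
  pd:
    lesion: {pd_scale: 0.1}
  hd:
    lesion: {hd_scale: 0.1}
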