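# Model and methods

`reachadapt` simulates trial-by-trial adaptation of planar reaching
movements under visuomotor perturbations, with two interacting learners —
an error-based (cerebellar) one and a reinforcement-based (basal-ganglia)
one — supervised by a critic that decides, from the reliability of error
feedback, which learner is allowed to act. This note documents the model
equations, the assumptions behind the reduced components, every tunable
parameter that matters, and the known limitations.

## Task geometry

Each trial is one reach from a fixed start to a target on a circle of
radius 0.20 m around the start. Coordinates: origin at the start, x to the
subject's right, y away from the body; directions in degrees CCW from +x
(90° is straight ahead). The subject sees only a cursor; the mapping from
hand to cursor can be perturbed (rotation about the start, x-reflection,
translation/shift, error clamp, or no feedback at all). The *perceived
vector error* `e` is the cursor displacement from the displayed target, in
metres; the *angular error* reported in summaries is the angle between the
perceived endpoint direction and the displayed target direction. Reward is
computed on the perceived (cursor-frame) error, since the apparatus scores
cursor–target proximity — except on error-clamp trials, which always pay
out.

## Arm surrogate

Only movement endpoints matter to trial-to-trial learning (subjects were
prevented from online correction), so the movement system is reduced to a
smooth deterministic forward map `F(p, W)` from a 6-component motor program
to a 2-D endpoint:

- the motor program `p ≥ 0` holds the drive amplitudes of six muscles (two
  mono-articular antagonist pairs — shoulder and elbow — plus one
  bi-articular pair) modulating one shared bell-shaped velocity template;
- the cerebellar correction acts multiplicatively, `p_cor = (I + W) p`,
  rectified at zero component-wise (drives cannot be negative; rectified
  trials are flagged);
- antagonist drives are differenced into two channels (bi-articular drives
  feed both, weights 0.3 and 0.2), a fixed 2×2 gain matrix `K` maps the
  channels to joint excursions from the rest posture of a two-link arm
  (links 0.5 m, shoulder 0.55 m behind the start), and trigonometric
  forward kinematics give the hand position.

`K = inv(∂F/∂θ at the 90° reference posture) · diag(g/a, g)` with endpoint
gain `g = 0.011` m per channel unit and anisotropy `a = 0.5`: the lateral
(x) screen axis is the mobile, high-gain axis, the depth axis the stiff
one. Real two-link arms do have anisotropic endpoint mobility; here the
ratio is a calibrated model constant. The inverse solver allocates each
channel excursion symmetrically about a co-contraction baseline of 6.0
(antagonist floored at one tenth of the baseline for extreme lateral
targets), which makes every solved program strictly positive, keeps the
program norm nearly direction-independent, and leaves equal headroom for
corrections in both directions. Round-trip accuracy of the solver is ~1e-16
(machine precision); the contract is < 1e-4 m.

The endpoint sensitivity `∂F/∂W` is the analytic outer-product tensor
`(∂F/∂drive)_ki · p_j` (zeroed where rectification clamps a drive); unit
tests verify it against central finite differences.

**Why these numbers.** The per-trial error map of the cerebellar update is
`e → (1−γ) e − λ M e` with `M = Σ_ij (∂F/∂W)_ij (∂F/∂W)_ijᵀ`. The gain and
anisotropy were calibrated *once*, jointly, so that (i) the inverse problem
is well conditioned over the 10–170° workspace, and (ii) with the fixed
strong-perturbation learning rate λ = 2 the simulated rotation scan
converges up to 80° and oscillates without decay at 85° — the behaviour of
the full neuromechanical model this surrogate stands in for. Near the
stability boundary convergence is necessarily slow (the spectral radius of
`I − λ R(θ) M` approaches 1), and an isotropic `M` cannot both converge at
80° within a 150-trial phase and diverge at 85°; the ~3:1 anisotropy opens
that window. At the 45° target, `λM` has eigenvalues ≈ (0.19, 0.62) at
λ = 2.

## Cerebellum

A single linear layer with weights `W` (6×6). After a trial with perceived
error `e`, executed program `p` and learning rate `λ`:

    W ← W − λ (∂F/∂W) e − γ W

γ (default 0.04 per trial) is the degradation ("forgetting") rate; the
balance of the two terms produces the non-zero asymptotic error, which
grows with γ and shrinks with λ (verified against the closed-form scalar
fixed point `e* = γ x₀ / (λ c² + γ)`). On declared no-visual-feedback
trials the state is frozen entirely (no learning, no decay); on error-clamp
trials the update runs with `e = 0`, so only degradation acts — this is
what washes the accumulated correction out during a clamp block.

After each update the learner predicts the next perceived error under a
*veridical-mapping* assumption:

    e_exp = e + [F(p, W_new) − F(p, W_old)]

i.e. the current perceived error plus the internally simulated endpoint
change. Predicting the *change* of the error (rather than re-deriving the
error from the true target) is essential: a pure shift leaves the error
vector untouched and must be scored as consistent no matter how large the
displacement, whereas rotations and reflections bend the realized change
away from the predicted one and are caught.

## Critic

On the next trial the critic compares prediction and observation,
`mismatch = ‖e_real − e_exp‖`, against thresholds proportional to the
subject's movement-variability estimate κ (set to the endpoint noise SD):

    mismatch <  t_low·κ   → λ ← speed_up · λ
    in between            → λ unchanged
    mismatch ≥  t_high·κ  → λ ← λ / slow_down

clipped to `[0.001, a_opt · λ_opt]`, where `λ_opt = (eᵀMe)/‖Me‖²` is the
rate that would cancel the current error in one linearized step (recomputed
every trial; the previous value is reused if `Me` vanishes, and λ is left
untouched when the current error is under 1 mm — a hit carries no
information). The same signal gates reinforcement: `DA = RPE + α·critic`,
so that while cerebellar corrections work, losing the reward does not
negatively reinforce the selected action; when they fail, λ (and the
offset) collapses and the basal ganglia are free to explore.

Per-context critic constants (κ always equals the context's noise SD):

| context | t_low | t_high | speed_up | slow_down | a_opt | α |
|---|---|---|---|---|---|---|
| 3-phase test contexts | 1.0 | 4.5 | 1.3 | 2.8 | 0.6 | 2.8 |
| slicing/calibration (critic variant) | 2.0 | 3.5 | 1.3 | 1.3 | 0.2 | 0 |
| prism throwing (graded reward) | 1.9 | 2.1 | 2.0 | 2.8 | 0.8 | 0 |
| retention protocol | 2.0 | 3.5 | 1.3 | 1.3 | 0.2 | 0 |

The last three rows are published protocol constants. The test-context row
is a package calibration (no published values exist): thresholds and α were
chosen so that mild perturbations remain cerebellum-dominated (no
exploration, aftereffect present) while strong rotations and reflections
collapse λ quickly enough that the reinforcement system takes over cleanly.
In the graded-reward and retention contexts the critic's reward offset is
folded into the printed reward formulas (`+0.7λ`, `+0.65λ`) and α = 0, to
avoid double counting.

## Basal ganglia

Each of the `n = 100` candidate actions (reaches uniformly spanning the
context's angular sector) owns a loop: cue-driven D1 neurons inhibit GPi;
D2 neurons inhibit GPe, releasing STN, which excites GPi; GPi inhibits the
loop's thalamocortical relay neuron. Rectified-linear rate units with unit
gains (GPe = [1 − d2]₊, STN = [1 − 0.8·GPe]₊, GPi = [1 − d1 + STN]₊, relay
drive = [1.5 − GPi + habit]₊). The habit shortcut (direct cortico-thalamic
weight) enters *inside* the relay rectification together with the GPi
input, so a hyperactive indirect pathway can override even a strong
(0.55) habitual association — punishments saturate otherwise and
exploration could never start. The relay layer competes through all-to-all
lateral inhibition (0.6) with weak self-excitation (0.5). With these gains
the point attractor reached from rest is winner-take-all: the maximally
driven loops (ties share symmetrically) settle at the fixed-point rate and
all others are fully suppressed. The default selection path evaluates that
attractor in closed form; an explicit ODE integrator (`method="ode"`,
adaptive step bounded by the stiff global-inhibition mode, residual < 1e-8)
is retained and tested to agree — it is ~600× slower but makes the
dynamical claim checkable. Mixture coefficients are the normalised relay
rates; the executed program is the mixture-weighted blend of the pool
programs.

Plasticity, per trial with dopamine `DA` and mixture `m`:

    Δw_d1 = +η_bg · pd_scale · DA · m      (clipped to [0, 2])
    Δw_d2 = −η_bg · pd_scale · DA · m      (clipped to [0, 2])

plus a slow uniform decay (1e-4/trial) of all cortico-striatal weights, and
Hebbian habit formation `Δw_habit = η_hab · m · relay` with η_hab = 1e-4 —
deliberately so slow it is negligible at these trial counts (habits are
pre-set per context: 0.3 in the test contexts, 0.55 in the prism context,
0.1 in the retention protocol). The reward expectation per cue tracks the
received reward at rate η_exp, and `RPE = R − expectation`. A literal
"difference of consecutive rewards" (η_exp = 1) makes a sustained miss
streak carry zero prediction error after one trial, which freezes
exploration; the default η_exp = 0.05 (0.02 in the graded-reward and
retention contexts) keeps misses negatively surprising over the ~10-trial
window in which exploration demonstrably unfolds.

Exploration itself is deterministic: tiny random initial PFC→D1 weights
(uniform on [0, 0.02], drawn once per run from a dedicated generator)
rank the otherwise identical actions; punishment of the current winner
hands selection to the next-ranked candidate, one per trial, until a
rewarded action locks in through positive reinforcement. Endpoint noise
enters only through the rewards. Lesions: Parkinsonian degeneration scales
η_bg by `pd_scale` (default 0.1 in the PD variant — dopamine loss slows
reinforcement); Huntington degeneration scales the D2 population output by
`hd_scale` (0.1 — punishment can no longer suppress the selected action).

η_bg is a free constant calibrated per context against the qualitative
timelines the protocols require: 0.08 in the test and prism contexts
(exploration within ~10 punished trials against a 0.3–0.55 habit), 0.006
in the retention protocol (the ~5 punished trials at each rotation onset
must *not* dislodge selection, while the 80-trial no-feedback block must
reliably complete the walk).

## Trial loop

Eight stages per trial: (1) BG select; (2) cerebellar correction;
(3) forward map; (4) Gaussian endpoint noise (SD 0.005 m in the test
contexts; per-context otherwise) then the perceptual transform;
(5) critic evaluation; (6) `DA = RPE + α·critic`; (7) BG and habit
updates; (8) cerebellar update. Model variants `cb`, `bg`, `cb+bg`,
`cb+critic`, `cb+bg+critic` omit the stages of absent components; variants
without BG execute the exact solved program for the cue target. In
contexts flagged "aware of the perturbation", the first trial of each
phase resets the error history: neither the critic nor the error-based
update acts on it (the stale prediction is retained so the *next* trial's
mismatch reflects the new conditions). In the retention protocol's
no-feedback block the critic output is forced to zero: the weight update
runs with λ = 0 (degradation only), the internal λ survives the block, and
no prediction is formed across it.

Randomness: one `numpy` generator per run seeded from `(base_seed+run, 0)`,
consumed in a fixed order — the cue draw (random-cue contexts only), then
the 2-D endpoint noise; a second generator `(base_seed+run, 1)` provides
the initial striatal weights. Batches are bit-reproducible.

## Contexts and problem sizes

The shipped YAML contexts carry the published constants: the five 3-phase
test contexts (50/50-or-100/50 trials; cues at 45/75/135°; spot reward 3
inside 4 cm; initial expectation 3; λ = 2, γ = 0.04); the 650-trial
multi-step/single-step slicing context (13 cues 60–90°, noise 1.05 cm,
λ = 1; ataxia variant γ = 0.16, noise 1.3 cm; single-step blocks of 50
trials filling trials 401–650, a layout choice where only the figure axis
is published); the 75-trial prism context (cues 70/110°, habits 0.55,
reward `−22‖e‖^1.5 + 0.7λ`, initial expectation 0, awareness reset on);
and the 290-trial retention protocol (single 90° cue, habit 0.1, reward
`2·Θ(0.028−‖e‖) + 0.65λ`, noise 8 mm, phases 20/60/80/30/60-or-100/40 with
30° then 45° rotations). Batch sizes follow the published figures: 32 runs
for the test contexts, 16 for the others. A full acceptance pass (32-run
rotation batch, a seven-angle 150-trial scan, and a 16-run retention
batch) takes a few seconds on one CPU.

The rotation scan classifies each angle from a fresh correction matrix
(γ = 0, λ = 2, 150 trials, true target at 45°): *converged* if the true
endpoint stays within 0.02 m of the target for 10 consecutive trials;
otherwise *spiraling* if the trailing-third mean distance is still
decreasing (≥ 5%) relative to the middle third; otherwise
*non-convergent*. The window and thresholds are package choices (the
phenomenon, not the classifier, is published) and are all arguments of
`rotation_scan`.

"Asymptotic error" is operationalised as the mean |angular error| over the
final 10 adaptation trials; "aftereffect" as the mean signed angular error
over the first 5 post-perturbation trials.

## What the simulations do and do not show

The generator *is* the study design: all inputs are simulated under the
stated protocols, so passing tests demonstrate internal consistency of the
mechanism — that the critic-gated interplay of the two learners reproduces
the published phenomenology — not agreement with new behavioural data.
Specific known limitations:

- The arm surrogate preserves the 6-input/2-output geometry, smoothness
  and invertibility of the full neuromechanical arm but none of its
  dynamics; quantities that depend on its conditioning (exact trial counts
  to criterion, the precise convergence boundary) are calibrated, not
  emergent.
- The reflection-adapted state is metastable by construction: once a
  rewarded action locks in, errors of a few millimetres keep re-engaging
  the cerebellum with mirrored feedback, the correction drifts, and the
  run occasionally re-explores. Controls end the reflection phase well
  adapted on average (and lesioned variants do not), but single runs
  wobble more than the published averages.
- A few degrees of residual aftereffect survive the reflection phases
  (from corrections accumulated while λ collapses); the published account
  reports essentially none.
- Selection is effectively hard winner-take-all at the fixed point; graded
  mixtures occur only at exact ties. The published description allows
  graded blends, but with competition strong enough that pre-set habits
  dominate, the attractor is single-winner anyway.
- Explicit/cognitive strategies, within-movement corrections and
  habit-formation timescales beyond these trial counts are out of scope.
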