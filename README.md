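# reachadapt

Trial-by-trial simulation of human motor adaptation to visuomotor
perturbations, for computational and behavioural neuroscientists studying
how error-based and reward-based learning share control of movement.

When the visual feedback of a reaching movement is distorted — rotated,
mirrored, or shifted — people still adapt, but apparently with different
machinery depending on the distortion. The cerebellum corrects movements
from the *vector error* (supervised, error-based learning); the basal
ganglia reinforce or suppress whole actions from *reward* (non-error-based
learning). If the error vector is mirrored, error-based corrections make
performance worse every trial, yet healthy subjects adapt anyway — while
patients with Parkinson's or Huntington's disease do not. `reachadapt`
implements a mechanistic account of this switch: a **critic** that compares
the cerebellum's predicted error against the observed one and, depending on
their consistency, gates both learners at once.

## The model

One trial is a planar reach parameterised by a 6-component motor program
`p` (muscle-drive amplitudes). A smooth invertible arm surrogate maps it to
an endpoint, `F(p, W)`, after the cerebellar correction `p_cor = (I + W) p`.
Three coupled processes update state between trials:

- **Cerebellum** — one gradient step on the squared perceived error with
  weight decay:
  `W ← W − λ (∂F/∂W) e − γ W`.
  The decay γ makes adaptation settle at a non-zero asymptotic error where
  learning balances forgetting.
- **Basal ganglia** — per-action loops (D1/D2 striatal pathways → GPe/STN →
  GPi → thalamus) with winner-take-all thalamic competition select a blend
  of candidate reaches; dopamine `DA` potentiates PFC→D1 and depresses
  PFC→D2 weights of the selected actions (`RPE = R − expectation`;
  PD lesion = scaled learning rate, HD lesion = scaled D2 output).
- **Critic** — with `mismatch = ‖e_real − e_exp‖` and thresholds
  proportional to the movement-variability estimate κ:
  speed λ up when the prediction holds, slow it down when it fails, clip to
  `[0.001, a_opt·λ_opt]`; and offset dopamine, `DA = RPE + α·critic`, so
  that losing reward during a well-corrected perturbation does not trigger
  exploration.

Four published experimental protocols ship as declarative YAML contexts:
three-phase shift/rotation/reflection tests, a multi-step/single-step
rotation calibration task (with a cerebellar-ataxia variant), a prism-
throwing analogue with PD/HD lesions, and a six-phase reinforcement-
dependent memory-retention protocol with an error clamp.

## Worked example

```
$ reachadapt simulate --context mild_rotation --runs 32 --seed 1 --model cb
mild_rotation: 32 runs x 150 trials
  asymptotic |error| (last 10 adaptation trials): 1.95 deg
  aftereffect (first 5 post trials): -9.05 deg
```

A 30° visuomotor rotation is introduced after 50 baseline trials. The first
perturbed trial misses by the full 30°; cerebellar learning then drives the
run-averaged error down to a ~2° asymptote (non-zero because weight decay
balances learning). When the rotation is removed, the accumulated internal
correction overshoots the other way — the −9° aftereffect — and washes out.
Per-trial records, a summary table and a reproducibility manifest are
written as CSV/JSON.

The same cerebellum-only model fails for strong rotations:

```
$ reachadapt scan-rotation --seed 2
  60.0 deg: converged       (final distance 0.0069 m)
  ...
  80.0 deg: converged       (final distance 0.0169 m)
  85.0 deg: non-convergent  (final distance 0.2569 m)
largest converging angle: 80.0 deg
```

Beyond ~80° the rotated error bends each correction so far off course that
the endpoint spirals around the target with non-decaying amplitude — the
regime in which the critic shuts error-based learning off and the basal
ganglia adapt by exploration instead (`--model cb+bg+critic`, the default).

Python API: `build_context(name, variant)` → `run_batch(spec, n_runs,
base_seed)` returns a `RunSummary` and a tidy per-trial `DataFrame`;
`rotation_scan(angles)` classifies convergence per angle. See
`docs/methods.md` for the full model description and parameter tables.

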