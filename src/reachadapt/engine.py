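"""Trial loop: wires arm, cerebellum, basal ganglia and critic together.

Each trial runs the same eight stages: (1) the basal ganglia select a blend
of the pool actions for the presented cue; (2) the cerebellum transforms the
blended program with its correction matrix; (3) the arm maps the corrected
program to an endpoint; (4) Gaussian endpoint noise is added and the visual
perturbation applied, yielding the perceived error; (5) the critic scores
the cerebellum's standing prediction against the perceived error and sets
the learning rate; (6) the dopamine signal is formed from the reward
prediction error and the critic output; (7) the basal ganglia update their
cortico-striatal and habit weights; (8) the cerebellum updates its
correction matrix and predicts the next error.  Model variants ("cb", "bg",
"cb+bg", "cb+critic", "cb+bg+critic") omit the stages of absent components,
mirroring the incremental construction of the full model.

Randomness: each run owns one generator seeded from (base_seed, run, 0) that
is consumed, in order, by the per-trial cue draw (only in random-cue
contexts) and the 2-D endpoint noise; a second generator seeded from
(base_seed, run, 1) provides the tiny random initial cortico-striatal
weights, so traces of model variants without basal ganglia are directly
comparable with those of variants with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arm import default_arm
from .basal_ganglia import (
    ActionPool,
    BGParams,
    BGState,
    bg_learn,
    bg_select,
    compute_rpe,
    habit_update,
    init_bg_state,
)
from .cerebellum import CorrectionState, cb_update, skip_update
from .critic import critic_eval, dopamine, lambda_optimal
from .protocols import Perturbation, ProtocolSpec, hand_target, perceive

__all__ = ["Simulator", "RunSummary", "run_trial", "run_batch", "rotation_scan"]


def _wrap(deg):
    return (deg + 180.0) % 360.0 - 180.0


def _angle(xy) -> float:
    return float(np.rad2deg(np.arctan2(xy[1], xy[0])))


@dataclass
class RunSummary:
    """Across-run summary of a batch: per-trial means and headline numbers."""

    n_runs: int
    phase: np.ndarray  # phase label per trial
    mean_error: np.ndarray  # per-trial mean signed angular error (deg)
    sem_error: np.ndarray  # sd / sqrt(n_runs); zero for a single run
    mean_abs_error: np.ndarray
    mean_lam: np.ndarray
    asymptotic_error: float  # mean |angular error|, last 10 adaptation trials
    aftereffect: float  # mean signed angular error, first 5 post trials

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self.mean_error) + 1),
                "phase": self.phase,
                "mean_angular_error_deg": self.mean_error,
                "sem_deg": self.sem_error,
                "mean_abs_error_deg": self.mean_abs_error,
                "mean_lambda": self.mean_lam,
            }
        )


class Simulator:
    """Mutable per-run simulation state for one protocol."""

    def __init__(self, spec: ProtocolSpec, seed: int, model: str | None = None, arm=None):
        self.spec = spec
        self.model = model or spec.model
        parts = set(self.model.split("+"))
        self.cb_on = "cb" in parts
        self.bg_on = "bg" in parts
        self.critic_on = "critic" in parts and spec.critic is not None
        self.arm = arm if arm is not None else default_arm()
        self.pool = ActionPool.build(
            self.arm, spec.pool["lo"], spec.pool["hi"], spec.pool["n"], spec.target_radius
        )
        self.rng = np.random.default_rng([seed, 0])
        rng_init = np.random.default_rng([seed, 1])
        self.bg_params = BGParams(**spec.bg_overrides) if spec.bg_overrides else BGParams()
        self.bg = init_bg_state(
            spec.cues, self.pool, spec.habit, spec.initial_expectation, self.bg_params, rng_init
        )
        self.cb = CorrectionState(
            W=np.zeros((6, 6)), lam=spec.cb["lam"], gamma=spec.cb["gamma"]
        )
        self.lambda_opt = None
        self._cue_programs: dict = {}
        self.trial_idx = 0
        self._phase_starts = np.cumsum([0] + [ph.n_trials for ph in spec.phases])

    def phase_of(self, trial_idx: int):
        i = int(np.searchsorted(self._phase_starts, trial_idx, side="right")) - 1
        return i, self.spec.phases[i]

    # ------------------------------------------------------------------ trial
    def step(self) -> dict:
        spec = self.spec
        phase_idx, phase = self.phase_of(self.trial_idx)
        first_of_phase = self.trial_idx == self._phase_starts[phase_idx]
        cue = phase.cue_for_trial(self.rng)
        pt_xy = spec.target_xy(cue)
        true_xy = spec.target_xy(phase.true_cue) if phase.true_cue else None
        pert = phase.perturbation

        # 1-2: action selection and cerebellar correction
        if self.bg_on:
            mixture = bg_select(cue, self.bg, self.bg_params, spec.lesion)
            p = self.pool.blend(mixture)
        else:
            # without basal ganglia the cortical controller solves the
            # inverse problem for the perceived target exactly
            mixture = None
            if cue not in self._cue_programs:
                from .arm import TargetSpec

                self._cue_programs[cue] = self.arm.solve_inverse(
                    TargetSpec(spec.cues[cue], spec.target_radius)
                )
            p = self._cue_programs[cue]
        W = self.cb.W if self.cb_on else None

        # 3-4: movement, noise, perception
        endpoint, rectified = self.arm.forward_flagged(p, W)
        noisy = endpoint + self.rng.normal(0.0, spec.noise_sd, 2)
        pe, e_perceived, available = perceive(noisy, pt_xy, pert, true_xy)

        jac = self.arm.jacobian(p, W) if self.cb_on else None
        lam_before = self.cb.lam

        # 5: critic evaluation
        branch = "off"
        mismatch = np.nan
        new_lam = lam_before
        if self.critic_on:
            if phase.critic_zero:
                branch, critic_out = "forced-zero", 0.0
            elif not available:
                branch, critic_out = "no-feedback", lam_before
            elif spec.awareness_reset and first_of_phase and phase_idx > 0:
                branch, critic_out = "reset", lam_before
            elif self.cb.e_exp is None or not self.cb_on:
                branch, critic_out = "init", lam_before
            else:
                self.lambda_opt = lambda_optimal(e_perceived, jac, fallback=self.lambda_opt)
                mismatch = float(np.linalg.norm(e_perceived - self.cb.e_exp))
                new_lam, branch = critic_eval(
                    e_perceived, self.cb.e_exp, lam_before, spec.critic, self.lambda_opt
                )
                critic_out = new_lam
        else:
            critic_out = lam_before

        # 6: reward and reinforcement signal
        e_for_reward = 0.0 if pert.kind == "error_clamp" else float(np.linalg.norm(e_perceived))
        reward = spec.reward_rule.reward(e_for_reward, critic_out)
        rpe = np.nan
        da = np.nan
        if self.bg_on:
            rpe = compute_rpe(reward, cue, self.bg, self.bg_params)
            alpha = spec.critic.alpha if self.critic_on else 0.0
            da = dopamine(rpe, critic_out if self.critic_on else 0.0, alpha)
            # 7: reinforcement and habit formation
            bg_learn(da, cue, mixture, self.bg, self.bg_params, spec.lesion)
            habit_update(cue, mixture, self.bg, self.bg_params)

        # 8: cerebellar update
        if self.cb_on:
            if branch == "reset":
                # the subject knows conditions just changed: the error history
                # is reset, so neither the critic nor the error-based update
                # acts on this trial (the stale prediction is kept so the
                # next trial's mismatch reflects the new conditions)
                self.cb = skip_update(self.cb)
            elif phase.critic_zero:
                # no visual error; learning silenced but degradation continues,
                # and the stored learning rate survives the block
                updated = cb_update(self.cb, p, np.zeros(2), jac, self.arm, lam=0.0)
                self.cb = replace(updated, lam=lam_before, e_exp=None)
            elif not available:
                self.cb = skip_update(self.cb)
            else:
                lam_for_update = new_lam if self.critic_on else lam_before
                self.cb = cb_update(self.cb, p, e_perceived, jac, self.arm, lam=lam_for_update)

        hand_xy = hand_target(pt_xy, pert, true_xy)
        record = {
            "trial": self.trial_idx + 1,
            "phase": phase.label,
            "cue": cue,
            "endpoint_x": endpoint[0],
            "endpoint_y": endpoint[1],
            "hand_angle_deg": _angle(noisy),
            "dist_true_m": float(np.linalg.norm(endpoint - hand_xy)),
            "perceived_error_m": float(np.linalg.norm(e_perceived)),
            "angular_error_deg": _wrap(_angle(pe) - _angle(pt_xy)),
            "reward": reward,
            "rpe": rpe,
            "da": da,
            "lambda_before": lam_before,
            "lambda_after": self.cb.lam,
            "lambda_opt": np.nan if self.lambda_opt is None else self.lambda_opt,
            "mismatch_m": mismatch,
            "critic_branch": branch,
            "w_norm": self.cb.w_norm,
            "mix_top": np.nan if mixture is None else float(np.max(mixture)),
            "mix_dir_deg": np.nan
            if mixture is None
            else float(self.pool.directions[int(np.argmax(mixture))]),
            "rectified": rectified,
            "feedback": available,
        }
        self.trial_idx += 1
        return record

    def run(self) -> pd.DataFrame:
        return pd.DataFrame([self.step() for _ in range(self.spec.n_trials)])


def run_trial(sim: Simulator) -> dict:
    """Execute one trial of an initialized simulator; returns the trial record."""
    return sim.step()


def run_batch(
    spec: ProtocolSpec,
    n_runs: int,
    base_seed: int = 0,
    model: str | None = None,
    arm=None,
) -> tuple[RunSummary, pd.DataFrame]:
    """Run `n_runs` seeded replicates; returns the summary and all trial records.

    Run r is seeded from (base_seed, r); batches are bit-reproducible for a
    fixed seed and context.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if arm is None:
        arm = default_arm()
    frames = []
    for r in range(n_runs):
        sim = Simulator(spec, seed=base_seed + r, model=model, arm=arm)
        df = sim.run()
        df.insert(0, "run", r)
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)

    per_trial = records.groupby("trial")["angular_error_deg"]
    mean_error = per_trial.mean().to_numpy()
    sd = per_trial.std(ddof=1).fillna(0.0).to_numpy() if n_runs > 1 else np.zeros_like(mean_error)
    sem = sd / np.sqrt(n_runs)
    mean_abs = records.assign(a=records.angular_error_deg.abs()).groupby("trial")["a"].mean().to_numpy()
    mean_lam = records.groupby("trial")["lambda_before"].mean().to_numpy()
    phase = records[records.run == 0].sort_values("trial")["phase"].to_numpy()

    adapt = records[records.phase == "adapt"]
    asymptotic = np.nan
    if len(adapt):
        last10 = sorted(adapt.trial.unique())[-10:]
        asymptotic = float(adapt[adapt.trial.isin(last10)].angular_error_deg.abs().mean())
    post = records[records.phase == "post"]
    aftereffect = np.nan
    if len(post):
        first5 = sorted(post.trial.unique())[:5]
        aftereffect = float(post[post.trial.isin(first5)].angular_error_deg.mean())

    summary = RunSummary(
        n_runs=n_runs,
        phase=phase,
        mean_error=mean_error,
        sem_error=sem,
        mean_abs_error=mean_abs,
        mean_lam=mean_lam,
        asymptotic_error=asymptotic,
        aftereffect=aftereffect,
    )
    return summary, records


def rotation_scan(
    angles,
    lam: float = 2.0,
    gamma: float = 0.0,
    n_trials: int = 150,
    noise_sd: float = 0.005,
    seed: int = 0,
    true_angle: float = 45.0,
    radius: float = 0.20,
    conv_dist: float = 0.02,
    conv_streak: int = 10,
    arm=None,
) -> dict:
    """Cerebellum-only adaptation to rotations of increasing angle.

    For each rotation angle the adaptation phase is simulated from a fresh
    correction matrix (degradation off by default, as in the stress test of
    pure error-based learning) and the endpoint sequence is classified:

    - ``converged``: true endpoint within `conv_dist` of the target for
      `conv_streak` consecutive trials;
    - ``spiraling``: no such streak, but the trailing-window mean distance
      still decreasing (stable focus);
    - ``non-convergent``: trailing mean distance not decreasing (oscillation
      with non-decaying amplitude).

    Returns {angle: {"verdict", "distances", "endpoints"}}.
    """
    if arm is None:
        arm = default_arm()
    out = {}
    for i, angle in enumerate(angles):
        rng = np.random.default_rng([seed, i, 0])
        pt = np.deg2rad(true_angle + angle)
        pt_xy = radius * np.array([np.cos(pt), np.sin(pt)])
        ta = np.deg2rad(true_angle)
        target_xy = radius * np.array([np.cos(ta), np.sin(ta)])
        rot = np.array(
            [
                [np.cos(np.deg2rad(angle)), -np.sin(np.deg2rad(angle))],
                [np.sin(np.deg2rad(angle)), np.cos(np.deg2rad(angle))],
            ]
        )
        p = arm.solve_inverse(pt_xy)
        cb = CorrectionState(W=np.zeros((6, 6)), lam=lam, gamma=gamma)
        dists = np.empty(n_trials)
        endpoints = np.empty((n_trials, 2))
        for t in range(n_trials):
            endpoint, _ = arm.forward_flagged(p, cb.W)
            endpoints[t] = endpoint
            dists[t] = np.linalg.norm(endpoint - target_xy)
            noisy = endpoint + rng.normal(0.0, noise_sd, 2)
            e = rot @ noisy - pt_xy
            jac = arm.jacobian(p, cb.W)
            cb = cb_update(cb, p, e, jac, arm)
        streak = 0
        converged = False
        for d in dists:
            streak = streak + 1 if d < conv_dist else 0
            if streak >= conv_streak:
                converged = True
                break
        if converged:
            verdict = "converged"
        else:
            half = n_trials // 3
            late = dists[-half:].mean()
            mid = dists[-2 * half : -half].mean()
            verdict = "spiraling" if late < 0.95 * mid else "non-convergent"
        out[float(angle)] = {"verdict": verdict, "distances": dists, "endpoints": endpoints}
    return out
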