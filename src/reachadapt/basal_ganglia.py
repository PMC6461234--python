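"""Basal-ganglia action selection and reinforcement learning.

Each candidate action (a reaching direction from the context's pool) owns a
parallel loop through the two striatal pathways: cue-driven direct-pathway
neurons (D1 MSN) inhibit GPi, while indirect-pathway neurons (D2 MSN) inhibit
GPe, which releases STN, which excites GPi; GPi tonically inhibits the
thalamocortical relay neuron of the loop.  Cortical (PFC) cue units are not
simulated — the active cue injects a constant drive through learned weights.
The loops interact only in the thalamus, where all-to-all lateral inhibition
plus weak self-excitation produces a winner-take-all competition; the relay
rates at the fixed point, normalised to sum one, are the coefficients with
which the candidate motor programs are blended into the executed program.

Plasticity: the reward prediction error RPE = R - expectation[cue] (the
expectation tracks the received reward), and the dopamine signal DA (RPE plus
the critic's offset) potentiates PFC->D1 and depresses PFC->D2 weights of the
just-selected actions when positive, and the reverse when negative; all
cortico-striatal weights slowly decay in the absence of reinforcement.
Habits — direct PFC->thalamus shortcuts — grow by slow Hebbian potentiation
of co-active cue/relay pairs.  Parkinsonian degeneration is modelled as a
scaling of the reinforcement learning rate (dopamine loss), Huntington
degeneration as a scaling of the D2 MSN population output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActionPool",
    "BGParams",
    "BGState",
    "LesionSpec",
    "init_bg_state",
    "bg_select",
    "compute_rpe",
    "bg_learn",
    "habit_update",
]


@dataclass(frozen=True)
class LesionSpec:
    """Disease models: PD scales reinforcement learning, HD scales D2 output."""

    pd_scale: float = 1.0
    hd_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.pd_scale <= 1 and 0 <= self.hd_scale <= 1):
            raise ValueError("lesion scales must lie in [0, 1]")


@dataclass
class ActionPool:
    """Candidate reaching movements, uniformly spaced over an angular sector."""

    directions: np.ndarray  # degrees, strictly increasing
    programs: np.ndarray  # (n_actions, 6) solved motor programs

    @classmethod
    def build(cls, arm, lo: float, hi: float, n_actions: int = 100, radius: float = 0.20):
        from .arm import TargetSpec

        directions = np.linspace(lo, hi, n_actions)
        programs = np.array([arm.solve_inverse(TargetSpec(a, radius)) for a in directions])
        return cls(directions=directions, programs=programs)

    @property
    def n_actions(self) -> int:
        return len(self.directions)

    def nearest(self, angle: float) -> int:
        return int(np.argmin(np.abs(self.directions - angle)))

    def blend(self, mixture: np.ndarray) -> np.ndarray:
        return np.asarray(mixture) @ self.programs


@dataclass(frozen=True)
class BGParams:
    """Loop-network constants and plasticity rates.

    The nucleus gains reproduce the documented selection logic (habits of the
    printed strengths dominate; punishment releases exploration; reward locks
    selection); they are model constants, not measured quantities.
    """

    # nucleus chain: GPe = [gpe0 - d2], STN = [stn0 - w_gpe_stn*GPe],
    # GPi = [gpi0 - d1 + w_stn_gpi*STN], relay drive = [thal0 - GPi] + habit
    gpe0: float = 1.0
    stn0: float = 1.0
    gpi0: float = 1.0
    thal0: float = 1.5
    w_gpe_stn: float = 0.8
    w_stn_gpi: float = 1.0
    # thalamic competition
    self_exc: float = 0.5
    lat_inh: float = 0.6
    dt: float = 0.2
    fp_tol: float = 1e-8
    max_iter: int = 20000
    # plasticity
    eta_bg: float = 0.03  # cortico-striatal learning rate
    delta_bg: float = 1e-4  # cortico-striatal decay per trial
    eta_exp: float = 0.05  # reward-expectation tracking rate
    eta_hab: float = 1e-4  # Hebbian habit-formation rate (slow)
    w_cap: float = 2.0  # upper bound on striatal weights
    init_scale: float = 0.02  # tiny random PFC->D1 weights (symmetry breaking)


@dataclass
class BGState:
    """Per-cue synaptic weights, reward expectations and last activities."""

    w_d1: dict
    w_d2: dict
    w_habit: dict
    reward_expectation: dict
    activities: dict = field(default_factory=dict)  # populations of last selection

    def to_json(self) -> str:
        def conv(d):
            return {k: np.asarray(v).tolist() for k, v in d.items()}

        return json.dumps(
            {
                "w_d1": conv(self.w_d1),
                "w_d2": conv(self.w_d2),
                "w_habit": conv(self.w_habit),
                "reward_expectation": {k: float(v) for k, v in self.reward_expectation.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BGState":
        d = json.loads(text)
        arr = lambda m: {k: np.asarray(v) for k, v in m.items()}
        return cls(
            w_d1=arr(d["w_d1"]),
            w_d2=arr(d["w_d2"]),
            w_habit=arr(d["w_habit"]),
            reward_expectation=d["reward_expectation"],
        )


def init_bg_state(
    cues: dict,
    pool: ActionPool,
    habit_strength: dict,
    initial_expectation: float,
    params: BGParams,
    rng: np.random.Generator,
) -> BGState:
    """Fresh state: pre-set habitual associations plus tiny random striatal weights.

    The random PFC->D1 weights (uniform on [0, init_scale]) break the
    symmetry between otherwise identical actions and define the deterministic
    order in which exploration visits them.
    """
    n = pool.n_actions
    w_d1, w_d2, w_habit = {}, {}, {}
    for cue, angle in cues.items():
        w_d1[cue] = rng.uniform(0.0, params.init_scale, n)
        w_d2[cue] = np.zeros(n)
        w_habit[cue] = np.zeros(n)
        w_habit[cue][pool.nearest(angle)] = habit_strength[cue]
    expect = {cue: float(initial_expectation) for cue in cues}
    return BGState(w_d1=w_d1, w_d2=w_d2, w_habit=w_habit, reward_expectation=expect)


def _relu(x):
    return np.maximum(x, 0.0)


def bg_select(
    cue,
    state: BGState,
    params: BGParams = BGParams(),
    lesion: LesionSpec = LesionSpec(),
    method: str = "attractor",
) -> np.ndarray:
    """Settle the loop network on its point attractor; return mixture coefficients.

    The upstream nuclei settle instantaneously (feed-forward chain given the
    cue drive); the thalamic stage is the only recurrent one.  With the
    calibrated competition gains (lat_inh >= 1 - self_exc) its attractor
    from rest has a closed form: the maximally driven relay neurons (ties
    share) settle at the symmetric fixed-point rate and every other loop is
    fully suppressed.  ``method="attractor"`` evaluates that closed form
    (residual exactly zero); ``method="ode"`` integrates the rate equation
    until the residual falls below `fp_tol` and is kept as a cross-check.
    The relay rates are normalised to sum one.
    """
    if cue not in state.w_d1:
        raise KeyError(f"unknown cue {cue!r}")
    d1 = _relu(state.w_d1[cue])
    d2 = _relu(state.w_d2[cue]) * lesion.hd_scale
    gpe = _relu(params.gpe0 - d2)
    stn = _relu(params.stn0 - params.w_gpe_stn * gpe)
    gpi = _relu(params.gpi0 - d1 + params.w_stn_gpi * stn)
    # habit shortcuts excite the relay neurons directly, inside the same
    # rectification as the GPi inhibition — a hyperactive indirect pathway
    # can therefore override even a strong habitual association
    drive = _relu(params.thal0 - gpi + state.w_habit[cue])

    if method == "attractor":
        if params.lat_inh < 1.0 - params.self_exc:
            raise ValueError("closed-form attractor requires lat_inh >= 1 - self_exc")
        x = np.zeros_like(drive)
        dmax = float(drive.max())
        if dmax > 0:
            winners = drive >= dmax - 1e-9 * max(dmax, 1.0)
            k = int(winners.sum())
            x[winners] = dmax / (1.0 - params.self_exc + params.lat_inh * (k - 1))
    elif method == "ode":
        x = np.zeros_like(drive)
        for _ in range(params.max_iter):
            total = x.sum()
            target = _relu(drive + params.self_exc * x - params.lat_inh * (total - x))
            dx = target - x
            # the global-inhibition mode is stiff while many units are
            # active; keep the explicit step inside its stability limit
            n_active = int(np.count_nonzero((x > 1e-10) | (target > 0)))
            dt = min(params.dt, 0.9 / (1.0 + params.lat_inh * n_active))
            x = x + dt * dx
            x[(target == 0) & (x < 1e-10)] = 0.0
            if np.max(np.abs(dx)) < params.fp_tol:
                break
        else:
            raise RuntimeError("thalamic relaxation did not reach a fixed point")
    else:
        raise ValueError(f"unknown method {method!r}")

    state.activities = {"d1": d1, "d2": d2, "gpe": gpe, "stn": stn, "gpi": gpi, "thal": x}
    s = x.sum()
    if s <= 0:
        return np.full_like(x, 1.0 / len(x))
    return x / s


def compute_rpe(reward: float, cue, state: BGState, params: BGParams = BGParams()) -> float:
    """RPE = reward - expectation[cue]; the expectation then tracks the reward.

    With the default tracking rate of 1 the expectation equals the previous
    reward for the cue, so the RPE is the temporal difference between the
    rewards of consecutive trials with that cue.
    """
    if not np.isfinite(reward):
        raise ValueError("reward must be finite")
    if cue not in state.reward_expectation:
        raise KeyError(f"unknown cue {cue!r}")
    rpe = float(reward) - state.reward_expectation[cue]
    state.reward_expectation[cue] += params.eta_exp * rpe
    return rpe


def bg_learn(
    da: float,
    cue,
    mixture: np.ndarray,
    state: BGState,
    params: BGParams = BGParams(),
    lesion: LesionSpec = LesionSpec(),
) -> None:
    """Dopamine-gated cortico-striatal plasticity on the selected actions.

    Positive DA potentiates PFC->D1 and depresses PFC->D2 in proportion to
    each action's share of the selection; negative DA does the opposite.
    All weights decay slowly and stay within [0, w_cap].
    """
    step = params.eta_bg * lesion.pd_scale * float(da) * np.asarray(mixture)
    for w, sgn in ((state.w_d1, 1.0), (state.w_d2, -1.0)):
        w[cue] = np.clip((1.0 - params.delta_bg) * w[cue] + sgn * step, 0.0, params.w_cap)


def habit_update(cue, mixture: np.ndarray, state: BGState, params: BGParams = BGParams()) -> None:
    """Slow Hebbian potentiation of direct cue->relay shortcuts."""
    thal = state.activities.get("thal")
    if thal is None or params.eta_hab == 0:
        return
    state.w_habit[cue] = np.clip(
        state.w_habit[cue] + params.eta_hab * np.asarray(mixture) * thal, 0.0, params.w_cap
    )
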