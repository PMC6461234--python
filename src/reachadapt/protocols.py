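"""Experimental protocols: perturbations, reward rules and phase schedules.

A protocol ("context") models everything the simulated subject does not
control: which cue is shown, how the visual feedback is transformed, and how
reward is computed.  Contexts are declarative phase schedules shipped as YAML
files; :func:`build_context` loads one by name and applies a variant (e.g.
the ataxia parameter set, a PD/HD lesion, or the binary-feedback protocol
arm).

Visual perturbations transform the *perceived* endpoint (and hence the
perceived vector error): a rotation turns the endpoint about the start
point, an x-reflection mirrors it, a shift translates the whole image so the
error vector itself is unchanged, an error clamp always displays a perfect
hit, and a no-feedback trial hides the error altogether.  Reward is computed
on the perceived (cursor-frame) error — the apparatus scores cursor-target
proximity — except that error-clamp trials always pay out.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .basal_ganglia import LesionSpec
from .critic import CriticParams

__all__ = [
    "Perturbation",
    "RewardRule",
    "Phase",
    "ProtocolSpec",
    "perceive",
    "build_context",
    "CONTEXT_NAMES",
]

PERTURBATION_KINDS = ("none", "shift", "rotation", "reflect_x", "error_clamp", "no_feedback")
REWARD_KINDS = ("spot", "gutierrez", "shmuelof")
MODELS = ("cb", "bg", "cb+bg", "cb+critic", "cb+bg+critic")
CONTEXT_NAMES = (
    "mild_shift",
    "mild_rotation",
    "strong_shift",
    "strong_rotation",
    "reflection",
    "schlerf",
    "gutierrez",
    "shmuelof",
)


@dataclass(frozen=True)
class Perturbation:
    """A visual transform of the feedback; rotations carry an angle (deg CCW)."""

    kind: str = "none"
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "rotation" and self.angle == 0.0:
            raise ValueError("rotation perturbation requires a non-zero angle")


@dataclass(frozen=True)
class RewardRule:
    """Reward as a function of the error magnitude and the learning rate.

    spot:      magnitude inside a circular target spot, else 0
    gutierrez: R = -22 |e|^1.5 + 0.7 lambda   (graded score, throwing task)
    shmuelof:  R = 2 Theta(0.028 - |e|) + 0.65 lambda   (explicit binary reward)
    """

    kind: str = "spot"
    magnitude: float = 3.0
    radius: float = 0.04  # m

    def __post_init__(self) -> None:
        if self.kind not in REWARD_KINDS:
            raise ValueError(f"unknown reward kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("reward spot radius must be positive")

    def reward(self, e_norm: float, lam: float = 0.0) -> float:
        e = float(e_norm)
        if self.kind == "spot":
            return self.magnitude if e < self.radius else 0.0
        if self.kind == "gutierrez":
            return -22.0 * e**1.5 + 0.7 * lam
        return (2.0 if e < 0.028 else 0.0) + 0.65 * lam


@dataclass
class Phase:
    """One block of trials with fixed cue schedule, perturbation and flags."""

    label: str
    n_trials: int
    cue: str | list
    perturbation: Perturbation = field(default_factory=Perturbation)
    true_cue: str | None = None  # where the hand must actually go (shift)
    visual_feedback: bool = True
    critic_zero: bool = False  # force the critic output to zero (Shmuelof BE)

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError(f"phase {self.label!r}: trial count must be positive")
        if self.perturbation.kind == "shift" and self.true_cue is None:
            raise ValueError(f"phase {self.label!r}: shift perturbation needs true_cue")

    def cue_for_trial(self, rng: np.random.Generator):
        if isinstance(self.cue, list):
            return self.cue[int(rng.integers(len(self.cue)))]
        return self.cue


def _rot(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def perceive(endpoint: np.ndarray, perceived_target: np.ndarray, pert: Perturbation,
             true_target: np.ndarray | None = None):
    """Apply the visual perturbation to a (noisy) endpoint.

    Returns ``(perceived_endpoint, error, available)`` where `error` is the
    perceived vector error (perceived endpoint minus displayed target) and
    `available` is False on no-feedback trials (the error is still computed —
    the apparatus knows it for reward — but the learner must not see it).
    """
    endpoint = np.asarray(endpoint, dtype=float)
    pt = np.asarray(perceived_target, dtype=float)
    if pert.kind == "none" or pert.kind == "no_feedback":
        pe = endpoint
    elif pert.kind == "rotation":
        pe = _rot(pert.angle) @ endpoint
    elif pert.kind == "reflect_x":
        pe = np.array([-endpoint[0], endpoint[1]])
    elif pert.kind == "shift":
        if true_target is None:
            raise ValueError("shift perturbation requires the true target")
        pe = endpoint + (pt - np.asarray(true_target, dtype=float))
    elif pert.kind == "error_clamp":
        pe = pt.copy()
    else:  # pragma: no cover
        raise ValueError(pert.kind)
    return pe, pe - pt, pert.kind != "no_feedback"


def hand_target(perceived_target: np.ndarray, pert: Perturbation,
                true_target: np.ndarray | None = None) -> np.ndarray:
    """Hand position that would zero the perceived error (the de-facto goal)."""
    pt = np.asarray(perceived_target, dtype=float)
    if pert.kind == "rotation":
        return _rot(-pert.angle) @ pt
    if pert.kind == "reflect_x":
        return np.array([-pt[0], pt[1]])
    if pert.kind == "shift":
        return np.asarray(true_target, dtype=float)
    return pt


@dataclass
class ProtocolSpec:
    """A fully parameterised experimental context."""

    name: str
    cues: dict  # cue id -> target angle (deg)
    habit: dict  # cue id -> habitual association strength
    phases: list
    pool: dict = field(default_factory=lambda: {"lo": 20.0, "hi": 155.0, "n": 100})
    target_radius: float = 0.20
    noise_sd: float = 0.005
    reward_rule: RewardRule = field(default_factory=RewardRule)
    initial_expectation: float = 0.0
    cb: dict = field(default_factory=lambda: {"lam": 2.0, "gamma": 0.04})
    critic: CriticParams | None = None
    lesion: LesionSpec = field(default_factory=LesionSpec)
    bg_overrides: dict = field(default_factory=dict)
    awareness_reset: bool = False
    model: str = "cb+bg+critic"
    variant: str = ""

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_trials(self) -> int:
        return sum(ph.n_trials for ph in self.phases)

    def target_xy(self, cue: str) -> np.ndarray:
        a = np.deg2rad(self.cues[cue])
        return self.target_radius * np.array([np.cos(a), np.sin(a)])

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model variant {self.model!r}")
        if not self.phases:
            raise ValueError("a protocol needs at least one phase")
        if self.target_radius <= 0:
            raise ValueError("target radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        for cue in self.cues:
            if cue not in self.habit:
                raise ValueError(f"cue {cue!r} has no initialized habit strength")
        for ph in self.phases:
            cues = ph.cue if isinstance(ph.cue, list) else [ph.cue]
            for c in cues + ([ph.true_cue] if ph.true_cue else []):
                if c not in self.cues:
                    raise ValueError(f"phase {ph.label!r} references unknown cue {c!r}")
        lam, gamma = self.cb.get("lam"), self.cb.get("gamma")
        if lam is None or lam < 0 or gamma is None or not 0 <= gamma < 1:
            raise ValueError("cb parameters need lam >= 0 and gamma in [0, 1)")

    def check_workspace(self, arm) -> None:
        """Verify every pool direction and cue target is solvable."""
        from .arm import TargetSpec, WorkspaceError

        bad = []
        angles = list(np.linspace(self.pool["lo"], self.pool["hi"], self.pool["n"]))
        angles += list(self.cues.values())
        for a in angles:
            try:
                arm.solve_inverse(TargetSpec(a, self.target_radius))
            except WorkspaceError:
                bad.append(float(a))
        if bad:
            raise ValueError(f"directions outside the arm workspace: {bad}")


# --------------------------------------------------------------- YAML loading

_ALLOWED_TOP = {
    "name", "cues", "habit", "phases", "pool", "target_radius", "noise_sd",
    "reward", "initial_expectation", "cb", "critic", "lesion", "bg",
    "awareness_reset", "model", "variants",
}
_ALLOWED_PHASE = {
    "label", "n_trials", "cue", "perturbation", "angle", "true_cue",
    "visual_feedback", "critic_zero",
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _build_phase(d: dict) -> Phase:
    unknown = set(d) - _ALLOWED_PHASE
    if unknown:
        raise ValueError(f"unknown phase keys {sorted(unknown)}; allowed: {sorted(_ALLOWED_PHASE)}")
    pert = Perturbation(d.get("perturbation", "none"), float(d.get("angle", 0.0)))
    return Phase(
        label=d["label"],
        n_trials=int(d["n_trials"]),
        cue=d["cue"],
        perturbation=pert,
        true_cue=d.get("true_cue"),
        visual_feedback=bool(d.get("visual_feedback", True)),
        critic_zero=bool(d.get("critic_zero", False)),
    )


def spec_from_dict(cfg: dict, variant: str = "") -> ProtocolSpec:
    """Validate a raw context dictionary and construct a ProtocolSpec."""
    unknown = set(cfg) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown context keys {sorted(unknown)}; allowed: {sorted(_ALLOWED_TOP)}")
    phases = [_build_phase(p) for p in cfg["phases"]]
    critic = None
    if cfg.get("critic") is not None:
        critic = CriticParams(**cfg["critic"])
    return ProtocolSpec(
        name=cfg["name"],
        cues={k: float(v) for k, v in cfg["cues"].items()},
        habit={k: float(v) for k, v in cfg["habit"].items()},
        phases=phases,
        pool=cfg.get("pool", {"lo": 20.0, "hi": 155.0, "n": 100}),
        target_radius=float(cfg.get("target_radius", 0.20)),
        noise_sd=float(cfg.get("noise_sd", 0.005)),
        reward_rule=RewardRule(**cfg.get("reward", {})),
        initial_expectation=float(cfg.get("initial_expectation", 0.0)),
        cb=dict(cfg.get("cb", {"lam": 2.0, "gamma": 0.04})),
        critic=critic,
        lesion=LesionSpec(**cfg.get("lesion", {})),
        bg_overrides=dict(cfg.get("bg", {})),
        awareness_reset=bool(cfg.get("awareness_reset", False)),
        model=cfg.get("model", "cb+bg+critic"),
        variant=variant,
    )


def _apply_variant(cfg: dict, parts: list[str]) -> dict:
    variants = cfg.get("variants", {}) or {}
    out = {k: v for k, v in cfg.items() if k != "variants"}
    for part in parts:
        if part not in variants:
            raise ValueError(
                f"unknown variant {part!r} for context {cfg['name']!r}; "
                f"available: {sorted(variants)}"
            )
        ov = copy.deepcopy(variants[part])
        phase_ov = ov.pop("phases", {})
        out = _deep_merge(out, ov)
        for label, pov in phase_ov.items():
            hit = False
            for ph in out["phases"]:
                if ph["label"] == label:
                    ph.update(copy.deepcopy(pov))
                    hit = True
            if not hit:
                raise ValueError(f"variant {part!r} overrides unknown phase {label!r}")
    return out


def _norm_variant(variant: str | None) -> list[str]:
    if not variant:
        return []
    v = variant.strip().lower().replace("be+ve", "beve")
    return [p for p in v.replace("-", ",").replace("+", ",").split(",") if p]


def build_context(name: str, variant: str | None = None, **overrides) -> ProtocolSpec:
    """Load a named context from the packaged YAML files and apply a variant.

    Variants compose with ',' (e.g. ``"pd,shift"`` or ``"be,clamp100"``);
    keyword overrides are merged last (e.g. ``model="cb"`` for a
    cerebellum-only run).
    """
    if name not in CONTEXT_NAMES:
        raise ValueError(f"unknown context {name!r}; available: {CONTEXT_NAMES}")
    text = resources.files("reachadapt.data.contexts").joinpath(f"{name}.yaml").read_text()
    cfg = yaml.safe_load(text)
    cfg = _apply_variant(cfg, _norm_variant(variant))
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return spec_from_dict(cfg, variant="+".join(_norm_variant(variant)))
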