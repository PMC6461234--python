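"""Configuration loading, validation, serialization and test fixtures.

User-supplied context files use the same YAML schema as the packaged
contexts (see ``reachadapt/data/contexts/``).  :func:`validate_config`
parses, validates (unknown keys rejected, invariants checked, workspace
coverage verified against the arm surrogate) and echoes the fully resolved
protocol.  :func:`make_fixture` writes small deterministic fixtures used by
the test-suite oracles.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .arm import default_arm
from .protocols import ProtocolSpec, spec_from_dict

__all__ = ["validate_config", "dump_spec", "load_spec", "make_fixture", "run_manifest"]


def validate_config(path, arm=None, check_workspace: bool = True) -> ProtocolSpec:
    """Load a context YAML file and validate every protocol invariant.

    Raises ValueError with the offending path and a remedy hint; returns the
    resolved :class:`ProtocolSpec` on success.
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    cfg.pop("variants", None)
    try:
        spec = spec_from_dict(cfg)
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc
    if check_workspace:
        spec.check_workspace(arm if arm is not None else default_arm())
    return spec


def dump_spec(spec: ProtocolSpec) -> dict:
    """Round-trippable dictionary form of a protocol (load(dump(s)) == s)."""
    phases = []
    for ph in spec.phases:
        d = {"label": ph.label, "n_trials": ph.n_trials, "cue": ph.cue}
        if ph.perturbation.kind != "none":
            d["perturbation"] = ph.perturbation.kind
        if ph.perturbation.angle:
            d["angle"] = ph.perturbation.angle
        if ph.true_cue is not None:
            d["true_cue"] = ph.true_cue
        if not ph.visual_feedback:
            d["visual_feedback"] = False
        if ph.critic_zero:
            d["critic_zero"] = True
        phases.append(d)
    out = {
        "name": spec.name,
        "cues": dict(spec.cues),
        "habit": dict(spec.habit),
        "pool": dict(spec.pool),
        "target_radius": spec.target_radius,
        "noise_sd": spec.noise_sd,
        "reward": {
            "kind": spec.reward_rule.kind,
            "magnitude": spec.reward_rule.magnitude,
            "radius": spec.reward_rule.radius,
        },
        "initial_expectation": spec.initial_expectation,
        "cb": dict(spec.cb),
        "lesion": {"pd_scale": spec.lesion.pd_scale, "hd_scale": spec.lesion.hd_scale},
        "awareness_reset": spec.awareness_reset,
        "model": spec.model,
        "phases": phases,
    }
    if spec.critic is not None:
        out["critic"] = dataclasses.asdict(spec.critic)
    if spec.bg_overrides:
        out["bg"] = dict(spec.bg_overrides)
    return out


def load_spec(cfg: dict) -> ProtocolSpec:
    return spec_from_dict(dict(cfg))


def make_fixture(kind: str, out_dir) -> Path:
    """Write a deterministic fixture; returns the path written.

    - ``linear_toy``: a one-dimensional linear forward map F = c (1 + w) p
      with its closed-form learning asymptote, for oracle tests.
    - ``tiny_protocol``: a three-phase context with 5 trials per phase for
      fast end-to-end checks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "linear_toy":
        c, lam, gamma, x0 = 2.0, 0.1, 0.02, 1.0
        fixture = {
            "kind": "linear_toy",
            "c": c,
            "lam": lam,
            "gamma": gamma,
            "target": x0,
            # fixed point of w_new = w - lam*c*(c*(1+w) - x0/p ...) on the
            # scalar system: asymptotic error gamma*x0/(lam*c^2 + gamma)
            "asymptotic_error": gamma * x0 / (lam * c**2 + gamma),
            "one_step_optimal_rate": 1.0 / c**2,
        }
        path = out_dir / "linear_toy.json"
        path.write_text(json.dumps(fixture, indent=2, sort_keys=True) + "\n")
        return path
    if kind == "tiny_protocol":
        cfg = {
            "name": "tiny",
            "cues": {"C1": 45.0, "C2": 75.0},
            "habit": {"C1": 0.3, "C2": 0.3},
            "pool": {"lo": 20.0, "hi": 155.0, "n": 20},
            "noise_sd": 0.005,
            "reward": {"kind": "spot", "magnitude": 3.0, "radius": 0.04},
            "initial_expectation": 3.0,
            "cb": {"lam": 2.0, "gamma": 0.04},
            "model": "cb",
            "phases": [
                {"label": "baseline", "n_trials": 5, "cue": "C1"},
                {"label": "adapt", "n_trials": 5, "cue": "C2",
                 "perturbation": "rotation", "angle": 30.0},
                {"label": "post", "n_trials": 5, "cue": "C1"},
            ],
        }
        spec_from_dict(cfg)  # validates
        path = out_dir / "tiny_protocol.yaml"
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
        return path
    raise ValueError(f"unknown fixture kind {kind!r}")


def run_manifest(spec: ProtocolSpec, n_runs: int, base_seed: int, model: str | None,
                 outputs: dict) -> dict:
    """Everything needed to reproduce a batch exactly."""
    from . import __version__

    return {
        "package_version": __version__,
        "context": spec.name,
        "variant": spec.variant,
        "model": model or spec.model,
        "n_runs": n_runs,
        "seeds": list(range(base_seed, base_seed + n_runs)),
        "arm": default_arm().to_dict(),
        "protocol": dump_spec(spec),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
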