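"""Performance critic: gates error-based learning and offsets dopamine.

The critic compares the cerebellum's predicted post-correction error with the
error actually perceived on the next trial,

    mismatch = || e_real - e_exp ||,

and classifies the prediction against two thresholds that are multiples of
the subject's estimate kappa of its own movement variability:

    consistent   (mismatch <  t_low  * kappa)  -> lambda * speed_up
    inconclusive (in between)                  -> lambda
    inconsistent (mismatch >= t_high * kappa)  -> lambda / slow_down

The output is clipped to [0.001, a_opt * lambda_opt], where lambda_opt is the
rate that would cancel the current error in a single step were the visual
mapping veridical.  If the current error is below 1 mm the critic leaves the
rate untouched (nothing informative can be read from a hit).  The same signal
offsets the reinforcement system: DA = RPE + alpha * critic, so that while
cerebellar corrections work, the loss of reward caused by a perturbation does
not negatively reinforce the selected action.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CriticParams", "critic_eval", "lambda_optimal", "dopamine"]

LAMBDA_FLOOR = 0.001
SMALL_ERROR = 0.001  # m; hits closer than this leave the rate unchanged


@dataclass(frozen=True)
class CriticParams:
    """Thresholds and rate-update factors of the critic."""

    t_low: float = 2.0
    t_high: float = 3.5
    kappa: float = 0.005  # movement-variability estimate (m)
    speed_up: float = 1.3
    slow_down: float = 1.3
    a_opt: float = 0.4  # fraction of the one-step-optimal rate (ceiling)
    alpha: float = 1.0  # dopamine coupling

    def __post_init__(self) -> None:
        if not (0 < self.t_low <= self.t_high):
            raise ValueError("need 0 < t_low <= t_high")
        if self.speed_up <= 1 or self.slow_down <= 1:
            raise ValueError("speed_up and slow_down must exceed 1")
        if not (0 < self.a_opt <= 1):
            raise ValueError("a_opt must be in (0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def critic_eval(
    e_real: np.ndarray,
    e_exp: np.ndarray,
    lam: float,
    params: CriticParams,
    lambda_opt: float,
) -> tuple[float, str]:
    """New cerebellar learning rate and the branch taken.

    Branches: 'up', 'hold', 'down', then 'floor'/'ceiling' if the bound
    binds, or 'small-error' when the 1-mm rule short-circuits the update.
    """
    e_real = np.asarray(e_real, dtype=float)
    e_exp = np.asarray(e_exp, dtype=float)
    if not (np.all(np.isfinite(e_real)) and np.all(np.isfinite(e_exp)) and np.isfinite(lam)):
        raise FloatingPointError("non-finite critic inputs")
    if np.linalg.norm(e_real) < SMALL_ERROR:
        return float(lam), "small-error"
    mismatch = float(np.linalg.norm(e_real - e_exp))
    if mismatch < params.t_low * params.kappa:
        out, branch = lam * params.speed_up, "up"
    elif mismatch >= params.t_high * params.kappa:
        out, branch = lam / params.slow_down, "down"
    else:
        out, branch = lam, "hold"
    ceiling = params.a_opt * lambda_opt
    if out > ceiling:
        return float(ceiling), "ceiling"
    if out < LAMBDA_FLOOR:
        return LAMBDA_FLOOR, "floor"
    return float(out), branch


def lambda_optimal(e: np.ndarray, jac: np.ndarray, fallback: float | None = None) -> float:
    """Learning rate that cancels the linearized error in one step.

    A gradient step with rate lambda moves the endpoint by -lambda * M e with
    M[k,l] = sum_ij jac[i,j,k] jac[i,j,l]; the least-squares one-step
    eliminator of e is lambda_opt = (e' M e) / ||M e||^2 (positive part).
    When M e vanishes the previous value is reused.
    """
    e = np.asarray(e, dtype=float)
    M = np.einsum("ijk,ijl->kl", np.asarray(jac), np.asarray(jac))
    Me = M @ e
    denom = float(Me @ Me)
    if denom <= 0:
        if fallback is None:
            raise ZeroDivisionError("degenerate Jacobian and no previous lambda_opt")
        return float(fallback)
    return max(float(e @ Me) / denom, 0.0)


def dopamine(rpe: float, critic_out: float, alpha: float) -> float:
    """Striatal reinforcement signal DA = RPE + alpha * critic."""
    return float(rpe) + float(alpha) * float(critic_out)
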