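"""Cerebellar error-based learner: the 6x6 correction matrix and its update rule.

The cerebellum is a single linear layer that transforms the cortical motor
program, ``p_cor = (I + W) p``, and adjusts ``W`` after every movement by one
gradient-descent step on the squared vector error, with an exponential weight
decay that models trial-to-trial forgetting:

    W_new[i,j] = W[i,j] - lambda * sum_k jac[i,j,k] e[k] - gamma * W[i,j]

where ``jac = dF/dW`` is the endpoint sensitivity tensor supplied by the arm
module, ``e`` the perceived vector error of the trial just completed,
``lambda`` the learning rate (set trial-by-trial by the critic when one is
active) and ``gamma`` the degradation rate.  The interplay of the two rates
produces the characteristic non-zero asymptotic error: learning stalls where
the gradient step is exactly cancelled by decay.

After an update the learner also forms a prediction ``e_exp`` of the error it
expects to perceive on the next trial, assuming the visual mapping is
veridical and the same program is executed:

    e_exp = e_perceived + [F(p, W_new) - F(p, W_old)]

i.e. the current perceived error plus the internally simulated change of the
endpoint.  The critic scores this prediction against the next observed error.
Working with the predicted *change* keeps large but unperturbing distortions
(e.g. a pure visual shift) consistent, while rotations and reflections of the
error vector break the prediction and are flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["CorrectionState", "apply_correction", "cb_update", "skip_update"]


@dataclass
class CorrectionState:
    """Cerebellar state: correction matrix, rates and the error prediction."""

    W: np.ndarray = field(default_factory=lambda: np.zeros((6, 6)))
    lam: float = 1.0
    gamma: float = 0.04
    e_exp: np.ndarray | None = None  # predicted next perceived error (m)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be a square matrix")
        if self.lam < 0:
            raise ValueError("learning rate must be >= 0")
        if not 0 <= self.gamma < 1:
            raise ValueError("degradation rate must be in [0, 1)")

    @property
    def w_norm(self) -> float:
        """Frobenius norm of the correction matrix (logged per trial)."""
        return float(np.linalg.norm(self.W))

    def to_json(self) -> str:
        return json.dumps(
            {
                "W": self.W.tolist(),
                "lam": self.lam,
                "gamma": self.gamma,
                "e_exp": None if self.e_exp is None else list(map(float, self.e_exp)),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CorrectionState":
        d = json.loads(text)
        e_exp = None if d["e_exp"] is None else np.asarray(d["e_exp"])
        return cls(W=np.asarray(d["W"]), lam=d["lam"], gamma=d["gamma"], e_exp=e_exp)


def apply_correction(p: np.ndarray, state: CorrectionState) -> np.ndarray:
    """Corrected motor program (I + W) p, before rectification by the arm."""
    p = np.asarray(p, dtype=float)
    return p + state.W @ p


def cb_update(
    state: CorrectionState,
    p: np.ndarray,
    e: np.ndarray,
    jac: np.ndarray,
    arm=None,
    lam: float | None = None,
) -> CorrectionState:
    """One gradient step on the squared error plus weight degradation.

    Parameters
    ----------
    state : CorrectionState
    p : motor program executed on the trial (pre-correction amplitudes).
    e : perceived 2-vector error (m) of the just-completed trial.
    jac : (6, 6, 2) endpoint sensitivity dF/dW at (p, W).
    arm : optional forward model used to form the error prediction e_exp for
        the critic; when None the prediction is the first-order one,
        e - lambda * M e.
    lam : learning rate override for this trial (critic output); defaults to
        the rate stored in the state.

    Returns a new state; the input state is not mutated.
    """
    lam_t = state.lam if lam is None else float(lam)
    e = np.asarray(e, dtype=float)
    grad = np.einsum("ijk,k->ij", np.asarray(jac), e)
    W_new = state.W - lam_t * grad - state.gamma * state.W
    if not np.all(np.isfinite(W_new)):
        raise FloatingPointError("non-finite cerebellar weights after update")
    if arm is not None:
        delta = arm.forward(p, W_new) - arm.forward(p, state.W)
    else:
        M = np.einsum("ijk,ijl->kl", np.asarray(jac), np.asarray(jac))
        delta = -lam_t * (M @ e)
    return replace(state, W=W_new, lam=lam_t, e_exp=e + delta)


def skip_update(state: CorrectionState) -> CorrectionState:
    """No-visual-feedback trial: no learning and no degradation.

    The correction matrix and the standing error prediction are carried over
    unchanged; nothing in the cerebellum sees such a trial.
    """
    return replace(state)
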