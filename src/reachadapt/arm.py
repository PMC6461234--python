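"""Reduced planar-arm surrogate: smooth, invertible map from motor programs to endpoints.

The movement system is summarised by a forward map ``F(p, W)`` from a
6-component motor program ``p`` (non-negative muscle-drive amplitudes for the
shoulder flexor/extensor, elbow flexor/extensor and bi-articular
flexor/extensor pairs, all modulating one shared bell-shaped velocity
template) to a 2-D movement endpoint, optionally transformed by a cerebellar
correction matrix ``W`` via ``p_cor = (I + W) p``.

The surrogate is a two-link arm: antagonist drives are differenced into two
channels (plus a bi-articular contribution to both), a fixed 2x2 gain matrix
``K`` converts the channels into joint excursions from the rest posture, and
trigonometric forward kinematics give the hand position.  ``K`` is the inverse
of the endpoint Jacobian at a reference posture times a scalar gain, so the
endpoint sensitivity to the channels is close to isotropic everywhere in the
workspace and the inverse problem is well conditioned.  Only the endpoint of
a reach matters to trial-to-trial learning, so within-movement kinematics are
not modelled.

Coordinates: origin at the movement start, x to the subject's right, y away
from the body; angles counterclockwise from +x, so 90 deg is straight ahead.
Unperturbed targets sit on a circle of radius 0.20 m around the start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "TargetSpec",
    "WorkspaceError",
    "PlanarArmSurrogate",
    "LinearArmSurrogate",
    "default_arm",
]

N_DRIVES = 6

#: signed channel mixing: row 0 = shoulder channel, row 1 = elbow channel.
#: Antagonists contribute with opposite sign; the bi-articular pair (drives
#: 4, 5) feeds both joints with smaller weight.
CHANNEL_MATRIX = np.array(
    [
        [1.0, -1.0, 0.0, 0.0, 0.3, -0.3],
        [0.0, 0.0, 1.0, -1.0, 0.2, -0.2],
    ]
)


class WorkspaceError(ValueError):
    """Raised when a target lies outside the surrogate's reachable workspace."""


@dataclass(frozen=True)
class TargetSpec:
    """A reach target given by direction (deg, CCW from +x) and radius (m)."""

    angle: float
    radius: float = 0.20

    def __post_init__(self) -> None:
        if not np.isfinite(self.angle) or not np.isfinite(self.radius):
            raise ValueError("target angle and radius must be finite")
        if self.radius < 0:
            raise ValueError("target radius must be >= 0")
        object.__setattr__(self, "angle", float(self.angle) % 360.0)

    @property
    def xy(self) -> np.ndarray:
        a = np.deg2rad(self.angle)
        return self.radius * np.array([np.cos(a), np.sin(a)])


def _as_target(target) -> TargetSpec:
    if isinstance(target, TargetSpec):
        return target
    x, y = np.asarray(target, dtype=float)
    return TargetSpec(float(np.rad2deg(np.arctan2(y, x))) % 360.0, float(np.hypot(x, y)))


@dataclass
class PlanarArmSurrogate:
    """Two-link planar arm driven by six muscle-drive amplitudes.

    Parameters
    ----------
    l1, l2 : float
        Link lengths (m).
    shoulder : array-like
        Shoulder pivot position in the start-centred frame (m).
    gain_scale : float
        Scalar endpoint gain (m per channel unit).  Together with the
        co-contraction baseline it sets the endpoint sensitivity to the
        correction matrix and therefore the per-trial learning contraction.
    baseline : float
        Co-contraction baseline added to every drive by the inverse solver;
        keeps all six program components strictly positive so the correction
        matrix can act through every input.
    gain_aniso : float
        Ratio of the depth-axis (y) to the lateral-axis (x) endpoint gain.
        Two-link arms have an anisotropic endpoint mobility ellipse; the
        surrogate keeps a fixed, calibrated ratio (< 1: the lateral axis is
        the mobile, high-gain one), which shapes how quickly errors along
        each screen axis are corrected.
    ref_angle, ref_radius : float
        Reference target whose posture defines the channel-to-joint gain
        matrix K = inv(dF/dtheta) * diag(gain_scale/gain_aniso, gain_scale).
    """

    l1: float = 0.5
    l2: float = 0.5
    shoulder: np.ndarray = field(default_factory=lambda: np.array([0.0, -0.55]))
    gain_scale: float = 0.011
    gain_aniso: float = 0.5
    baseline: float = 6.0
    ref_angle: float = 90.0
    ref_radius: float = 0.20
    elbow_sign: float = 1.0
    solver_tol: float = 1e-10

    def __post_init__(self) -> None:
        self.shoulder = np.asarray(self.shoulder, dtype=float)
        self._rest_theta = self._ik(np.zeros(2))
        # K maps the two drive channels onto joint excursions from rest.
        ref_xy = TargetSpec(self.ref_angle, self.ref_radius).xy
        theta_ref = self._ik(ref_xy)
        gains = np.diag([self.gain_scale / self.gain_aniso, self.gain_scale])
        self._K = np.linalg.inv(self._fk_jacobian(theta_ref)) @ gains
        self._Kinv = np.linalg.inv(self._K)

    # ------------------------------------------------------------------ FK/IK
    def _fk(self, theta: np.ndarray) -> np.ndarray:
        t1, t2 = theta
        return self.shoulder + np.array(
            [
                self.l1 * np.cos(t1) + self.l2 * np.cos(t1 + t2),
                self.l1 * np.sin(t1) + self.l2 * np.sin(t1 + t2),
            ]
        )

    def _fk_jacobian(self, theta: np.ndarray) -> np.ndarray:
        t1, t2 = theta
        s1, c1 = np.sin(t1), np.cos(t1)
        s12, c12 = np.sin(t1 + t2), np.cos(t1 + t2)
        return np.array(
            [
                [-self.l1 * s1 - self.l2 * s12, -self.l2 * s12],
                [self.l1 * c1 + self.l2 * c12, self.l2 * c12],
            ]
        )

    def _ik(self, xy: np.ndarray) -> np.ndarray:
        v = np.asarray(xy, dtype=float) - self.shoulder
        d2 = float(v @ v)
        d = np.sqrt(d2)
        lo = abs(self.l1 - self.l2) + 0.05
        hi = (self.l1 + self.l2) * 0.95
        if not (lo <= d <= hi):
            raise WorkspaceError(
                f"point {np.round(xy, 4)} at {d:.3f} m from the shoulder is outside "
                f"the workspace annulus [{lo:.3f}, {hi:.3f}] m"
            )
        cos_el = (d2 - self.l1**2 - self.l2**2) / (2 * self.l1 * self.l2)
        cos_el = np.clip(cos_el, -1.0, 1.0)
        t2 = self.elbow_sign * np.arccos(cos_el)
        t1 = np.arctan2(v[1], v[0]) - np.arctan2(
            self.l2 * np.sin(t2), self.l1 + self.l2 * np.cos(t2)
        )
        return np.array([t1, t2])

    # ------------------------------------------------------------- interface
    def solve_inverse(self, target) -> np.ndarray:
        """Motor program reaching `target` with zero correction.

        The two joint excursions are converted back to channel values and
        allocated to the agonist of each antagonist pair; the bi-articular
        pair stays at the co-contraction baseline.  Raises
        :class:`WorkspaceError` for unreachable targets.
        """
        t = _as_target(target)
        if t.radius < self.solver_tol:
            return np.full(N_DRIVES, self.baseline)
        theta = self._ik(t.xy)
        u = self._Kinv @ (theta - self._rest_theta)
        p = np.full(N_DRIVES, self.baseline)
        floor = 0.1 * self.baseline
        for ch, (iago, iant) in enumerate(((0, 1), (2, 3))):
            v = u[ch]
            if v < 0:
                iago, iant = iant, iago
                v = -v
            # balanced reciprocal activation about the co-contraction
            # baseline; for large excursions the antagonist saturates at a
            # small floor and the agonist carries the remainder
            ant = max(self.baseline - v / 2, floor)
            p[iago], p[iant] = ant + v, ant
        return p

    def corrected_program(self, p: np.ndarray, W: np.ndarray | None):
        """Apply ``(I + W) p`` and rectify negative drives at zero.

        Returns ``(p_cor, rectified)`` where `rectified` flags any clipping.
        """
        p = np.asarray(p, dtype=float)
        if p.shape != (N_DRIVES,):
            raise ValueError(f"motor program must have {N_DRIVES} components")
        if W is None:
            return p, False
        p_cor = p + np.asarray(W, dtype=float) @ p
        rectified = bool(np.any(p_cor < 0))
        if rectified:
            p_cor = np.maximum(p_cor, 0.0)
        return p_cor, rectified

    def forward(self, p: np.ndarray, W: np.ndarray | None = None) -> np.ndarray:
        """Movement endpoint F(p, W) in metres (deterministic)."""
        p_cor, _ = self.corrected_program(p, W)
        theta = self._rest_theta + self._K @ (CHANNEL_MATRIX @ p_cor)
        return self._fk(theta)

    def forward_flagged(self, p, W=None):
        p_cor, rectified = self.corrected_program(p, W)
        theta = self._rest_theta + self._K @ (CHANNEL_MATRIX @ p_cor)
        return self._fk(theta), rectified

    def jacobian(self, p: np.ndarray, W: np.ndarray | None = None) -> np.ndarray:
        """Endpoint derivatives dF_k/dW_ij as a (6, 6, 2) tensor.

        F depends on W only through the corrected program, so the tensor is
        the outer product of the endpoint sensitivity to drive i and the
        program component j (zeroed where rectification clamps a drive).
        """
        p = np.asarray(p, dtype=float)
        p_cor, _ = self.corrected_program(p, W)
        theta = self._rest_theta + self._K @ (CHANNEL_MATRIX @ p_cor)
        B = self._fk_jacobian(theta) @ self._K @ CHANNEL_MATRIX  # (2, 6)
        active = (p_cor > 0).astype(float)
        jac = np.einsum("ki,i,j->ijk", B, active, p)
        if not np.all(np.isfinite(jac)):
            raise FloatingPointError("non-finite endpoint Jacobian")
        return jac

    def error_gain(self, p, W=None) -> np.ndarray:
        """2x2 matrix M with dF = -lambda * M e for a gradient step on error e."""
        jac = self.jacobian(p, W)
        return np.einsum("ijk,ijl->kl", jac, jac)

    def to_dict(self) -> dict:
        return {
            "l1": self.l1,
            "l2": self.l2,
            "shoulder": [float(x) for x in self.shoulder],
            "gain_scale": self.gain_scale,
            "gain_aniso": self.gain_aniso,
            "baseline": self.baseline,
            "ref_angle": self.ref_angle,
            "ref_radius": self.ref_radius,
            "elbow_sign": self.elbow_sign,
        }


class LinearArmSurrogate:
    """Linear forward map F(p, W) = M (I + W) p used as an analytic oracle.

    Exposes the same interface as :class:`PlanarArmSurrogate`; its Jacobian
    has the closed form dF_k/dW_ij = M[k, i] * p[j].
    """

    def __init__(self, M: np.ndarray, baseline: float = 1.0):
        self.M = np.asarray(M, dtype=float)
        self.baseline = baseline
        self.n_drives = self.M.shape[1]

    def solve_inverse(self, target) -> np.ndarray:
        t = _as_target(target)
        p, *_ = np.linalg.lstsq(self.M, t.xy, rcond=None)
        p = p + self.baseline
        if np.linalg.norm(self.M @ p - t.xy - self.M @ np.full_like(p, self.baseline)) > 1e-8:
            raise WorkspaceError("target outside the range of the linear map")
        return p

    def corrected_program(self, p, W):
        p = np.asarray(p, dtype=float)
        if W is None:
            return p, False
        return p + np.asarray(W) @ p, False

    def forward(self, p, W=None):
        p_cor, _ = self.corrected_program(p, W)
        return self.M @ p_cor

    def forward_flagged(self, p, W=None):
        return self.forward(p, W), False

    def jacobian(self, p, W=None):
        p = np.asarray(p, dtype=float)
        return np.einsum("ki,j->ijk", self.M, p)

    def error_gain(self, p, W=None):
        jac = self.jacobian(p, W)
        return np.einsum("ijk,ijl->kl", jac, jac)


def default_arm(overrides: dict | None = None) -> PlanarArmSurrogate:
    """Construct the surrogate from the packaged, versioned parameter file."""
    text = resources.files("reachadapt.data").joinpath("arm_default.yaml").read_text()
    params = yaml.safe_load(text)
    params.pop("version", None)
    if overrides:
        params.update(overrides)
    return PlanarArmSurrogate(**params)
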