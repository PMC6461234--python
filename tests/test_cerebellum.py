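"""Correction-matrix dynamics: gradient step, degradation, and their balance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reachadapt.cerebellum import CorrectionState, apply_correction, cb_update, skip_update


def scalar_jac(c, p=1.0):
    """dF/dW tensor of the one-dimensional linear system F = c (1 + w) p."""
    return np.array(c * p).reshape(1, 1, 1)


class TestApplyCorrection:
    @pytest.mark.parametrize(
        "W, expected",
        [
            (np.zeros((6, 6)), np.ones(6)),
            (-np.eye(6), np.zeros(6)),
            (0.1 * np.eye(6), np.full(6, 1.1)),
        ],
    )
    def test_linear_transform(self, W, expected):
        state = CorrectionState(W=W)
        assert np.allclose(apply_correction(np.ones(6), state), expected)


class TestUpdateRule:
    def test_zero_error_zero_decay_leaves_weights(self, linear_arm):
        p = np.ones(6)
        state = CorrectionState(W=np.full((6, 6), 0.3), lam=1.0, gamma=0.0)
        new = cb_update(state, p, np.zeros(2), linear_arm.jacobian(p), linear_arm)
        assert np.allclose(new.W, state.W)

    def test_zero_rate_is_pure_degradation(self, linear_arm):
        p = np.ones(6)
        state = CorrectionState(W=np.full((6, 6), 0.5), lam=0.0, gamma=0.04)
        new = cb_update(state, p, np.array([0.1, -0.2]), linear_arm.jacobian(p), linear_arm)
        assert np.allclose(new.W, 0.96 * state.W)

    def test_nonfinite_result_raises(self):
        state = CorrectionState(W=np.zeros((1, 1)), lam=1.0)
        with pytest.raises(FloatingPointError):
            cb_update(state, np.ones(1), np.array([np.inf]), scalar_jac(1.0))

    def test_scalar_system_reaches_learning_forgetting_balance(self):
        # independent oracle: iterate the scalar recursion by hand
        c, lam, gamma, x0, p = 2.0, 0.1, 0.02, 1.0, 1.0
        w = 0.0
        for _ in range(2000):
            e = c * (1 + w) * p - x0
            w = w - lam * c * p * e - gamma * w
        expected_asymptote = gamma * x0 / (lam * (c * p) ** 2 + gamma)
        assert abs(c * (1 + w) - x0 - 0.0) == pytest.approx(expected_asymptote, rel=1e-6)

        # the module must reproduce the same fixed point
        state = CorrectionState(W=np.zeros((1, 1)), lam=lam, gamma=gamma)
        for _ in range(2000):
            e = np.array([c * (1 + state.W[0, 0]) * p - x0])
            state = cb_update(state, np.array([p]), e, scalar_jac(c, p))
        final_error = c * (1 + state.W[0, 0]) * p - x0
        assert final_error == pytest.approx(expected_asymptote, rel=1e-6)

    def test_asymptote_grows_with_gamma_and_shrinks_with_lambda(self):
        def asymptote(lam, gamma):
            c, x0 = 2.0, 1.0
            state = CorrectionState(W=np.zeros((1, 1)), lam=lam, gamma=gamma)
            for _ in range(3000):
                e = np.array([c * (1 + state.W[0, 0]) - x0])
                state = cb_update(state, np.ones(1), e, scalar_jac(c))
            return abs(c * (1 + state.W[0, 0]) - x0)

        assert asymptote(0.1, 0.08) > asymptote(0.1, 0.02)
        assert asymptote(0.2, 0.02) < asymptote(0.05, 0.02)

    def test_prediction_tracks_internal_model(self, arm, solved_90):
        state = CorrectionState(W=np.zeros((6, 6)), lam=1.0, gamma=0.0)
        e = np.array([0.03, -0.01])
        jac = arm.jacobian(solved_90, state.W)
        new = cb_update(state, solved_90, e, jac, arm)
        expected = e + arm.forward(solved_90, new.W) - arm.forward(solved_90, state.W)
        assert np.allclose(new.e_exp, expected)


class TestSkip:
    def test_skip_is_identity(self):
        state = CorrectionState(W=np.full((6, 6), 0.2), lam=1.5, gamma=0.04,
                                e_exp=np.array([0.01, 0.0]))
        new = skip_update(state)
        assert np.array_equal(new.W, state.W)
        assert new.lam == state.lam
        assert np.array_equal(new.e_exp, state.e_exp)

    def test_interleaved_skips_freeze_norm(self, linear_arm):
        p = np.ones(6)
        e = np.array([0.05, 0.02])
        full = CorrectionState(W=np.zeros((6, 6)), lam=0.5, gamma=0.04)
        mixed = CorrectionState(W=np.zeros((6, 6)), lam=0.5, gamma=0.04)
        jac = linear_arm.jacobian(p)
        norms_full, norms_mixed = [], []
        for k in range(10):
            full = cb_update(full, p, e, jac, linear_arm)
            norms_full.append(np.linalg.norm(full.W))
            if k % 2 == 0:
                mixed = cb_update(mixed, p, e, jac, linear_arm)
            else:
                before = np.linalg.norm(mixed.W)
                mixed = skip_update(mixed)
                assert np.linalg.norm(mixed.W) == before
            norms_mixed.append(np.linalg.norm(mixed.W))
        assert norms_mixed[-1] < norms_full[-1]


def test_state_round_trips_through_json():
    state = CorrectionState(W=np.arange(36.0).reshape(6, 6), lam=1.7, gamma=0.04,
                            e_exp=np.array([0.01, -0.02]))
    again = CorrectionState.from_json(state.to_json())
    assert np.array_equal(again.W, state.W)
    assert again.lam == state.lam and again.gamma == state.gamma
    assert np.array_equal(again.e_exp, state.e_exp)
    bare = CorrectionState.from_json(CorrectionState().to_json())
    assert bare.e_exp is None


@settings(deadline=None, max_examples=20)
@given(gamma=st.floats(0.01, 0.3), n=st.integers(1, 30))
def test_pure_decay_is_geometric(gamma, n):
    rng = np.random.default_rng(0)
    W0 = rng.normal(0, 1, (6, 6))
    state = CorrectionState(W=W0.copy(), lam=0.0, gamma=gamma)
    p = np.ones(6)
    jac = np.zeros((6, 6, 2))
    for _ in range(n):
        state = cb_update(state, p, np.zeros(2), jac)
    assert np.linalg.norm(state.W) == pytest.approx(
        (1 - gamma) ** n * np.linalg.norm(W0), rel=1e-9
    )


class TestRotatedErrorOracle:
    """Feeding a rotated error makes the per-trial map a complex spiral.

    For the two-dimensional isotropic linear system the linearized map has
    eigenvalues (1 - gamma) - lam*c_eff*exp(+-i theta); the simulated
    recursion must converge exactly when the spectral radius is below one.
    """

    @pytest.mark.parametrize("theta_deg", [0, 30, 60, 80, 100, 130])
    def test_convergence_matches_eigenvalue_prediction(self, theta_deg):
        c, lam, gamma = 1.0, 0.3, 0.0
        M = np.zeros((2, 6))
        M[0, 0] = M[1, 1] = c
        from reachadapt.arm import LinearArmSurrogate

        toy = LinearArmSurrogate(M)
        p = np.zeros(6)
        p[:2] = 1.0
        c_eff = c**2 * float(p @ p)  # error gain of the isotropic toy
        th = np.deg2rad(theta_deg)
        rho = abs((1 - gamma) - lam * c_eff * np.exp(1j * th))
        target = np.array([0.3, 0.1])
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        state = CorrectionState(W=np.zeros((6, 6)), lam=lam, gamma=gamma)
        errs = []
        for _ in range(120):
            e_true = toy.forward(p, state.W) - target
            errs.append(np.linalg.norm(e_true))
            state = cb_update(state, p, R @ e_true, toy.jacobian(p, state.W), toy)
        if rho < 0.97:
            assert errs[-1] < 1e-3 * errs[0]
        elif rho > 1.03:
            assert errs[-1] > errs[0]
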