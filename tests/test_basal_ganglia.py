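"""Action selection, reinforcement plasticity, habits and lesion models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reachadapt.basal_ganglia import (
    ActionPool,
    BGParams,
    BGState,
    LesionSpec,
    bg_learn,
    bg_select,
    compute_rpe,
    habit_update,
    init_bg_state,
)

PARAMS = BGParams()


@pytest.fixture(scope="module")
def pool(arm):
    return ActionPool.build(arm, 20.0, 155.0, 100)


def fresh_state(pool, habit=0.3, expectation=3.0, seed=1, cues=None):
    cues = cues or {"C": 90.0}
    return init_bg_state(cues, pool, {c: habit for c in cues}, expectation, PARAMS,
                         np.random.default_rng(seed))


class TestSelection:
    def test_strong_habit_dominates(self, pool):
        st_ = fresh_state(pool, habit=0.55)
        mix = bg_select("C", st_, PARAMS)
        assert mix[pool.nearest(90.0)] > 0.9

    def test_symmetric_weights_share_selection(self, pool):
        st_ = fresh_state(pool, habit=0.0)
        st_.w_d1["C"][:] = 0.0
        st_.w_habit["C"][[10, 40]] = 0.4
        mix = bg_select("C", st_, PARAMS)
        assert mix[10] == pytest.approx(mix[40]) == pytest.approx(0.5)

    def test_silenced_indirect_pathway_still_selects(self, pool):
        st_ = fresh_state(pool)
        mix = bg_select("C", st_, PARAMS, LesionSpec(hd_scale=0.0))
        assert mix.sum() == pytest.approx(1.0)
        assert np.all(mix >= 0)

    def test_unknown_cue_rejected(self, pool):
        with pytest.raises(KeyError):
            bg_select("nope", fresh_state(pool), PARAMS)

    def test_attractor_matches_ode_integration(self, pool):
        st_ = fresh_state(pool, habit=0.3, seed=9)
        for _ in range(6):
            fast = bg_select("C", st_, PARAMS, method="attractor")
            slow = bg_select("C", st_, PARAMS, method="ode")
            assert np.allclose(fast, slow, atol=1e-6)
            bg_learn(-3.0, "C", fast, st_, PARAMS)

    def test_selection_deterministic_in_state(self, pool):
        st_ = fresh_state(pool, seed=3)
        assert np.array_equal(bg_select("C", st_, PARAMS), bg_select("C", st_, PARAMS))


class TestRPE:
    @pytest.mark.parametrize("expectation, reward, rpe", [(3.0, 3.0, 0.0), (0.0, 0.0, 0.0), (3.0, 0.0, -3.0)])
    def test_prediction_error(self, pool, expectation, reward, rpe):
        st_ = fresh_state(pool, expectation=expectation)
        assert compute_rpe(reward, "C", st_, PARAMS) == pytest.approx(rpe)

    def test_expectation_converges_geometrically(self, pool):
        st_ = fresh_state(pool, expectation=0.0)
        gaps = []
        for _ in range(30):
            compute_rpe(2.0, "C", st_, PARAMS)
            gaps.append(abs(2.0 - st_.reward_expectation["C"]))
        ratios = np.array(gaps[1:]) / np.array(gaps[:-1])
        assert np.allclose(ratios, 1 - PARAMS.eta_exp, rtol=1e-9)

    def test_unknown_cue_rejected(self, pool):
        with pytest.raises(KeyError):
            compute_rpe(1.0, "nope", fresh_state(pool), PARAMS)

    def test_nonfinite_reward_rejected(self, pool):
        with pytest.raises(ValueError):
            compute_rpe(np.nan, "C", fresh_state(pool), PARAMS)


class TestPlasticity:
    def test_zero_dopamine_only_decays(self, pool):
        st_ = fresh_state(pool)
        st_.w_d1["C"][:] = 0.5
        st_.w_d2["C"][:] = 0.5
        mix = bg_select("C", st_, PARAMS)
        bg_learn(0.0, "C", mix, st_, PARAMS)
        assert np.allclose(st_.w_d1["C"], 0.5 * (1 - PARAMS.delta_bg))
        assert np.allclose(st_.w_d2["C"], 0.5 * (1 - PARAMS.delta_bg))

    def test_positive_dopamine_reinforces_winner(self, pool):
        st_ = fresh_state(pool)
        st_.w_d2["C"][:] = 0.2
        mix = bg_select("C", st_, PARAMS)
        win = int(np.argmax(mix))
        d1_before, d2_before = st_.w_d1["C"][win], st_.w_d2["C"][win]
        bg_learn(2.0, "C", mix, st_, PARAMS)
        assert st_.w_d1["C"][win] > d1_before
        assert st_.w_d2["C"][win] < d2_before
        assert np.all(st_.w_d2["C"] >= 0)

    def test_sustained_punishment_triggers_exploration(self, pool):
        st_ = fresh_state(pool, habit=0.3, seed=9)
        visited = []
        for _ in range(20):
            mix = bg_select("C", st_, PARAMS)
            visited.append(int(np.argmax(mix)))
            bg_learn(-3.0, "C", mix, st_, PARAMS)
        # habitual action selected first, then suppressed in favour of a walk
        assert visited[0] == pool.nearest(90.0)
        assert len(set(visited)) > 5
        # across-trial selection entropy rises once punishment releases the walk
        first, second = visited[:10], visited[10:]
        def entropy(xs):
            _, counts = np.unique(xs, return_counts=True)
            f = counts / len(xs)
            return -np.sum(f * np.log(f))
        assert entropy(second) > entropy(first)

    def test_pd_lesion_slows_reacquisition(self, pool):
        def trials_to_flip(lesion):
            st_ = fresh_state(pool, habit=0.3, seed=9)
            habit_action = pool.nearest(90.0)
            for t in range(1, 500):
                mix = bg_select("C", st_, PARAMS, lesion)
                if int(np.argmax(mix)) != habit_action:
                    return t
                bg_learn(-3.0, "C", mix, st_, PARAMS, lesion)
            return 500

        assert trials_to_flip(LesionSpec(pd_scale=0.1)) > trials_to_flip(LesionSpec())

    def test_hd_lesion_blocks_suppression(self, pool):
        st_ = fresh_state(pool, habit=0.3, seed=9)
        lesion = LesionSpec(hd_scale=0.1)
        habit_action = pool.nearest(90.0)
        for _ in range(25):
            mix = bg_select("C", st_, PARAMS, lesion)
            bg_learn(-3.0, "C", mix, st_, PARAMS, lesion)
        assert int(np.argmax(bg_select("C", st_, PARAMS, lesion))) == habit_action


class TestHabits:
    def test_repetition_potentiates_only_selected(self, pool):
        params = BGParams(eta_hab=1e-3)
        st_ = fresh_state(pool, habit=0.3)
        win = pool.nearest(90.0)
        before = st_.w_habit["C"].copy()
        for _ in range(200):
            mix = bg_select("C", st_, params)
            habit_update("C", mix, st_, params)
        assert st_.w_habit["C"][win] > before[win]
        others = np.arange(100) != win
        assert np.allclose(st_.w_habit["C"][others], before[others])

    def test_zero_rate_freezes_habits(self, pool):
        params = BGParams(eta_hab=0.0)
        st_ = fresh_state(pool)
        before = st_.w_habit["C"].copy()
        mix = bg_select("C", st_, params)
        habit_update("C", mix, st_, params)
        assert np.array_equal(st_.w_habit["C"], before)

    def test_empty_mixture_no_change(self, pool):
        params = BGParams(eta_hab=1e-3)
        st_ = fresh_state(pool)
        bg_select("C", st_, params)
        before = st_.w_habit["C"].copy()
        habit_update("C", np.zeros(100), st_, params)
        assert np.array_equal(st_.w_habit["C"], before)


@settings(deadline=None, max_examples=25)
@given(seed=st.integers(0, 10_000), habit=st.floats(0.0, 0.8), d2=st.floats(0.0, 1.5))
def test_mixture_is_a_distribution(seed, habit, d2):
    from reachadapt.arm import default_arm

    pool = ActionPool.build(default_arm(), 40.0, 110.0, 30)
    st_ = init_bg_state({"C": 90.0}, pool, {"C": habit}, 0.0, PARAMS,
                        np.random.default_rng(seed))
    st_.w_d2["C"][::3] = d2
    mix = bg_select("C", st_, PARAMS)
    assert np.all(mix >= 0)
    assert mix.sum() == pytest.approx(1.0)


def test_state_round_trips_through_json(pool):
    st_ = fresh_state(pool)
    again = BGState.from_json(st_.to_json())
    assert np.array_equal(again.w_d1["C"], st_.w_d1["C"])
    assert again.reward_expectation == st_.reward_expectation
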