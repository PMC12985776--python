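"""Reward, greedy selection, actor-critic, and the closed loop."""

import numpy as np
import pytest

from inie.controller import (
    Action,
    ActionSpace,
    ControllerState,
    LoopConfig,
    PolicyModel,
    RewardConfig,
    action_features,
    actor_critic_update,
    greedy_select,
    reward,
    run_closed_loop,
)
from inie.phantom import generate_vessel_tree, rasterize_phantom


# ---------------------------------------------------------------------------
# reward
# ---------------------------------------------------------------------------


def test_reward_zero_when_all_terms_zero():
    cfg = RewardConfig(1.0, 1.0, 1.0)
    x = np.ones((4, 4))
    assert reward(0.0, 0.0, x, x, cfg) == 0.0


def test_reward_single_term():
    cfg = RewardConfig(alpha=1.0, beta=0.0, gamma_smooth=0.0)
    x = np.ones((2, 2))
    assert reward(0.3, 5.0, x, x, cfg) == pytest.approx(-0.3)


def test_reward_worked_example():
    cfg = RewardConfig(alpha=1.0, beta=2.0, gamma_smooth=1.0)
    x_prev = np.zeros((1, 10))
    x_t = np.zeros((1, 10))
    x_t[0, 0] = np.sqrt(0.1)  # ||dx||^2 = 0.1
    assert reward(0.5, 0.25, x_t, x_prev, cfg) == pytest.approx(-1.1)


def test_reward_linear_in_weights():
    rng = np.random.default_rng(0)
    x1, x2 = rng.random((2, 8, 8))
    base = RewardConfig(0.7, 0.3, 0.2)
    scaled = RewardConfig(2.1, 0.9, 0.6)
    r1 = reward(0.4, 0.6, x1, x2, base)
    r3 = reward(0.4, 0.6, x1, x2, scaled)
    assert r3 == pytest.approx(3 * r1)


# ---------------------------------------------------------------------------
# action space and greedy selection
# ---------------------------------------------------------------------------


def _state():
    return ControllerState(np.zeros(8), 0)


def test_action_space_rejects_visited_overlap():
    with pytest.raises(ValueError):
        ActionSpace([(1, 2)], [], visited_lines={2})


def test_greedy_single_candidate():
    space = ActionSpace([(0, 1, 2)], [])
    a = greedy_select(_state(), space, lambda a: 1.0)
    assert a.indices == (0, 1, 2)


def test_greedy_picks_lower_expected_uncertainty():
    space = ActionSpace([(0, 1), (2, 3)], [])
    scores = {(0, 1): 0.9, (2, 3): 0.2}
    a = greedy_select(_state(), space, lambda a: scores[a.indices])
    assert a.indices == (2, 3)


def test_greedy_tie_break_by_order():
    space = ActionSpace([(0, 1), (2, 3)], [])
    a = greedy_select(_state(), space, lambda a: 0.5)
    assert a.indices == (0, 1)


def test_greedy_empty_candidates_error():
    with pytest.raises(ValueError):
        greedy_select(_state(), ActionSpace([], []), lambda a: 0.0)


# ---------------------------------------------------------------------------
# actor-critic
# ---------------------------------------------------------------------------


def test_log_prob_gradient_matches_finite_differences():
    pol = PolicyModel(hidden=8, seed=1)
    rng = np.random.default_rng(0)
    s = rng.random(8)
    feats = rng.random((3, 4))
    logp, _, grad = pol.log_prob_grad(s, feats, 1)
    h = 1e-6
    for name in ("W1", "b1", "W2"):
        W = getattr(pol, name)
        flat = W.reshape(-1)
        gflat = np.asarray(grad[name]).reshape(-1)
        for i in range(0, flat.size, max(1, flat.size // 7)):
            old = flat[i]
            flat[i] = old + h
            lp2, _, _ = pol.log_prob_grad(s, feats, 1)
            flat[i] = old
            fd = (lp2 - logp) / h
            assert fd == pytest.approx(gflat[i], rel=1e-4, abs=1e-7)


def test_policy_outputs_proper_distribution():
    pol = PolicyModel(seed=2)
    rng = np.random.default_rng(1)
    p = pol.probabilities(rng.random(8), rng.random((5, 4)))
    assert p.shape == (5,)
    assert np.all(p > 0)
    assert p.sum() == pytest.approx(1.0)


def test_zero_advantage_leaves_actor_unchanged():
    pol = PolicyModel(seed=3)
    s = np.full(8, 0.3)
    feats = np.array([[1.0, 0.0, 0.0, 0.0]])
    v = pol.value(s)
    before = pol.W1.copy()
    actor_critic_update([(s, feats, 0, v, None)], pol,
                        lr_actor=0.5, lr_critic=0.0, entropy_bonus=0.0)
    np.testing.assert_array_equal(pol.W1, before)


def test_two_armed_bandit_converges():
    """With deterministic +1/-1 rewards the policy puts >= 0.9 probability
    on the better arm after 500 updates."""
    pol = PolicyModel(hidden=16, seed=3)
    s = np.zeros(8)
    feats = np.array([[1.0, 0.0, 0.2, 0.1], [0.0, 1.0, 0.0, 0.1]])
    rng = np.random.default_rng(7)
    for _ in range(500):
        a = pol.sample(s, feats, rng)
        r = 1.0 if a == 0 else -1.0
        actor_critic_update([(s, feats, a, r, None)], pol,
                            lr_actor=0.05, lr_critic=0.05)
    assert pol.probabilities(s, feats)[0] > 0.9


def test_critic_converges_on_constant_reward_mdp():
    """TD learning drives V toward R / (1 - gamma) on a one-state MDP."""
    pol = PolicyModel(hidden=16, discount_factor=0.9, seed=5)
    s = np.full(8, 0.3)
    feats = np.array([[1.0, 0.0, 0.0, 0.0]])
    for _ in range(4000):
        actor_critic_update([(s, feats, 0, 1.0, s)], pol,
                            lr_actor=0.0, lr_critic=0.02)
    assert pol.value(s) == pytest.approx(10.0, rel=0.05)


def test_nan_reward_raises():
    pol = PolicyModel(seed=6)
    s = np.zeros(8)
    feats = np.array([[1.0, 0.0, 0.0, 0.0]])
    with pytest.raises(FloatingPointError):
        actor_critic_update([(s, feats, 0, np.nan, None)], pol)


def test_action_features_shapes():
    mr = action_features(Action("mr", (10, 11, 12)), 128, 60)
    pet = action_features(Action("pet", (0, 1)), 128, 60)
    assert mr.shape == pet.shape == (4,)
    assert mr[0] == 1.0 and pet[1] == 1.0


# ---------------------------------------------------------------------------
# closed loop (small, fast configurations)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_phantom():
    return rasterize_phantom(generate_vessel_tree(2, n_loops=1), 128)


def test_degenerate_budget_single_step(small_phantom):
    trace = run_closed_loop(small_phantom, "greedy", budget=0.105, seed=0)
    assert len(trace.steps) == 1
    assert "sampling_reduction_pct" in trace.final_metrics


def test_infinite_stop_threshold_stops_immediately(small_phantom):
    trace = run_closed_loop(small_phantom, "greedy",
                            stop_threshold=np.inf, seed=0)
    assert len(trace.steps) == 1


def test_closed_loop_never_reacquires(small_phantom):
    trace = run_closed_loop(small_phantom, "greedy", seed=1)
    seen_lines, seen_angles = set(), set()
    for s in trace.steps:
        if s.action is None:
            continue
        idx = set(s.action.indices)
        if s.action.kind == "mr":
            assert not (idx & seen_lines)
            seen_lines |= idx
        else:
            assert not (idx & seen_angles)
            seen_angles |= idx


def test_closed_loop_fraction_nondecreasing_and_reproducible(small_phantom):
    t1 = run_closed_loop(small_phantom, "greedy", seed=5)
    t2 = run_closed_loop(small_phantom, "greedy", seed=5)
    fr = t1.sampling_fractions
    assert np.all(np.diff(fr) >= 0)
    assert t1.final_metrics == t2.final_metrics
    assert [s.reward for s in t1.steps] == [s.reward for s in t2.steps]


def test_invalid_arguments():
    ph = rasterize_phantom(generate_vessel_tree(0, n_loops=0), 128)
    with pytest.raises(ValueError):
        run_closed_loop(ph, "greedy", budget=0.0)
    with pytest.raises(ValueError):
        run_closed_loop(ph, "nope")
    with pytest.raises(ValueError):
        run_closed_loop(ph, "policy")  # policy object required
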