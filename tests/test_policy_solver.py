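import itertools
import math

import numpy as np
import pytest

from patchforage.foraging_model import (
    Action,
    ForagingConfig,
    P3,
    P4,
    PatchState,
    discounted_reward,
    transition_distribution,
)
from patchforage.policy_solver import (
    PolicyTable,
    belief_posterior,
    consume_value,
    enumerate_states,
    evaluate_global_rate,
    extract_thresholds,
    get_state_space,
    inspect_value,
    optimize_policy,
    solve_dp,
)
from patchforage.task_simulation import environment_variants, simulate_patch


# ---------------------------------------------------------------------------
# independent oracles


def eval_policy_recursive(cfg, env, choice):
    """Expected (discounted reward, patch time) for one deterministic
    per-state plan, by direct recursion over the outcome tree.

    ``choice`` maps each state to 'inspect' or to an integer consume count.
    Independent of the DP solver: uses only the transition primitive and the
    discounting formula.
    """

    def go(state):
        c = choice[state]
        if c == "inspect":
            r = t = 0.0
            for s2, p in transition_distribution(cfg, state):
                rr, tt = go(s2)
                r += p * rr
                t += p * tt
            return r, t
        n = state.n_inspected
        rew = sum(
            discounted_reward(state.revealed[j - 1],
                              n * cfg.t_inspect + j * cfg.t_consume, cfg.k)
            for j in range(1, c + 1))
        return rew, n * cfg.t_inspect + c * cfg.t_consume + cfg.t_travel

    return go(PatchState(env))


def exhaustive_best_rate(cfg):
    """Max long-run reward rate over every deterministic policy, by brute
    force: enumerate all per-state plans per environment, then maximize the
    combined reward/time ratio over environment combinations."""
    per_env = []
    for env in range(1, cfg.n_envs + 1):
        states = [s for s in enumerate_states(cfg) if s.env == env]
        options = []
        for s in states:
            opts = list(range(s.n_inspected + 1))
            if s.n_inspected < cfg.n_objects:
                opts.append("inspect")
            options.append(opts)
        outcomes = []
        for combo in itertools.product(*options):
            choice = dict(zip(states, combo))
            outcomes.append(eval_policy_recursive(cfg, env, choice))
        per_env.append(np.array(outcomes))
    best = 0.0
    rews = [a[:, 0] for a in per_env]
    times = [a[:, 1] for a in per_env]
    for combo in itertools.product(*[range(len(a)) for a in per_env]):
        r = sum(rews[e][i] for e, i in enumerate(combo))
        t = sum(times[e][i] for e, i in enumerate(combo))
        best = max(best, r / t)
    return best


# ---------------------------------------------------------------------------
# state enumeration


class TestEnumerateStates:
    def test_default_state_count_is_25025(self, default_config):
        assert len(enumerate_states(default_config)) == 25025

    def test_count_formula(self, default_config):
        n_sizes = 6
        expected = 5 * sum(math.comb(n + n_sizes - 1, n_sizes - 1)
                           for n in range(10))
        assert len(enumerate_states(default_config)) == expected == 25025

    def test_single_env_no_objects(self):
        cfg = ForagingConfig(n_envs=1, n_objects=0, p_max=0.5, tau=0.0)
        assert len(enumerate_states(cfg)) == 1

    def test_two_envs_one_object_binary_sizes(self):
        point = ((1.0, 0.0, 0.0, 0.0, 0.0),) * 2
        cfg = ForagingConfig(n_envs=2, n_objects=1, p_max=(0.2, 0.8),
                             tau=(0.0, 0.0), size_dist=point)
        states = enumerate_states(cfg)
        assert len(states) == 6  # 2 envs x {(), (0,), (1,)}
        assert len(set(states)) == 6

    def test_canonical_order_is_deterministic(self, default_config):
        a = enumerate_states(default_config)
        b = enumerate_states(default_config)
        assert a == b


# ---------------------------------------------------------------------------
# per-state values


class TestConsumeValue:
    def test_fresh_patch_no_opportunity_cost(self, default_config):
        assert consume_value(default_config, PatchState(1), 0.0) == (0.0, 0)

    def test_hand_evaluated_single_reward(self, default_config):
        v, i = consume_value(default_config, PatchState(1, (3,)), 0.0)
        assert i == 1
        assert v == pytest.approx(3 * 0.725 ** 1.75 / 23.75, rel=1e-9)
        assert v == pytest.approx(0.0720, abs=2e-4)

    @pytest.mark.parametrize("r_global", [0.0, 0.05, 0.2])
    def test_zero_reward_never_consumed(self, default_config, r_global):
        _, i = consume_value(default_config, PatchState(1, (0,)), r_global)
        assert i == 0

    def test_unsorted_revealed_rejected(self, default_config):
        state = PatchState.__new__(PatchState)
        object.__setattr__(state, "env", 1)
        object.__setattr__(state, "revealed", (1, 3))
        with pytest.raises(ValueError):
            consume_value(default_config, state, 0.0)


class TestInspectValue:
    def test_constant_successor_values(self, default_config):
        state = PatchState(2, (3,))
        succ = {s: 0.42 for s, _ in
                transition_distribution(default_config, state)}
        assert inspect_value(default_config, state, succ) == \
            pytest.approx(0.42)

    def test_deterministic_transition_when_rewardless(self):
        cfg = ForagingConfig(p_max=0.0)
        state = PatchState(1)
        succ_state = state.with_outcome(0)
        assert inspect_value(cfg, state, {succ_state: 0.7}) == \
            pytest.approx(0.7)

    def test_matches_hand_expectation_tree(self, toy_config):
        # one-step lookahead from the fresh patch in env 2 (p1 = 0.8),
        # terminal values chosen arbitrarily
        state = PatchState(2)
        vals = {PatchState(2, (0,)): 0.1, PatchState(2, (1,)): 0.9}
        expected = 0.2 * 0.1 + 0.8 * 0.9
        assert inspect_value(toy_config, state, vals) == \
            pytest.approx(expected)

    def test_missing_successor_raises(self, default_config):
        with pytest.raises(KeyError):
            inspect_value(default_config, PatchState(1), {})


# ---------------------------------------------------------------------------
# dynamic programming and the fixed point


class TestSolveDP:
    def test_terminal_states_always_consume(self, solved_default,
                                            default_config):
        policy = solved_default.policy
        full = PatchState(3, (5, 4, 3, 2, 1, 0, 0, 0, 0))
        assert policy.action(full) is Action.CONSUME_AND_LEAVE

    def test_value_is_max_of_action_values(self, solved_default):
        vt = solved_default.values
        non_terminal = ~np.isnan(vt.v_inspect)
        assert np.allclose(
            vt.v[non_terminal],
            np.maximum(vt.v_inspect[non_terminal],
                       vt.v_consume[non_terminal]))

    def test_value_monotone_in_revealed_size(self, solved_default,
                                             default_config):
        vt = solved_default.values
        for base in [(2, 0, 0), (4, 2, 1), (1, 1, 0, 0, 0)]:
            for env in (1, 3, 5):
                grown = (3,) + base[1:] if base[0] == 2 else \
                    (base[0] + 1,) + base[1:]
                lo = vt.lookup(PatchState(env, tuple(sorted(base,
                                                            reverse=True))))
                hi = vt.lookup(PatchState(env, tuple(sorted(grown,
                                                            reverse=True))))
                assert hi["v"] >= lo["v"] - 1e-12


class TestEvaluateGlobalRate:
    def test_consume_immediately_policy_earns_nothing(self, default_config):
        space = get_state_space(default_config)
        policy = PolicyTable(space,
                             np.zeros(space.n_states, dtype=bool),
                             np.zeros(space.n_states, dtype=np.int64))
        assert evaluate_global_rate(default_config, policy) == 0.0

    def test_rewardless_world_rate_is_zero(self):
        cfg = ForagingConfig(p_max=0.0)
        res = optimize_policy(cfg)
        assert res.rate_history[0] == 0.0
        assert res.r_global == 0.0

    def test_matches_monte_carlo(self, toy_config):
        res = optimize_policy(toy_config, P4, max_iter=100)
        rng = np.random.default_rng(11)
        n = 20_000
        rews = np.empty(n)
        times = np.empty(n)
        for i in range(n):
            tr = simulate_patch(toy_config, res, rng)
            rews[i], times[i] = tr.reward_total, tr.duration
        rate_hat = rews.sum() / times.sum()
        # delta-method standard error of a ratio of means
        resid = rews - rate_hat * times
        se = resid.std(ddof=1) / math.sqrt(n) / times.mean()
        assert abs(rate_hat - res.r_global) < 3 * se


class TestOptimizePolicy:
    def test_converges_within_40_iterations(self, solved_default):
        assert solved_default.converged
        assert solved_default.iterations_used <= 40
        h = solved_default.rate_history
        assert abs(h[-1] - h[-2]) < 1e-6

    def test_fixed_point_self_consistency(self, solved_default,
                                          default_config):
        # mean fresh-patch value over environments equals the global rate
        vt = solved_default.values
        fresh = [vt.lookup(PatchState(e))["v"] for e in range(1, 6)]
        assert np.mean(fresh) == pytest.approx(solved_default.r_global,
                                               abs=1e-5)

    def test_information_ordering(self, solved_all_policies):
        r = {k: v.r_global for k, v in solved_all_policies.items()}
        assert r["P4"] >= r["P3"] - 1e-12
        assert r["P3"] >= r["P1"] - 1e-12
        assert r["P4"] >= r["P2"] - 1e-12

    def test_dp_matches_exhaustive_policy_enumeration(self, toy_config):
        res = optimize_policy(toy_config, P4, max_iter=100, tol=1e-12)
        assert res.r_global == pytest.approx(exhaustive_best_rate(toy_config),
                                             abs=1e-9)

    def test_dp_matches_oracle_on_second_toy(self):
        point = ((0.0, 0.0, 1.0, 0.0, 0.0),) * 2
        cfg = ForagingConfig(n_envs=2, n_objects=2, p_max=(0.5, 0.9),
                             tau=(1.2, 0.2), size_dist=point)
        res = optimize_policy(cfg, P4, max_iter=100, tol=1e-12)
        assert res.r_global == pytest.approx(exhaustive_best_rate(cfg),
                                             abs=1e-9)


class TestThresholds:
    def test_default_policy_is_threshold_separable(self, solved_default,
                                                   default_config):
        extract_thresholds(default_config, solved_default)  # must not raise

    def test_thresholds_non_increasing_in_inspections(self, solved_default,
                                                      default_config):
        thr = extract_thresholds(default_config, solved_default).threshold
        # the n=0 slice has a single (inspect-only) state, so its threshold
        # is one-sided; monotonicity is a claim about the populated slices
        assert np.all(np.diff(thr[:, 1:], axis=1) <= 1e-12)

    def test_thresholds_increase_with_environment_richness(
            self, solved_default, default_config):
        thr = extract_thresholds(default_config, solved_default).threshold
        assert np.all(np.diff(thr[:, 1:], axis=0) >= -1e-12)
        assert np.any(np.diff(thr[:, 1:], axis=0) > 1e-6)

    def test_null_model_thresholds_equal_across_environments(self):
        cfg = environment_variants("E")
        res = optimize_policy(cfg)
        thr = extract_thresholds(cfg, res).threshold
        assert np.allclose(thr, thr[0])


class TestBeliefPosterior:
    def test_uniform_prior_before_any_inspection(self, default_config):
        b = belief_posterior(default_config, 0, ())
        assert b.posterior == pytest.approx((0.2,) * 5)

    def test_single_reward_weights_by_p_max(self, default_config):
        b = belief_posterior(default_config, 1, (2,))
        assert np.allclose(b.posterior, (0.04, 0.12, 0.20, 0.28, 0.36))

    def test_single_blank_weights_by_complement(self, default_config):
        b = belief_posterior(default_config, 1, (0,))
        expected = np.array([0.9, 0.7, 0.5, 0.3, 0.1]) / 2.5
        assert np.allclose(b.posterior, expected)

    def test_impossible_evidence_raises(self):
        cfg = ForagingConfig(p_max=0.0)
        with pytest.raises(ValueError):
            belief_posterior(cfg, 1, (3,))

    def test_matches_forward_reach_probabilities(self, default_config):
        # the forward occupancy under always-inspect is an independent route
        # to the same likelihood
        space = get_state_space(default_config)
        for n, pos in [(2, 4), (3, 10), (4, 0)]:
            ms = space.multisets[n][pos]
            b = belief_posterior(default_config, n, ms)
            reach = space.reach[n][:, pos]
            assert np.allclose(b.posterior, reach / reach.sum())
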