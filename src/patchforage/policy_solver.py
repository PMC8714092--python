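"""Dynamic-programming solution of the object-inspection foraging MDP.

The state is ``(env, n_inspected, revealed)`` where ``revealed`` is the
non-increasing multiset of revealed reward sizes. Values are expressed as
reward rates over a fixed horizon ``T_max``:

* ``V(s, consume) = max_i [ sum_{j<=i} r_j (1-k)^(n t_ins + j t_con)
  + R_global (T_max - (n t_ins + i t_con + t_travel)) ] / T_max`` —
  consume the ``i`` biggest revealed rewards, travel, then earn the global
  rate for the remaining horizon;
* ``V(s, inspect) = E[V(s')]`` over the successor distribution of inspecting
  the next object.

The optimal policy is the fixed point of an iterative procedure: starting
from ``R_global = 0``, alternately solve the DP for the greedy policy at the
current rate and re-evaluate that policy's true long-run reward rate by
exact forward expectation, until the policy is stable and the rate change
falls below tolerance.

Information-restricted policies (a POMDP relaxation) are solved by the same
backward induction, except that all states sharing the observable features
share one action and one consumption count, chosen to maximize the
belief-weighted value. The belief over hidden components at a given
observable signature is exact: a uniform prior over environments times the
forward reach probability of each revealed multiset under inspection.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .foraging_model import (
    REWARD_SIZES,
    Action,
    ForagingConfig,
    ObservableSpec,
    P4,
    PatchState,
    object_reward_probability,
    transition_distribution,
)

__all__ = [
    "StateSpace",
    "ValueTable",
    "PolicyTable",
    "SolverResult",
    "ThresholdCurve",
    "BeliefState",
    "enumerate_states",
    "get_state_space",
    "consume_value",
    "inspect_value",
    "solve_dp",
    "evaluate_global_rate",
    "optimize_policy",
    "extract_thresholds",
    "belief_posterior",
]


class StateSpace:
    """Canonical enumeration of the patch MDP plus precomputed solver arrays.

    States are ordered by (n_inspected, env, revealed multiset), the multisets
    within one level enumerated lexicographically over descending reward
    sizes. Revealed-reward multisets only range over sizes that are actually
    producible under the config (``config.size_support``).
    """

    def __init__(self, config: ForagingConfig):
        self.config = config
        support = config.size_support  # descending, includes 0
        n_obj, n_envs = config.n_objects, config.n_envs
        t_ins, t_con = config.t_inspect, config.t_consume
        k, T_max = config.k, config.T_max

        # multisets per inspection level, as non-increasing tuples
        self.multisets: list[list[tuple[int, ...]]] = [
            list(combinations_with_replacement(support, n))
            for n in range(n_obj + 1)
        ]
        self._ms_index: list[dict[tuple[int, ...], int]] = [
            {ms: j for j, ms in enumerate(level)} for level in self.multisets
        ]
        self.level_sizes = [n_envs * len(lv) for lv in self.multisets]
        self.level_offsets = np.concatenate([[0], np.cumsum(self.level_sizes)])
        self.n_states = int(self.level_offsets[-1])

        # discounted cumulative consumption values A[n][j, i] and the
        # residual-horizon terms B[n][i]
        self.A: list[np.ndarray] = []
        self.B: list[np.ndarray] = []
        for n, level in enumerate(self.multisets):
            i = np.arange(n + 1)
            rewards = np.array(level, dtype=float)  # (m, n)
            disc = (1.0 - k) ** (n * t_ins + np.arange(1, n + 1) * t_con)
            cum = np.concatenate(
                [np.zeros((len(level), 1)),
                 np.cumsum(rewards * disc, axis=1)], axis=1)
            self.A.append(cum)  # (m, n+1)
            self.B.append(T_max - (n * t_ins + i * t_con + config.t_travel))

        # transition structure: outcome o inserted into the multiset.
        # succ_pos[n][j, o] is env-independent; outcome probabilities are
        # per (env, level).
        self.outcomes = support  # outcome values, descending (0 is last)
        n_out = len(support)
        self.succ_pos: list[np.ndarray] = []
        self.out_prob: list[np.ndarray] = []  # per level: (n_envs, n_out)
        size_q = {m: [config.size_dist[e][m - 1] for e in range(n_envs)]
                  for m in REWARD_SIZES}
        for n in range(n_obj):
            level = self.multisets[n]
            nxt = self._ms_index[n + 1]
            sp = np.empty((len(level), n_out), dtype=np.int64)
            for j, ms in enumerate(level):
                for oi, o in enumerate(support):
                    sp[j, oi] = nxt[tuple(sorted(ms + (o,), reverse=True))]
            self.succ_pos.append(sp)
            probs = np.zeros((n_envs, n_out))
            for e in range(n_envs):
                p = object_reward_probability(config, e + 1, n + 1)
                for oi, o in enumerate(support):
                    probs[e, oi] = (1.0 - p) if o == 0 else p * size_q[o][e]
            self.out_prob.append(probs)

        # forward reach probabilities under always-inspect:
        # reach[n][e, j] = P(revealed multiset | env, n inspections)
        self.reach: list[np.ndarray] = [np.ones((n_envs, 1))]
        for n in range(n_obj):
            nxt = np.zeros((n_envs, len(self.multisets[n + 1])))
            cur = self.reach[n]
            for e in range(n_envs):
                np.add.at(nxt[e], self.succ_pos[n].ravel(),
                          (cur[e][:, None] * self.out_prob[n][e]).ravel())
            self.reach.append(nxt)

    # -- indexing -----------------------------------------------------------

    def n_multisets(self, n: int) -> int:
        return len(self.multisets[n])

    def index(self, state: PatchState) -> int:
        n = state.n_inspected
        j = self._ms_index[n][state.revealed]
        return int(self.level_offsets[n]
                   + (state.env - 1) * self.n_multisets(n) + j)

    def state(self, idx: int) -> PatchState:
        n = int(np.searchsorted(self.level_offsets, idx, side="right") - 1)
        off = idx - self.level_offsets[n]
        m = self.n_multisets(n)
        return PatchState(int(off // m) + 1, self.multisets[n][int(off % m)])

    def states(self) -> list[PatchState]:
        return [
            PatchState(e + 1, ms)
            for n in range(self.config.n_objects + 1)
            for e in range(self.config.n_envs)
            for ms in self.multisets[n]
        ]

    def level_view(self, arr: np.ndarray, n: int) -> np.ndarray:
        """View a flat per-state array as (n_envs, n_multisets) at level n."""
        lo, hi = self.level_offsets[n], self.level_offsets[n + 1]
        return arr[lo:hi].reshape(self.config.n_envs, self.n_multisets(n))


@functools.lru_cache(maxsize=8)
def get_state_space(config: ForagingConfig) -> StateSpace:
    """Cached state-space construction (configs are immutable)."""
    return StateSpace(config)


def enumerate_states(config: ForagingConfig) -> list[PatchState]:
    """All MDP states in canonical order.

    Every combination of environment, inspection count 0..n_objects and
    non-increasing multiset of producible reward sizes appears exactly once.
    """
    return get_state_space(config).states()


# ---------------------------------------------------------------------------
# per-state reference operations


def consume_value(
    config: ForagingConfig, state: PatchState, r_global: float
) -> tuple[float, int]:
    """Value (reward/s) of consuming optimally many revealed rewards and leaving.

    Maximizes over the count ``i`` of biggest revealed rewards to consume;
    returns ``(value, best_count)``. Smaller counts win ties.
    """
    if any(state.revealed[i] < state.revealed[i + 1]
           for i in range(len(state.revealed) - 1)):
        raise ValueError("revealed must be sorted non-increasing")
    if r_global < 0:
        raise ValueError("r_global must be >= 0")
    n = state.n_inspected
    k, T = config.k, config.T_max
    best_v, best_i, acc = -math.inf, 0, 0.0
    for i in range(n + 1):
        if i > 0:
            acc += state.revealed[i - 1] * (1.0 - k) ** (
                n * config.t_inspect + i * config.t_consume)
        residual = T - (n * config.t_inspect + i * config.t_consume
                        + config.t_travel)
        v = (acc + r_global * residual) / T
        if v > best_v:
            best_v, best_i = v, i
    return best_v, best_i


def inspect_value(
    config: ForagingConfig,
    state: PatchState,
    value_lookup: Mapping[PatchState, float],
) -> float:
    """Expected successor value of inspecting the next object."""
    total = 0.0
    for succ, p in transition_distribution(config, state):
        if succ not in value_lookup:
            raise KeyError(f"missing successor value for {succ}")
        total += p * value_lookup[succ]
    return total


# ---------------------------------------------------------------------------
# result containers


@dataclass
class ValueTable:
    """Per-state action values (flat arrays in canonical state order).

    ``v_consume`` and ``best_consume_count`` are the per-state greedy
    consumption value and count; ``v_inspect`` is NaN at terminal states;
    ``v`` is the value of the state under the solved policy (for the fully
    observable policy this equals ``max(v_inspect, v_consume)``).
    """

    space: StateSpace
    v: np.ndarray
    v_inspect: np.ndarray
    v_consume: np.ndarray
    best_consume_count: np.ndarray

    def lookup(self, state: PatchState) -> dict:
        i = self.space.index(state)
        return {
            "v": float(self.v[i]),
            "v_inspect": float(self.v_inspect[i]),
            "v_consume": float(self.v_consume[i]),
            "best_consume_count": int(self.best_consume_count[i]),
        }


@dataclass
class PolicyTable:
    """Per-state action and consumption-count plan."""

    space: StateSpace
    inspect: np.ndarray  # bool; True = INSPECT
    consume_count: np.ndarray  # int; count used if/when consuming

    def action(self, state: PatchState) -> Action:
        return (Action.INSPECT if self.inspect[self.space.index(state)]
                else Action.CONSUME_AND_LEAVE)

    def count(self, state: PatchState) -> int:
        return int(self.consume_count[self.space.index(state)])

    def same_as(self, other: "PolicyTable | None") -> bool:
        return (other is not None
                and np.array_equal(self.inspect, other.inspect)
                and np.array_equal(self.consume_count, other.consume_count))


@dataclass
class SolverResult:
    """Converged solve: value/policy tables, fixed-point rate and history."""

    config: ForagingConfig
    observable: ObservableSpec
    values: ValueTable
    policy: PolicyTable
    r_global: float
    iterations_used: int
    rate_history: list[float]
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        """One row per state: env, n_inspected, revealed, values, action."""
        space = self.values.space
        rows = []
        for i, s in enumerate(space.states()):
            rows.append({
                "env": s.env,
                "n_inspected": s.n_inspected,
                "revealed": " ".join(map(str, s.revealed)),
                "v_inspect": self.values.v_inspect[i],
                "v_consume": self.values.v_consume[i],
                "v": self.values.v[i],
                "action": ("inspect" if self.policy.inspect[i]
                           else "consume_and_leave"),
                "consume_count": int(self.policy.consume_count[i]),
            })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "policy": self.observable.name,
            "r_global": self.r_global,
            "iterations_used": self.iterations_used,
            "converged": self.converged,
            "rate_history": list(self.rate_history),
        }


@dataclass
class ThresholdCurve:
    """Per (env, n_inspected) consumption-value decision thresholds.

    For each slice the policy consumes exactly when ``V(s, consume)`` exceeds
    the threshold. ``lo`` is the largest consumption value among
    inspect-states, ``hi`` the smallest among consume-states (±inf when a
    side is empty); ``threshold`` is their midpoint, or the finite side's
    value for one-sided slices.
    """

    threshold: np.ndarray  # (n_envs, n_objects)
    lo: np.ndarray
    hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n_envs, n_obj = self.threshold.shape
        rows = [{"env": e + 1, "n_inspected": n,
                 "threshold": self.threshold[e, n],
                 "lo": self.lo[e, n], "hi": self.hi[e, n]}
                for e in range(n_envs) for n in range(n_obj)]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BeliefState:
    """Posterior over environments given the observable evidence."""

    posterior: tuple[float, ...]
    n_inspected: int
    evidence: tuple[int, ...]


# ---------------------------------------------------------------------------
# dynamic programming


def _group_weights(w: np.ndarray) -> np.ndarray:
    """Normalize non-negative weights; fall back to uniform if all zero."""
    total = w.sum()
    if total <= 0:
        return np.full(w.shape, 1.0 / w.size)
    return w / total


def solve_dp(
    config: ForagingConfig,
    r_global: float,
    observable: ObservableSpec = P4,
    space: StateSpace | None = None,
) -> tuple[ValueTable, PolicyTable]:
    """Backward induction for the greedy policy at a fixed global rate.

    Proceeds from ``n_inspected = n_objects`` down to 0. For restricted
    observability, states sharing an observable signature share one action
    and one consumption count, chosen to maximize the belief-weighted value;
    ties go to consume-and-leave.
    """
    if space is None:
        space = get_state_space(config)
    n_obj, n_envs, T = config.n_objects, config.n_envs, config.T_max
    N = space.n_states
    v = np.zeros(N)
    v_insp = np.full(N, np.nan)
    v_cons = np.zeros(N)
    greedy_cnt = np.zeros(N, dtype=np.int64)
    inspect = np.zeros(N, dtype=bool)
    plan_cnt = np.zeros(N, dtype=np.int64)

    for n in range(n_obj, -1, -1):
        m = space.n_multisets(n)
        cons_mat = space.A[n] + r_global * space.B[n]  # (m, n+1)
        vc_ms = cons_mat.max(axis=1) / T
        ci_ms = cons_mat.argmax(axis=1)

        vcl = space.level_view(v_cons, n)
        vcl[:] = vc_ms
        space.level_view(greedy_cnt, n)[:] = ci_ms

        # per-state consumption value/count under the observability rules
        if observable.revealed:
            cons_val = np.broadcast_to(vc_ms, (n_envs, m))
            cons_cnt = np.broadcast_to(ci_ms, (n_envs, m))
        else:
            reach = space.reach[n]  # (n_envs, m)
            cons_val = np.empty((n_envs, m))
            cons_cnt = np.empty((n_envs, m), dtype=np.int64)
            if observable.env:  # P2: one count per environment
                for e in range(n_envs):
                    bw = _group_weights(reach[e])
                    i_star = int(np.argmax(bw @ cons_mat))
                    cons_val[e] = cons_mat[:, i_star] / T
                    cons_cnt[e] = i_star
            else:  # P1: one count per level
                bw = _group_weights(reach.mean(axis=0))
                i_star = int(np.argmax(bw @ cons_mat))
                cons_val[:] = cons_mat[:, i_star] / T
                cons_cnt[:] = i_star

        if n == n_obj:  # terminal: consume is the only action
            space.level_view(v, n)[:] = cons_val
            space.level_view(plan_cnt, n)[:] = cons_cnt
            continue

        v_next = space.level_view(v, n + 1)
        vi = np.empty((n_envs, m))
        for e in range(n_envs):
            vi[e] = v_next[e][space.succ_pos[n]] @ space.out_prob[n][e]
        space.level_view(v_insp, n)[:] = vi

        # action selection per observable signature (ties -> consume)
        if observable.env and observable.revealed:
            act = vi > cons_val
        elif observable.revealed:  # P3: signature = (n, multiset)
            reach = space.reach[n]
            wsum = reach.sum(axis=0)
            safe = np.where(wsum > 0, wsum, 1.0)
            mi = np.where(wsum > 0, (reach * vi).sum(axis=0) / safe,
                          vi.mean(axis=0))
            act = np.broadcast_to(mi > vc_ms, (n_envs, m))
        elif observable.env:  # P2: signature = (env, n)
            act = np.empty((n_envs, m), dtype=bool)
            for e in range(n_envs):
                bw = _group_weights(space.reach[n][e])
                act[e] = (bw @ vi[e]) > (bw @ cons_val[e])
        else:  # P1: signature = n
            bw = _group_weights(space.reach[n].ravel())
            act = np.full((n_envs, m),
                          bw @ vi.ravel() > bw @ cons_val.ravel())

        space.level_view(inspect, n)[:] = act
        space.level_view(plan_cnt, n)[:] = cons_cnt
        space.level_view(v, n)[:] = np.where(act, vi, cons_val)

    values = ValueTable(space, v, v_insp, v_cons, greedy_cnt)
    policy = PolicyTable(space, inspect, plan_cnt)
    return values, policy


def evaluate_global_rate(
    config: ForagingConfig,
    policy: PolicyTable,
    space: StateSpace | None = None,
) -> float:
    """Exact long-run reward rate of a policy (no sampling).

    Forward-propagates state probabilities from a uniform-random environment
    entry, accumulating the expected discounted reward consumed per patch and
    the expected patch time including travel; returns their ratio.
    """
    if space is None:
        space = policy.space
    n_obj, n_envs = config.n_objects, config.n_envs
    t_ins, t_con, t_trv = config.t_inspect, config.t_consume, config.t_travel
    e_rew = 0.0
    e_time = 0.0
    cur = np.full((n_envs, 1), 1.0 / n_envs)  # level-0 occupancy
    for n in range(n_obj + 1):
        act = space.level_view(policy.inspect, n)
        cnt = space.level_view(policy.consume_count, n)
        stop = ~act if n < n_obj else np.ones_like(act, dtype=bool)
        if stop.any():
            p_stop = np.where(stop, cur, 0.0)
            rew = np.take_along_axis(
                space.A[n], cnt.T, axis=1).T  # (n_envs, m) consumed reward
            e_rew += float((p_stop * rew).sum())
            e_time += float(
                (p_stop * (n * t_ins + cnt * t_con + t_trv)).sum())
        if n < n_obj:
            go = np.where(act, cur, 0.0)
            nxt = np.zeros((n_envs, space.n_multisets(n + 1)))
            for e in range(n_envs):
                if go[e].any():
                    np.add.at(nxt[e], space.succ_pos[n].ravel(),
                              (go[e][:, None] * space.out_prob[n][e]).ravel())
            cur = nxt
    return e_rew / e_time


def optimize_policy(
    config: ForagingConfig,
    observable: ObservableSpec = P4,
    max_iter: int = 40,
    tol: float = 1e-6,
    space: StateSpace | None = None,
) -> SolverResult:
    """Find the reward-rate-optimal policy via the iterative fixed point.

    Starts from ``R_global = 0`` and alternates a DP solve with an exact
    re-evaluation of the resulting policy's true global reward rate, stopping
    when the policy is unchanged between iterations and the rate changes by
    less than ``tol`` (reward/s), or after ``max_iter`` iterations
    (flagged as non-converged, not raised).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if space is None:
        space = get_state_space(config)
    r = 0.0
    prev_policy: PolicyTable | None = None
    history: list[float] = []
    converged = False
    iterations = 0
    values = policy = None
    for it in range(1, max_iter + 1):
        values, policy = solve_dp(config, r, observable, space)
        r_new = evaluate_global_rate(config, policy, space)
        history.append(r_new)
        iterations = it
        if policy.same_as(prev_policy) and abs(r_new - r) < tol:
            converged = True
            r = r_new
            break
        prev_policy, r = policy, r_new
    return SolverResult(config, observable, values, policy, r,
                        iterations, history, converged)


def extract_thresholds(
    config: ForagingConfig, result: SolverResult
) -> ThresholdCurve:
    """Per (env, n_inspected) decision thresholds of a solved policy.

    Verifies that within every slice the policy's choices are exactly
    separated by a single consumption-value threshold (consume above,
    inspect below) and raises if any slice is not threshold-separable.
    """
    space = result.values.space
    n_envs, n_obj = config.n_envs, config.n_objects
    lo = np.full((n_envs, n_obj), -np.inf)
    hi = np.full((n_envs, n_obj), np.inf)
    thr = np.empty((n_envs, n_obj))
    for n in range(n_obj):
        vc = space.level_view(result.values.v_consume, n)
        act = space.level_view(result.policy.inspect, n)
        for e in range(n_envs):
            ins, con = vc[e][act[e]], vc[e][~act[e]]
            if ins.size:
                lo[e, n] = ins.max()
            if con.size:
                hi[e, n] = con.min()
            if lo[e, n] > hi[e, n] + 1e-12:
                raise ValueError(
                    f"slice env={e + 1}, n_inspected={n} is not "
                    f"threshold-separable (max inspect {lo[e, n]:.6g} > "
                    f"min consume {hi[e, n]:.6g})")
            if np.isfinite(lo[e, n]) and np.isfinite(hi[e, n]):
                thr[e, n] = 0.5 * (lo[e, n] + hi[e, n])
            elif np.isfinite(hi[e, n]):
                thr[e, n] = hi[e, n]
            elif np.isfinite(lo[e, n]):
                thr[e, n] = lo[e, n]
            else:  # empty slice cannot occur: every level has states
                thr[e, n] = np.nan
    return ThresholdCurve(thr, lo, hi)


def belief_posterior(
    config: ForagingConfig,
    n_inspected: int,
    evidence: Sequence[int],
) -> BeliefState:
    """Exact Bayesian posterior over environments given observed evidence.

    ``evidence`` is the non-increasing multiset of revealed reward sizes
    after ``n_inspected`` inspections. The likelihood per environment is the
    Poisson-binomial probability of the observed number of reward successes
    over the index-dependent reward probabilities, times the multinomial
    likelihood of the observed size multiset under the environment's size
    distribution. The prior over environments is uniform.
    """
    ev = tuple(int(r) for r in evidence)
    if len(ev) != n_inspected:
        raise ValueError("evidence length must equal n_inspected")
    if any(ev[i] < ev[i + 1] for i in range(len(ev) - 1)):
        raise ValueError("evidence must be sorted non-increasing")
    nonzero = [r for r in ev if r > 0]
    c = len(nonzero)
    counts = {m: nonzero.count(m) for m in set(nonzero)}
    multinom = math.factorial(c)
    for mult in counts.values():
        multinom //= math.factorial(mult)

    lik = np.zeros(config.n_envs)
    for e in range(1, config.n_envs + 1):
        # Poisson-binomial distribution of the success count
        poly = np.ones(1)
        for i in range(1, n_inspected + 1):
            p = object_reward_probability(config, e, i)
            poly = np.convolve(poly, [1.0 - p, p])
        count_prob = poly[c] if c < len(poly) else 0.0
        size_lik = multinom
        for m, mult in counts.items():
            size_lik *= config.size_dist[e - 1][m - 1] ** mult
        lik[e - 1] = count_prob * size_lik
    total = lik.sum()
    if total <= 0:
        raise ValueError("impossible evidence: zero likelihood in every "
                         "environment")
    return BeliefState(tuple(lik / total), n_inspected, ev)
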