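"""Domain types and generative mathematics of the object-inspection foraging world.

The world is a patch-foraging environment: an agent enters a patch drawn
uniformly from ``n_envs`` environments of differing richness. Each patch holds
``n_objects`` objects whose hidden rewards must be *inspected* (time cost
``t_inspect``) before they can be *consumed* (time cost ``t_consume``).
Object ``i`` (1-based) in environment ``env`` delivers a reward with
probability ``p_max(env) * 2**(-tau(env) * (i - 1))``; when reward occurs its
size is an integer 1..5 drawn from the environment's size distribution, and 0
otherwise. Rewards decay with delay via a temporal discount rate ``k``:
a reward of size ``r`` consumed ``t`` seconds into the patch is worth
``r * (1 - k)**t``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "REWARD_SIZES",
    "ForagingConfig",
    "PatchState",
    "Action",
    "ObservableSpec",
    "object_reward_probability",
    "discounted_reward",
    "transition_distribution",
]

#: Possible nonzero reward sizes. Size 0 means "revealed, no reward".
REWARD_SIZES = (1, 2, 3, 4, 5)

_UNIFORM_SIZES = tuple(1.0 / len(REWARD_SIZES) for _ in REWARD_SIZES)


def _as_env_tuple(value, n_envs: int, name: str) -> tuple[float, ...]:
    """Broadcast a scalar to one value per environment; validate length."""
    if np.isscalar(value):
        return (float(value),) * n_envs
    out = tuple(float(v) for v in value)
    if len(out) != n_envs:
        raise ValueError(f"{name} must have one entry per environment "
                         f"({n_envs}), got {len(out)}")
    return out


@dataclass(frozen=True)
class ForagingConfig:
    """Full parameterization of environments, objects, time costs and discounting.

    Parameters
    ----------
    n_envs : int
        Number of environments (levels of richness).
    n_objects : int
        Objects per patch.
    p_max : float or sequence of float
        Per-environment reward probability of the best object.
    tau : float or sequence of float
        Per-environment decay rate of reward probability with object index.
    size_dist : sequence of sequence of float, optional
        Per-environment probability vector over reward sizes 1..5 given that
        reward occurs. Defaults to uniform in every environment.
    t_inspect, t_consume, t_travel : float
        Time costs in seconds of one inspection, one consumption, and one
        patch change.
    k : float
        Temporal discount rate per second, strictly in (0, 1).
    T_max : float, optional
        Normalization horizon in seconds. Defaults to the maximum possible
        patch duration ``n_objects * (t_inspect + t_consume) + t_travel``.
    """

    n_envs: int = 5
    n_objects: int = 9
    p_max: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    tau: tuple[float, ...] = (0.7, 0.7, 0.7, 0.7, 0.7)
    size_dist: tuple[tuple[float, ...], ...] | None = None
    t_inspect: float = 0.5
    t_consume: float = 1.25
    t_travel: float = 8.0
    k: float = 0.275
    T_max: float | None = None

    def __post_init__(self):
        if self.n_envs < 1 or self.n_objects < 0:
            raise ValueError("n_envs must be >= 1 and n_objects >= 0")
        object.__setattr__(self, "p_max",
                           _as_env_tuple(self.p_max, self.n_envs, "p_max"))
        object.__setattr__(self, "tau",
                           _as_env_tuple(self.tau, self.n_envs, "tau"))
        if self.size_dist is None:
            sd = (_UNIFORM_SIZES,) * self.n_envs
        else:
            sd = tuple(tuple(float(q) for q in row) for row in self.size_dist)
            if len(sd) != self.n_envs:
                raise ValueError("size_dist needs one row per environment")
        for row in sd:
            if len(row) != len(REWARD_SIZES):
                raise ValueError("each size_dist row must have 5 entries "
                                 "(sizes 1..5)")
            if any(q < 0 for q in row) or abs(sum(row) - 1.0) > 1e-9:
                raise ValueError("each size_dist row must be a probability "
                                 "vector summing to 1")
        object.__setattr__(self, "size_dist", sd)
        if any(not (0.0 <= p <= 1.0) for p in self.p_max):
            raise ValueError("p_max entries must lie in [0, 1]")
        if any(t < 0 for t in self.tau):
            raise ValueError("tau entries must be >= 0")
        for name in ("t_inspect", "t_consume", "t_travel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.k < 1.0):
            raise ValueError("k must lie strictly in (0, 1)")
        if self.T_max is None:
            object.__setattr__(
                self, "T_max",
                self.n_objects * (self.t_inspect + self.t_consume)
                + self.t_travel)
        elif self.T_max <= 0:
            raise ValueError("T_max must be > 0")

    # -- derived quantities -------------------------------------------------

    @property
    def size_support(self) -> tuple[int, ...]:
        """Reward sizes that can actually be revealed, in descending order.

        Always includes 0 (the "no reward" outcome); includes a nonzero size
        iff it has positive probability in at least one environment.
        """
        sizes = {0}
        for row in self.size_dist:
            sizes.update(m for m, q in zip(REWARD_SIZES, row) if q > 0)
        return tuple(sorted(sizes, reverse=True))

    def reward_probabilities(self, env: int) -> np.ndarray:
        """Reward probability of each object (index 1..n_objects) in ``env``."""
        i = np.arange(1, self.n_objects + 1)
        return self.p_max[env - 1] * 2.0 ** (-self.tau[env - 1] * (i - 1))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_envs": self.n_envs,
            "n_objects": self.n_objects,
            "p_max": list(self.p_max),
            "tau": list(self.tau),
            "size_dist": [list(row) for row in self.size_dist],
            "t_inspect": self.t_inspect,
            "t_consume": self.t_consume,
            "t_travel": self.t_travel,
            "k": self.k,
            "T_max": self.T_max,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ForagingConfig":
        return cls(**dict(d))

    def save(self, path) -> None:
        """Write the config as YAML (.yaml/.yml) or JSON (.json)."""
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "ForagingConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def replace(self, **changes) -> "ForagingConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class PatchState:
    """One MDP state: environment identity and the revealed rewards so far.

    ``env`` is the 1-based environment label; ``revealed`` is the
    non-increasing tuple of revealed reward sizes (0 = revealed, no reward).
    The number of objects inspected so far is ``len(revealed)``.
    """

    env: int
    revealed: tuple[int, ...] = ()

    def __post_init__(self):
        rev = tuple(int(r) for r in self.revealed)
        object.__setattr__(self, "revealed", rev)
        if any(rev[i] < rev[i + 1] for i in range(len(rev) - 1)):
            raise ValueError("revealed must be sorted non-increasing")
        if any(r not in (0, *REWARD_SIZES) for r in rev):
            raise ValueError("revealed entries must be integers 0..5")

    @property
    def n_inspected(self) -> int:
        return len(self.revealed)

    def with_outcome(self, size: int) -> "PatchState":
        """State after inspecting the next object and revealing ``size``."""
        rev = tuple(sorted(self.revealed + (int(size),), reverse=True))
        return PatchState(self.env, rev)


class Action(Enum):
    INSPECT = "inspect"
    CONSUME_AND_LEAVE = "consume_and_leave"


@dataclass(frozen=True)
class ObservableSpec:
    """Which state components a policy may condition on.

    The inspection count is always observable. The four canonical policies:

    * ``P1`` — inspection count only,
    * ``P2`` — environment + inspection count,
    * ``P3`` — revealed rewards + inspection count,
    * ``P4`` — the full state.
    """

    env: bool = True
    revealed: bool = True

    @property
    def name(self) -> str:
        return {(False, False): "P1", (True, False): "P2",
                (False, True): "P3", (True, True): "P4"}[
                    (self.env, self.revealed)]

    @classmethod
    def from_name(cls, name: str) -> "ObservableSpec":
        table = {"P1": cls(env=False, revealed=False),
                 "P2": cls(env=True, revealed=False),
                 "P3": cls(env=False, revealed=True),
                 "P4": cls(env=True, revealed=True)}
        try:
            return table[name.upper()]
        except KeyError:
            raise ValueError(
                f"unknown policy name {name!r}; valid: P1, P2, P3, P4"
            ) from None


# Canonical observability settings.
P1 = ObservableSpec(env=False, revealed=False)
P2 = ObservableSpec(env=True, revealed=False)
P3 = ObservableSpec(env=False, revealed=True)
P4 = ObservableSpec(env=True, revealed=True)


def object_reward_probability(config: ForagingConfig, env: int, i: int) -> float:
    """Reward probability of object ``i`` (1-based) in environment ``env`` (1-based).

    Exponentially decaying in the object index: the first object is the best,
    with probability ``p_max(env)``, and each subsequent object's probability
    is scaled by ``2**(-tau(env))``.
    """
    if not 1 <= env <= config.n_envs:
        raise IndexError(f"env must be in 1..{config.n_envs}, got {env}")
    if not 1 <= i <= config.n_objects:
        raise IndexError(f"object index must be in 1..{config.n_objects}, "
                         f"got {i}")
    return config.p_max[env - 1] * 2.0 ** (-config.tau[env - 1] * (i - 1))


def discounted_reward(r: float, t_delay: float, k: float) -> float:
    """Value of a reward of size ``r`` consumed after ``t_delay`` seconds.

    Multiplicative decay ``r * (1 - k)**t_delay``; at ``t_delay = 0`` the full
    reward is obtained.
    """
    if t_delay < 0:
        raise ValueError("t_delay must be >= 0")
    if not (0.0 < k < 1.0):
        raise ValueError("k must lie strictly in (0, 1)")
    if r < 0:
        raise ValueError("r must be >= 0")
    return r * (1.0 - k) ** t_delay


def transition_distribution(
    config: ForagingConfig, state: PatchState
) -> list[tuple[PatchState, float]]:
    """Successor distribution of inspecting the next object.

    The next object is ``n_inspected + 1``. With probability ``p_i`` a size
    drawn from the environment's size distribution is inserted into the
    sorted multiset of revealed rewards; with probability ``1 - p_i`` a 0 is
    inserted. Successors with zero probability are omitted, so the result
    has at most 6 entries.
    """
    n = state.n_inspected
    if n >= config.n_objects:
        raise ValueError("cannot inspect: all objects already inspected")
    p = object_reward_probability(config, state.env, n + 1)
    out: list[tuple[PatchState, float]] = []
    if p < 1.0:
        out.append((state.with_outcome(0), 1.0 - p))
    if p > 0.0:
        for m, q in zip(REWARD_SIZES, config.size_dist[state.env - 1]):
            if q > 0:
                out.append((state.with_outcome(m), p * q))
    return out
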