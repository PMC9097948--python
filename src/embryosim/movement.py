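"""Directed single-cell migration as hierarchical path optimization.

The migration of a cell such as Cpaaa — anterior movement by intercalation
between neighbor cells — is framed as a path optimization problem: the
agent must thread a crowded field toward a destination, optionally via an
ordered sequence of sub-goals (the rosette-like waypoints along the
intercalation channel), while neighbor cells and the eggshell act as hard
constraints (occupied lattice sites / lattice bounds).

The learner is tabular Q-learning over a discretized local state: the
agent's lattice offset to its *current* goal, an occupancy mask of the
adjacent sites, and the goal index. This keeps the scheme exact, seeded
and desk-scale; the environment/reward contract is fixed so that a
function-approximation learner could be dropped in behind the same
interface.

Rewards: each step costs ``step_cost``; bumping into an occupied or
off-lattice site costs ``collision_penalty`` extra (the agent stays put);
reaching the current goal earns ``goal_reward`` and advances the goal
index. An episode ends at the final destination or after ``max_steps``.
"""

from __future__ import annotations

import ast
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import yaml

from .errors import ConfigurationError, RolloutError

Site = tuple[int, ...]


def _moves(ndim: int) -> list[tuple[int, ...]]:
    """Axis-aligned unit moves, then stay; order fixes the tie-break."""
    out = []
    for axis in range(ndim):
        for sign in (1, -1):
            step = [0] * ndim
            step[axis] = sign
            out.append(tuple(step))
    out.append(tuple([0] * ndim))
    return out


@dataclass(frozen=True)
class MigrationEnvironment:
    """Bounded integer lattice with static obstacle cells and ordered goals."""

    shape: tuple[int, ...]
    occupied: frozenset
    start: Site
    goals: tuple[Site, ...]  # sub-goals in order, destination last
    spacing: float = 1.0  # um per lattice unit
    step_cost: float = 1.0
    collision_penalty: float = 5.0
    goal_reward: float = 100.0
    max_steps: int = 200

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(
            self, "occupied", frozenset(tuple(int(v) for v in s) for s in self.occupied)
        )
        object.__setattr__(self, "start", tuple(int(v) for v in self.start))
        object.__setattr__(
            self, "goals", tuple(tuple(int(v) for v in g) for g in self.goals)
        )
        if not self.goals:
            raise ValueError("need at least one goal")
        if len(set(self.goals)) != len(self.goals):
            raise ValueError("goals must be distinct")
        for s in (self.start, *self.goals):
            if s in self.occupied:
                raise ValueError(f"site {s} is occupied")
            if not self.in_bounds(s):
                raise ValueError(f"site {s} is off-lattice")
        if self.step_cost < 0 or self.collision_penalty < 0 or self.goal_reward <= 0:
            raise ValueError("invalid reward constants")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def actions(self) -> list[tuple[int, ...]]:
        return _moves(self.ndim)

    @property
    def destination(self) -> Site:
        return self.goals[-1]

    def in_bounds(self, site: Site) -> bool:
        return all(0 <= v < n for v, n in zip(site, self.shape))

    def is_free(self, site: Site) -> bool:
        return self.in_bounds(site) and site not in self.occupied

    def observation(self, site: Site, goal_index: int) -> tuple:
        """Discretized learner state: goal offset, local occupancy, goal index."""
        goal = self.goals[goal_index]
        rel = tuple(g - s for g, s in zip(goal, site))
        mask = tuple(
            not self.is_free(tuple(s + m for s, m in zip(site, move)))
            for move in self.actions[:-1]
        )
        return (rel, mask, goal_index)


@dataclass(frozen=True)
class EnvState:
    site: Site
    goal_index: int
    steps: int
    done: bool = False


def initial_state(env: MigrationEnvironment) -> EnvState:
    """Start-of-episode state; done immediately if start is the destination."""
    gi = 0
    site = env.start
    # starting on a (sub-)goal counts as already achieved
    while gi < len(env.goals) and site == env.goals[gi]:
        gi += 1
    return EnvState(site, min(gi, len(env.goals) - 1), 0, done=gi == len(env.goals))


def env_step(
    env: MigrationEnvironment, state: EnvState, action: int
) -> tuple[EnvState, float, bool]:
    """Apply one action; returns (next_state, reward, done)."""
    moves = env.actions
    if not 0 <= action < len(moves):
        raise ValueError(f"action {action} outside action set of size {len(moves)}")
    target = tuple(s + m for s, m in zip(state.site, moves[action]))
    blocked = moves[action] != moves[-1] and not env.is_free(target)
    site = state.site if blocked else target
    reward = -env.step_cost - (env.collision_penalty if blocked else 0.0)
    gi = state.goal_index
    done = False
    if site == env.goals[gi]:
        reward += env.goal_reward
        if gi == len(env.goals) - 1:
            done = True
        else:
            gi += 1
    steps = state.steps + 1
    if steps >= env.max_steps:
        done = True
    return EnvState(site, gi, steps, done), reward, done


# -- policy -------------------------------------------------------------------


@dataclass
class Policy:
    """Learned action-value table keyed by (observation, action index)."""

    q: dict = field(default_factory=dict)
    n_actions: int = 5
    training_returns: list = field(default_factory=list)

    def value(self, obs: tuple, action: int) -> float:
        return self.q.get((obs, action), 0.0)

    def greedy_action(self, obs: tuple) -> int:
        """Argmax over actions, lowest index on ties."""
        best, best_v = 0, -np.inf
        for a in range(self.n_actions):
            v = self.value(obs, a)
            if v > best_v:
                best, best_v = a, v
        return best

    def save(self, path) -> None:
        payload = {
            "n_actions": self.n_actions,
            "q": {f"{obs!r}|{a}": v for (obs, a), v in self.q.items()},
            "training_returns": self.training_returns,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "Policy":
        with open(path) as fh:
            payload = json.load(fh)
        q = {}
        for key, v in payload["q"].items():
            obs_repr, a = key.rsplit("|", 1)
            q[(ast.literal_eval(obs_repr), int(a))] = v
        return cls(q, payload["n_actions"], payload.get("training_returns", []))


def check_reachable(env: MigrationEnvironment) -> None:
    """Verify start -> goal_1 -> ... -> destination through free sites."""
    g = nx.Graph()
    free = [
        site
        for site in np.ndindex(*env.shape)
        if env.is_free(site)
    ]
    g.add_nodes_from(free)
    for site in free:
        for move in _moves(env.ndim)[:-1]:
            nb = tuple(s + m for s, m in zip(site, move))
            if env.is_free(nb):
                g.add_edge(site, nb)
    waypoints = [env.start, *env.goals]
    for a, b in zip(waypoints, waypoints[1:]):
        if not nx.has_path(g, a, b):
            raise ConfigurationError(f"goal {b} unreachable from {a}")


def train_q_learning(
    env: MigrationEnvironment,
    episodes: int = 3000,
    alpha: float = 0.5,
    gamma: float = 0.95,
    epsilon_schedule: Callable[[int], float] | tuple[float, float] = (1.0, 0.05),
    seed: int = 0,
) -> Policy:
    """Tabular Q-learning; bit-reproducible for fixed seed and config."""
    if episodes < 1:
        raise ValueError("episodes must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if not 0 <= gamma < 1:
        raise ValueError("gamma must be in [0, 1)")
    check_reachable(env)
    if callable(epsilon_schedule):
        eps_at = epsilon_schedule
    else:
        e0, e1 = epsilon_schedule
        eps_at = lambda ep: e0 + (e1 - e0) * ep / max(1, episodes - 1)

    rng = np.random.default_rng(seed)
    n_actions = len(env.actions)
    policy = Policy(n_actions=n_actions)
    q = policy.q
    for ep in range(episodes):
        eps = eps_at(ep)
        state = initial_state(env)
        total = 0.0
        while not state.done:
            obs = env.observation(state.site, state.goal_index)
            if rng.random() < eps:
                action = int(rng.integers(n_actions))
            else:
                action = policy.greedy_action(obs)
            nxt, reward, done = env_step(env, state, action)
            total += reward
            obs_next = env.observation(nxt.site, nxt.goal_index)
            target = reward
            if not done:
                target += gamma * max(
                    q.get((obs_next, a), 0.0) for a in range(n_actions)
                )
            key = (obs, action)
            old = q.get(key, 0.0)
            q[key] = old + alpha * (target - old)
            state = nxt
        policy.training_returns.append(total)
    return policy


def greedy_rollout(
    env: MigrationEnvironment, policy: Policy, seed: int = 0
) -> tuple[list[Site], float]:
    """Deterministic greedy path from start; returns (path, total reward).

    The path lists the sites visited after the start (empty if the start
    already satisfies all goals). A revisited (site, goal index) pair under
    the deterministic policy means a loop and aborts the rollout.
    """
    state = initial_state(env)
    path: list[Site] = []
    total = 0.0
    visited = {(state.site, state.goal_index)}
    while not state.done:
        obs = env.observation(state.site, state.goal_index)
        action = policy.greedy_action(obs)
        state, reward, done = env_step(env, state, action)
        total += reward
        path.append(state.site)
        key = (state.site, state.goal_index)
        if not done and key in visited:
            raise RolloutError(
                f"greedy rollout revisited {key[0]} at goal index {key[1]}"
            )
        visited.add(key)
        if done and state.site != env.destination:
            raise RolloutError("rollout hit the step limit before the destination")
    return path, total


def path_statistics(paths: Sequence[Sequence[Site]]) -> tuple[np.ndarray, np.ndarray]:
    """Per-time-step mean position and standard deviation across runs.

    Ragged paths are padded with their final position (a finished cell
    stays put). Returns arrays of shape (T, ndim) where T is the longest
    path length.
    """
    if not paths:
        raise ValueError("need at least one path")
    lengths = [len(p) for p in paths]
    T = max(lengths)
    if T == 0:
        raise ValueError("all paths are empty")
    ndim = len(paths[0][0]) if paths[0] else len(next(p for p in paths if p)[0])
    stacked = np.empty((len(paths), T, ndim), dtype=float)
    for k, p in enumerate(paths):
        if not p:
            raise ValueError("cannot pad a zero-length path")
        arr = np.asarray(p, dtype=float)
        stacked[k, : len(p)] = arr
        stacked[k, len(p):] = arr[-1]
    return stacked.mean(axis=0), stacked.std(axis=0)


# -- scenario file ------------------------------------------------------------


def save_scenario(env: MigrationEnvironment, path) -> None:
    payload = {
        "shape": list(env.shape),
        "spacing": env.spacing,
        "occupied": sorted(list(s) for s in env.occupied),
        "start": list(env.start),
        "goals": [list(g) for g in env.goals],
        "step_cost": env.step_cost,
        "collision_penalty": env.collision_penalty,
        "goal_reward": env.goal_reward,
        "max_steps": env.max_steps,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def load_scenario(path) -> MigrationEnvironment:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return MigrationEnvironment(
        shape=tuple(payload["shape"]),
        occupied=frozenset(tuple(s) for s in payload["occupied"]),
        start=tuple(payload["start"]),
        goals=tuple(tuple(g) for g in payload["goals"]),
        spacing=payload.get("spacing", 1.0),
        step_cost=payload.get("step_cost", 1.0),
        collision_penalty=payload.get("collision_penalty", 5.0),
        goal_reward=payload.get("goal_reward", 100.0),
        max_steps=payload.get("max_steps", 200),
    )
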