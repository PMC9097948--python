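"""Synthetic fixtures: lineages, division observations, migration scenarios.

Everything the other modules consume can be generated here as a pure
function of a spec plus a seed, standing in for the observation datasets
(lineage tables, tracked division axes, migration fields) that would
normally come from automated lineaging of 3D time-lapse imaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import division_direction as dd
from .errors import ConfigurationError
from .lineage import FATE_LABELS, LineageNode, LineageTree
from .mechanics import rodrigues_rotation
from .movement import MigrationEnvironment, check_reachable


@dataclass(frozen=True)
class SynthSpec:
    """Parameters for the synthetic generators."""

    generations: int = 4
    division_interval: int = 15  # minutes between successive rounds
    noise_angle_deg: float = 5.0
    n_observations: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.division_interval <= 0:
            raise ValueError("division interval must be positive")
        if self.noise_angle_deg < 0:
            raise ValueError("noise angle must be >= 0")
        if self.n_observations < 1:
            raise ValueError("need at least one observation")


# -- lineage ------------------------------------------------------------------

#: Cycled over nodes in breadth-first order (the five tissue-marker labels).
_CYCLE_FATES = tuple(f for f in FATE_LABELS if f not in ("other", "unassigned"))


def synth_lineage(spec: SynthSpec) -> LineageTree:
    """Complete binary tree: root "AB", uniform division interval.

    Every non-leaf divides every ``division_interval`` minutes; fates are
    assigned cyclically from the tissue-marker label set in breadth-first
    order. Deterministic for a given spec (the seed is part of the spec
    but this generator has no random choices).
    """
    nodes: list[LineageNode] = []
    frontier = [("AB", None, 0)]
    counter = 0
    for gen in range(spec.generations + 1):
        next_frontier = []
        terminal = gen == spec.generations
        for name, parent, birth in frontier:
            division = None if terminal else birth + spec.division_interval
            fate = _CYCLE_FATES[counter % len(_CYCLE_FATES)]
            counter += 1
            nodes.append(LineageNode(name, parent, birth, division, fate))
            if not terminal:
                next_frontier.append((name + "a", name, division))
                next_frontier.append((name + "p", name, division))
        frontier = next_frontier
    return LineageTree(nodes)


# -- division observations ----------------------------------------------------


def _uniform_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def synth_divisions(
    K_true,
    n: int = 200,
    noise_angle_deg: float = 5.0,
    seed: int = 0,
    p_zero_s: float = 0.2,
    p_zero_e: float = 0.3,
) -> list[dd.ObservedDivision]:
    """Observations generated from a known coefficient vector.

    Components are uniform on the sphere; ``s`` and ``e`` are zeroed with
    the given probabilities (a dividing cell may feel no squeeze). The
    observed axis is the model composition tilted by a random angle about
    a uniformly random transverse axis; the tilt angle is half-normal with
    *mean* ``noise_angle_deg`` so the generated data's mean angular
    deviation equals the nominal noise level.
    """
    K = np.asarray(K_true, dtype=float)
    if K.min() < 0 or abs(K.sum() - 1.0) > 1e-9:
        raise ValueError("K_true must lie on the unit simplex")
    rng = np.random.default_rng(seed)
    # half-normal with mean m has scale m * sqrt(pi/2)
    scale = np.deg2rad(noise_angle_deg) * np.sqrt(np.pi / 2.0)
    out = []
    k = 0
    while len(out) < n:
        p = _uniform_unit_vectors(rng, 1)[0]
        s = _uniform_unit_vectors(rng, 1)[0]
        e = _uniform_unit_vectors(rng, 1)[0]
        if rng.random() < p_zero_s:
            s = np.zeros(3)
        if rng.random() < p_zero_e:
            e = np.zeros(3)
        comps = dd.DirectionComponents(p, s, e)
        if np.linalg.norm(comps.matrix() @ K) < 1e-9:
            continue  # all active cues have zero weight; resample
        axis_true = dd.compose_direction(K, comps)
        # uniform transverse axis: orthogonalize a random vector against axis_true
        t = _uniform_unit_vectors(rng, 1)[0]
        t = t - (t @ axis_true) * axis_true
        while np.linalg.norm(t) < 1e-9:
            t = _uniform_unit_vectors(rng, 1)[0]
            t = t - (t @ axis_true) * axis_true
        t /= np.linalg.norm(t)
        angle = abs(rng.normal(0.0, scale)) if noise_angle_deg > 0 else 0.0
        observed = rodrigues_rotation(axis_true, t, angle)
        out.append(dd.ObservedDivision(f"obs{k:04d}", comps, observed))
        k += 1
    return out


# -- migration scenarios ------------------------------------------------------

SCENARIO_KINDS = ("corridor", "open_grid", "detour", "cpaaa_like")


def synth_migration_scenario(kind: str, seed: int = 0) -> MigrationEnvironment:
    """Canonical migration test fields; all destination-reachable.

    ``cpaaa_like`` emulates the anterior intercalation of Cpaaa: a band of
    occupied neighbor cells crossed by a single free channel, with four
    ordered sub-goals along the channel (the successive rosette waypoints)
    followed by the destination beyond the band.
    """
    if kind == "corridor":
        env = MigrationEnvironment(
            shape=(7, 1),
            occupied=frozenset(),
            start=(0, 0),
            goals=((6, 0),),
            max_steps=100,
        )
    elif kind == "open_grid":
        env = MigrationEnvironment(
            shape=(7, 7),
            occupied=frozenset(),
            start=(0, 0),
            goals=((6, 6),),
            max_steps=200,
        )
    elif kind == "detour":
        wall = frozenset((3, y) for y in range(0, 6))  # gap at y=6
        env = MigrationEnvironment(
            shape=(7, 7),
            occupied=wall,
            start=(0, 3),
            goals=((6, 3),),
            max_steps=200,
        )
    elif kind == "cpaaa_like":
        band = frozenset(
            (x, y) for y in (2, 3, 4, 5) for x in range(9) if x != 4
        )
        env = MigrationEnvironment(
            shape=(9, 8),
            occupied=band,
            start=(4, 0),
            goals=((4, 2), (4, 3), (4, 4), (4, 5), (4, 7)),  # 4 sub-goals + destination
            max_steps=300,
        )
    else:
        raise ValueError(f"unknown scenario kind {kind!r}; choose from {SCENARIO_KINDS}")
    try:
        check_reachable(env)
    except ConfigurationError as exc:  # pragma: no cover - construction guarantee
        raise AssertionError(f"generated scenario {kind} not reachable: {exc}")
    return env
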