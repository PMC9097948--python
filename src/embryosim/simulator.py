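"""Agent-based engine advancing the embryo in 1-minute observation steps.

Each step: (1) execute every division the lineage schedules at this time,
in lexicographic mother-name order — the division axis comes from the
direction model applied to current geometry, daughters are placed along it
and named by the Sulston convention (anterior daughter on the hemisphere
the axis shares with the AP axis); (2) rebuild the contact graph and relax
the spring-mass network to quasi-equilibrium inside the eggshell; (3)
record a snapshot. Fate and division timing are data from the lineage
table; mechanics only decides *where* cells sit.

One relaxation per observation step: a division breaks the previous
equilibrium and the new one is computed immediately, consistent with
mechanics being fast on the 1-minute cadence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from . import division_direction as dd
from . import lineage as lin
from . import mechanics as mech
from .errors import ConfigurationError, EmbryosimError

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Geometry, mechanics and model knobs for one run.

    The default eggshell matches the embryo's rough dimensions (50 um long,
    30 um across -> semi-axes 25, 15, 15 um); the default time step is the
    1-minute imaging cadence. The initial root radius fills 60% of the
    shell volume at the 16-cell stage under equal-volume splitting, which
    for the default shell is exactly 15 um.
    """

    eggshell_semi_axes: tuple[float, float, float] = (25.0, 15.0, 15.0)
    ap_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    time_step: int = 1
    spring_k: float = mech.DEFAULT_K
    shell_k: float = mech.DEFAULT_K_SHELL
    contact_factor: float = mech.DEFAULT_CONTACT_FACTOR
    offset_fraction: float = 0.5
    tol_grad: float = mech.DEFAULT_TOL_GRAD
    max_iter: int = mech.DEFAULT_MAX_ITER
    fill_fraction: float = 0.6  # shell volume fraction at the 16-cell stage
    axis_noise_deg: float = 3.0  # seeded stochastic tilt of each division axis
    division_K: tuple[float, float, float] = (0.5, 0.3, 0.2)
    seed: int = 0
    end_time: Optional[int] = None

    def __post_init__(self):
        a, b, c = self.eggshell_semi_axes
        if min(a, b, c) <= 0:
            raise ConfigurationError("eggshell semi-axes must be positive")
        ap = np.asarray(self.ap_axis, float)
        n = np.linalg.norm(ap)
        if n == 0:
            raise ConfigurationError("AP axis must be nonzero")
        self.ap_axis = tuple(ap / n)
        if self.time_step <= 0:
            raise ConfigurationError("time step must be positive")

    @property
    def shell(self) -> mech.EggshellEllipsoid:
        return mech.EggshellEllipsoid(tuple(self.eggshell_semi_axes))

    def initial_radius(self) -> float:
        """Root radius giving fill_fraction of shell volume (volume conserved)."""
        a, b, c = self.eggshell_semi_axes
        return float((self.fill_fraction * a * b * c) ** (1.0 / 3.0))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "eggshell_semi_axes", "ap_axis", "division_K",
        ):
            if key in payload:
                kwargs[key] = tuple(payload.pop(key))
        kwargs.update(payload)
        return cls(**kwargs)


@dataclass(frozen=True)
class DivisionRecord:
    time: int
    mother: str
    daughters: tuple[str, str]
    axis: tuple[float, float, float]


@dataclass
class Trajectory:
    """Per-time-point snapshots plus the division event log."""

    times: list[int] = field(default_factory=list)
    snapshots: list[list[mech.Cell]] = field(default_factory=list)
    events: list[DivisionRecord] = field(default_factory=list)

    def counts(self) -> list[int]:
        return [len(s) for s in self.snapshots]

    def frames(self):
        return list(zip(self.times, self.snapshots))

    def total_volume(self, index: int) -> float:
        return float(sum(c.volume for c in self.snapshots[index]))


def run_simulation(
    config: SimulationConfig,
    tree: lin.LineageTree,
    initial_state: Optional[Sequence[mech.Cell]] = None,
    division_model: Optional[dd.DivisionDirectionModel] = None,
) -> Trajectory:
    """Advance from the root's birth to end_time, recording every step."""
    shell = config.shell
    ap = np.asarray(config.ap_axis, float)
    model = division_model or dd.DivisionDirectionModel(np.asarray(config.division_K))
    rng = np.random.default_rng(config.seed)

    start = tree.root.birth_time
    if initial_state is None:
        cells = {
            tree.root.name: mech.Cell(
                tree.root.name,
                np.asarray(shell.center, float),
                config.initial_radius(),
                polarity=ap,
            )
        }
        if len(lin.cells_alive_at(tree, start)) != 1:
            raise ConfigurationError("default initial state requires a single root cell")
    else:
        cells = {c.name: c.copy() for c in initial_state}
        expected = lin.cells_alive_at(tree, start)
        if set(cells) != expected:
            raise ConfigurationError(
                f"initial cells {sorted(cells)} != lineage cells alive at t={start} "
                f"({sorted(expected)})"
            )

    end = config.end_time
    if end is None:
        end = max(
            [n.division_time for n in tree if n.division_time is not None] + [start]
        )
    schedule = tree.division_schedule()
    traj = Trajectory()

    for t in range(start, end + 1, config.time_step):
        due = [e for e in schedule if e.time == t]
        for event in due:  # already lexicographic within a time
            if event.dividing_cell not in cells:
                raise EmbryosimError(
                    f"t={t}: scheduled division of absent cell {event.dividing_cell}"
                )
            mother = cells.pop(event.dividing_cell)
            neighbors = [c for c in cells.values() if c.name != mother.name]
            if mother.polarity is None:
                mother.polarity = ap.copy()
            axis = dd.predict_axis(model, mother, neighbors, shell)
            if config.axis_noise_deg > 0:
                # deterministic seeded tilt: breaks the collinear degeneracy a
                # noise-free axis model would lock the embryo into (all cells
                # on one line, a saddle the relaxation cannot leave)
                axis = mech.tilt_vector(axis, config.axis_noise_deg, rng)
            plus, minus = mech.place_daughters(
                mother, axis, config.offset_fraction
            )
            # anterior daughter on the hemisphere the axis shares with AP
            anterior, posterior = lin.daughter_names(mother.name, axis, ap)
            if float(axis @ ap) >= 0:
                named = {anterior: plus, posterior: minus}
            else:
                named = {anterior: minus, posterior: plus}
            expected = set(event.daughter_names)
            if set(named) != expected:
                raise EmbryosimError(
                    f"t={t}: lineage daughters {sorted(expected)} != "
                    f"naming convention {sorted(named)}"
                )
            for name, cell in named.items():
                cell.name = name
                cell.polarity = axis.copy()
                cells[name] = cell
            logger.info(
                "t=%d division %s -> %s along axis (%.3f, %.3f, %.3f)",
                t, mother.name, "+".join(sorted(named)), *axis,
            )
            traj.events.append(
                DivisionRecord(t, mother.name, tuple(sorted(named)), tuple(axis))
            )

        ordered = [cells[name] for name in sorted(cells)]
        _jitter_coincident(ordered, rng)
        if due or not traj.snapshots:
            net = mech.build_neighbor_graph(
                ordered, config.contact_factor, config.spring_k
            )
            try:
                positions, _ = mech.relax_to_equilibrium(
                    net,
                    shell,
                    k_shell=config.shell_k,
                    tol_grad=config.tol_grad,
                    max_iter=config.max_iter,
                )
            except EmbryosimError as exc:
                raise EmbryosimError(f"t={t}: {exc}") from exc
            for cell, pos in zip(ordered, positions):
                cell.position = pos
        traj.times.append(t)
        traj.snapshots.append([c.copy() for c in ordered])

        expected_alive = lin.cells_alive_at(tree, t)
        if set(cells) != expected_alive:
            raise EmbryosimError(
                f"t={t}: live cells {sorted(cells)} != lineage {sorted(expected_alive)}"
            )
    return traj


def _jitter_coincident(cells: Sequence[mech.Cell], rng: np.random.Generator) -> None:
    """Separate exactly coincident cells by 1e-6 um so springs have a direction."""
    for i, a in enumerate(cells):
        for b in cells[i + 1:]:
            if np.array_equal(a.position, b.position):
                shift = rng.normal(size=3)
                shift *= 1e-6 / np.linalg.norm(shift)
                b.position = b.position + shift
                logger.warning(
                    "coincident cells %s and %s jittered by 1e-6 um", a.name, b.name
                )


def write_trajectory(traj: Trajectory, path) -> None:
    """Write the nuclei time-series table (time,name,x,y,z,radius)."""
    mech.write_nuclei_table(traj.frames(), path)


def read_trajectory(path) -> Trajectory:
    """Read a nuclei table back into a Trajectory (no event log in the file)."""
    traj = Trajectory()
    for t, cells in mech.read_nuclei_table(path):
        traj.times.append(int(t))
        traj.snapshots.append(cells)
    return traj
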