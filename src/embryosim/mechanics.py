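"""Quasi-equilibrium spring-mass mechanics of the early embryo.

Each cell is a point mass; contacting neighbors are joined by linear
springs with rest length equal to the sum of their radii; the rigid
eggshell is an ellipsoidal one-sided quadratic penalty. Inertia and
damping are neglected — mechanical relaxation is fast relative to the
1-minute observation cadence — so at every observation step the cell
positions are taken to minimize the total potential energy:

    E(x) = sum_edges 1/2 k (|x_i - x_j| - L0)^2
         + sum_cells 1/2 k_shell max(0, g(x_i) + rho_i - 1)^2

where g(x) = sqrt(((x-c)_1/a)^2 + ((x-c)_2/b)^2 + ((x-c)_3/c)^2) is the
normalized ellipsoid coordinate and rho_i = r_i * g(x_i)/|x_i - c| is the
cell radius rescaled to normalized units along the ray from the shell
center through the cell (exact on that ray: g(x + r x/|x|) = g(x) + rho).
A cell whose surface pokes through the shell (g + rho > 1) is pushed back;
cells strictly inside feel nothing.

Minimization is delegated to L-BFGS-B with the analytic gradient; the
contract is only that the returned configuration meets the gradient
tolerance and never exceeds the starting energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .errors import ConvergenceError, DegeneracyError

logger = logging.getLogger(__name__)

#: Defaults for the spring constants and tolerances; the observation data
#: constrain none of them, so they are exposed in the simulation config.
DEFAULT_K = 1.0           # spring stiffness, energy / um^2
DEFAULT_K_SHELL = 10.0    # eggshell penalty stiffness, energy (normalized coords)
DEFAULT_CONTACT_FACTOR = 1.2
DEFAULT_TOL_GRAD = 1e-6   # energy / um
DEFAULT_MAX_ITER = 10_000

NUCLEI_COLUMNS = ["time", "name", "x", "y", "z", "radius"]


@dataclass
class Cell:
    """A cell agent: point position, effective radius, optional polarity."""

    name: str
    position: np.ndarray
    radius: float
    polarity: Optional[np.ndarray] = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError(f"{self.name}: radius must be positive")
        if self.polarity is not None:
            self.polarity = np.asarray(self.polarity, dtype=float).reshape(3)
            n = np.linalg.norm(self.polarity)
            if abs(n - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: polarity must be unit norm")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    def copy(self) -> "Cell":
        return Cell(
            self.name,
            self.position.copy(),
            self.radius,
            None if self.polarity is None else self.polarity.copy(),
        )


@dataclass(frozen=True)
class EggshellEllipsoid:
    """Rigid ellipsoidal eggshell, semi-axes in um, a >= b >= c."""

    semi_axes: tuple[float, float, float] = (25.0, 15.0, 15.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError("semi-axes must satisfy a >= b >= c > 0")

    def normalized_coord(self, x: np.ndarray) -> np.ndarray:
        """g(x) for one point or a stack of points."""
        y = (np.atleast_2d(np.asarray(x, float)) - np.asarray(self.center)) / np.asarray(
            self.semi_axes
        )
        g = np.linalg.norm(y, axis=1)
        return g if np.asarray(x).ndim > 1 else g[0]

    def normalized_radius(self, x: np.ndarray, radius: float) -> float:
        """Cell radius in normalized units along the central ray through x."""
        y = np.asarray(x, float) - np.asarray(self.center)
        d = np.linalg.norm(y)
        if d == 0.0:
            return 0.0
        return radius * float(self.normalized_coord(x)) / d

    def overlap(self, x: np.ndarray, radius: float) -> float:
        """g(x) + rho - 1; positive when the cell pokes through the shell."""
        return float(self.normalized_coord(x)) + self.normalized_radius(x, radius) - 1.0

    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class SpringEdge:
    i: int
    j: int
    stiffness: float
    rest_length: float

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-edges are not allowed")
        if self.stiffness <= 0 or self.rest_length <= 0:
            raise ValueError("stiffness and rest length must be positive")


@dataclass
class SpringNetwork:
    """Cells plus the spring edges connecting contacting pairs."""

    cells: list[Cell]
    edges: list[SpringEdge] = field(default_factory=list)

    def positions(self) -> np.ndarray:
        return np.array([c.position for c in self.cells], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        return np.array([c.radius for c in self.cells], dtype=float)

    def index_of(self, name: str) -> int:
        for k, c in enumerate(self.cells):
            if c.name == name:
                return k
        raise KeyError(name)


# -- construction ------------------------------------------------------------


def build_neighbor_graph(
    cells: Sequence[Cell],
    contact_factor: float = DEFAULT_CONTACT_FACTOR,
    stiffness: float = DEFAULT_K,
) -> SpringNetwork:
    """Connect every pair of cells within contact range by a spring.

    Pair (i, j) is in contact iff |x_i - x_j| <= contact_factor*(r_i + r_j);
    the spring's rest length is r_i + r_j (just-touching separation). The
    observation data never define "neighboring", so a distance-threshold
    contact rule is used; it is rebuilt after every division.
    """
    if not cells:
        raise ValueError("need at least one cell")
    if contact_factor <= 0:
        raise ValueError("contact_factor must be positive")
    cells = list(cells)
    pos = np.array([c.position for c in cells]).reshape(-1, 3)
    radii = np.array([c.radius for c in cells])
    edges: list[SpringEdge] = []
    if len(cells) > 1:
        rmax = radii.max()
        tree = cKDTree(pos)
        for i, j in sorted(tree.query_pairs(r=contact_factor * 2.0 * rmax)):
            d = np.linalg.norm(pos[i] - pos[j])
            if d == 0.0:
                raise DegeneracyError(
                    f"cells {cells[i].name} and {cells[j].name} are coincident"
                )
            if d <= contact_factor * (radii[i] + radii[j]):
                edges.append(SpringEdge(i, j, stiffness, radii[i] + radii[j]))
    return SpringNetwork(cells, edges)


# -- energy and gradient ------------------------------------------------------


def potential_energy(
    net: SpringNetwork,
    shell: Optional[EggshellEllipsoid],
    positions: Optional[np.ndarray] = None,
    k_shell: float = DEFAULT_K_SHELL,
) -> float:
    """Total potential energy of the network at the given positions."""
    e, _ = energy_and_gradient(net, shell, positions, k_shell)
    return e


def energy_and_gradient(
    net: SpringNetwork,
    shell: Optional[EggshellEllipsoid],
    positions: Optional[np.ndarray] = None,
    k_shell: float = DEFAULT_K_SHELL,
) -> tuple[float, np.ndarray]:
    """Energy plus its analytic gradient d E / d x, shape (n, 3)."""
    x = net.positions() if positions is None else np.asarray(positions, float).reshape(-1, 3)
    if not np.all(np.isfinite(x)):
        raise ValueError("positions must be finite")
    grad = np.zeros_like(x)
    energy = 0.0

    for edge in net.edges:
        dx = x[edge.i] - x[edge.j]
        d = np.linalg.norm(dx)
        stretch = d - edge.rest_length
        energy += 0.5 * edge.stiffness * stretch**2
        if d > 0:
            f = edge.stiffness * stretch / d * dx
            grad[edge.i] += f
            grad[edge.j] -= f

    if shell is not None:
        axes = np.asarray(shell.semi_axes)
        center = np.asarray(shell.center)
        radii = net.radii()
        for k in range(len(x)):
            y = x[k] - center
            d = np.linalg.norm(y)
            if d == 0.0:
                continue  # at center: deep inside, no penalty
            u = y / axes
            g = np.linalg.norm(u)
            h = g * (1.0 + radii[k] / d)  # = g + rho
            if h <= 1.0:
                continue
            energy += 0.5 * k_shell * (h - 1.0) ** 2
            dg = y / (axes**2 * g)
            dh = dg * (1.0 + radii[k] / d) - g * radii[k] * y / d**3
            grad[k] += k_shell * (h - 1.0) * dh

    return float(energy), grad


# -- relaxation ---------------------------------------------------------------


def relax_to_equilibrium(
    net: SpringNetwork,
    shell: Optional[EggshellEllipsoid] = None,
    frozen: Iterable[str] = (),
    k_shell: float = DEFAULT_K_SHELL,
    tol_grad: float = DEFAULT_TOL_GRAD,
    max_iter: int = DEFAULT_MAX_ITER,
    pin_gauge: bool = True,
) -> tuple[np.ndarray, float]:
    """Minimize the potential energy; return (positions, final energy).

    Frozen cells keep their positions exactly. Without a shell the energy
    is invariant under rigid motions, so (unless the caller froze cells)
    the first cell is pinned and the second restricted to the line joining
    it to the first — enough to make small-system minima unique without
    affecting any inter-cell distance.
    """
    frozen = set(frozen)
    n = len(net.cells)
    if n - len(frozen) < 1:
        raise ValueError("need at least one unfrozen cell")
    x0 = net.positions()
    e0, _ = energy_and_gradient(net, shell, x0, k_shell)

    fixed = np.zeros(n, dtype=bool)
    for name in frozen:
        fixed[net.index_of(name)] = True

    line_idx = None  # (cell index, unit direction, anchor)
    if shell is None and not frozen and pin_gauge and n >= 2:
        fixed[0] = True
        u = x0[1] - x0[0]
        norm = np.linalg.norm(u)
        if norm > 0:
            line_idx = (1, u / norm, x0[1].copy())

    free = [
        k for k in range(n) if not fixed[k] and (line_idx is None or k != line_idx[0])
    ]

    def unpack(theta: np.ndarray) -> np.ndarray:
        x = x0.copy()
        off = 0
        if line_idx is not None:
            k, u, anchor = line_idx
            x[k] = anchor + theta[0] * u
            off = 1
        if free:
            x[free] = theta[off:].reshape(-1, 3)
        return x

    def pack_grad(g: np.ndarray) -> np.ndarray:
        parts = []
        if line_idx is not None:
            _, u, _ = line_idx
            parts.append([float(g[line_idx[0]] @ u)])
        if free:
            parts.append(g[free].ravel())
        return np.concatenate(parts) if parts else np.zeros(0)

    theta0_parts = []
    if line_idx is not None:
        theta0_parts.append([0.0])
    if free:
        theta0_parts.append(x0[free].ravel())
    theta0 = np.concatenate(theta0_parts)

    def objective(theta):
        e, g = energy_and_gradient(net, shell, unpack(theta), k_shell)
        return e, pack_grad(g)

    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": max_iter,
            "gtol": tol_grad * 1e-2,
            "ftol": 1e-16,
            "maxls": 100,
        },
    )
    x_final = unpack(res.x)
    e_final, g_final = energy_and_gradient(net, shell, x_final, k_shell)
    g_final[fixed] = 0.0
    if line_idx is not None:
        # only the along-line component is a true degree of freedom
        k, u, _ = line_idx
        g_final[k] = (g_final[k] @ u) * u
    gmax = float(np.abs(g_final).max()) if n else 0.0
    if gmax > tol_grad or e_final > e0 + 1e-12:
        raise ConvergenceError(
            f"relaxation did not converge (|grad|_max={gmax:.3e}, "
            f"E0={e0:.6e}, E={e_final:.6e})",
            positions=x_final,
            energy=e_final,
            grad_norm=gmax,
        )
    return x_final, e_final


# -- division geometry --------------------------------------------------------


def rodrigues_rotation(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate ``v`` by ``angle`` radians about the unit vector ``axis``."""
    v = np.asarray(v, float)
    axis = np.asarray(axis, float)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * (axis @ v) * (1 - np.cos(angle))
    )


def tilt_vector(
    v: np.ndarray, angle_scale_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Tilt a unit vector by a half-normal random angle about a random
    transverse axis (mean tilt = ``angle_scale_deg``)."""
    if angle_scale_deg <= 0:
        return np.asarray(v, float)
    v = np.asarray(v, float)
    t = rng.normal(size=3)
    t = t - (t @ v) * v
    while np.linalg.norm(t) < 1e-9:
        t = rng.normal(size=3)
        t = t - (t @ v) * v
    t /= np.linalg.norm(t)
    angle = abs(rng.normal(0.0, np.deg2rad(angle_scale_deg) * np.sqrt(np.pi / 2.0)))
    out = rodrigues_rotation(v, t, angle)
    return out / np.linalg.norm(out)


def place_daughters(
    mother: Cell, direction: Sequence[float], offset_fraction: float = 0.5
) -> tuple[Cell, Cell]:
    """Split a mother into two equal-volume daughters along ``direction``.

    Daughters sit at mother.position +/- offset_fraction*r*direction with
    radius r / 2^(1/3), conserving total volume exactly. They inherit the
    mother's polarity; the caller may overwrite it (e.g. with the division
    axis chosen by the direction model).
    """
    d = np.asarray(direction, dtype=float).reshape(3)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("division direction must be nonzero")
    d = d / norm
    if not 0 < offset_fraction <= 1:
        raise ValueError("offset_fraction must be in (0, 1]")
    r_daughter = mother.radius / 2.0 ** (1.0 / 3.0)
    offset = offset_fraction * mother.radius * d
    pol = None if mother.polarity is None else mother.polarity.copy()
    plus = Cell(mother.name + "+", mother.position + offset, r_daughter, pol)
    minus = Cell(
        mother.name + "-",
        mother.position - offset,
        r_daughter,
        None if pol is None else pol.copy(),
    )
    return plus, minus


# -- nuclei time-series table -------------------------------------------------


def write_nuclei_table(frames: Iterable[tuple[float, Sequence[Cell]]], path) -> None:
    """Write an AceTree-style nuclei table: time,name,x,y,z,radius (um)."""
    rows = []
    for t, cells in frames:
        for c in cells:
            x, y, z = c.position
            rows.append(
                {"time": t, "name": c.name, "x": x, "y": y, "z": z, "radius": c.radius}
            )
    pd.DataFrame(rows, columns=NUCLEI_COLUMNS).to_csv(path, index=False)


def read_nuclei_table(path) -> list[tuple[float, list[Cell]]]:
    """Read the nuclei table back into per-time-point cell lists.

    Extra columns are tolerated and ignored.
    """
    df = pd.read_csv(path)
    missing = [c for c in NUCLEI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"nuclei table missing columns: {missing}")
    frames = []
    for t, group in df.groupby("time", sort=True):
        cells = [
            Cell(str(r.name), np.array([r.x, r.y, r.z]), float(r.radius))
            for r in group.itertuples(index=False)
        ]
        frames.append((float(t), cells))
    return frames
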