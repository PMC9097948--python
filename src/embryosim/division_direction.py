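"""Cell-division axis model: weighted combination of three direction cues.

The axis along which a mother cell divides is modeled as the normalized
combination of three unit 3-vectors:

  * ``p`` — the dominant polarity of the dividing cell,
  * ``s`` — the composite of cell-cell squeeze directions from its
    contacting neighbors (zero when nothing overlaps),
  * ``e`` — the cell-eggshell squeeze direction (zero when the cell does
    not press on the shell),

each weighted by a nonnegative coefficient:

    d_pred = normalize(K_p * p + K_s * s + K_e * e).

The coefficients are fitted to observed division axes by minimizing the
summed angular error sum_i arccos(|d_pred,i . d_obs,i|). Division axes are
undirected lines (microscopy cannot orient them consistently), hence the
absolute dot product. The objective is invariant to positive rescaling of
K, so the gauge ||K||_1 = 1, K >= 0 is imposed for identifiability.

The squeeze-vector functional forms (overlap-weighted repulsion and the
inward ellipsoid normal) are modeling choices of this package; the cues
themselves are only named, not specified, by the observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import DegeneracyError, UnderdeterminedFitWarning
from .mechanics import Cell, EggshellEllipsoid

_UNIT_TOL = 1e-6


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise DegeneracyError("cannot normalize a zero vector")
    return v / n


@dataclass(frozen=True)
class DirectionComponents:
    """The three direction cues for one division. s and e may be zero."""

    p: np.ndarray
    s: np.ndarray
    e: np.ndarray

    def __post_init__(self):
        for label in ("p", "s", "e"):
            v = np.asarray(getattr(self, label), dtype=float).reshape(3)
            object.__setattr__(self, label, v)
            n = np.linalg.norm(v)
            if label == "p" and abs(n - 1.0) > _UNIT_TOL:
                raise ValueError("polarity component must be unit norm")
            if label != "p" and n > 0 and abs(n - 1.0) > _UNIT_TOL:
                raise ValueError(f"nonzero component {label} must be unit norm")

    def matrix(self) -> np.ndarray:
        """Columns [p s e]: compose_direction(K) = normalize(matrix @ K)."""
        return np.column_stack([self.p, self.s, self.e])


@dataclass(frozen=True)
class ObservedDivision:
    name: str
    components: DirectionComponents
    observed_axis: np.ndarray

    def __post_init__(self):
        axis = np.asarray(self.observed_axis, dtype=float).reshape(3)
        if abs(np.linalg.norm(axis) - 1.0) > _UNIT_TOL:
            raise ValueError(f"{self.name}: observed axis must be unit norm")
        object.__setattr__(self, "observed_axis", axis)


@dataclass(frozen=True)
class DivisionDirectionModel:
    """Fitted coefficients (K_p, K_s, K_e) on the unit simplex."""

    K: np.ndarray
    objective: Optional[float] = None
    n_observations: Optional[int] = None

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float).reshape(3)
        if np.any(K < -1e-12):
            raise ValueError("coefficients must be nonnegative")
        K = np.clip(K, 0.0, None)
        total = K.sum()
        if total == 0:
            raise ValueError("coefficients cannot all be zero")
        object.__setattr__(self, "K", K / total)

    def to_dict(self) -> dict:
        return {
            "K_p": float(self.K[0]),
            "K_s": float(self.K[1]),
            "K_e": float(self.K[2]),
            "objective": self.objective,
            "n_observations": self.n_observations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DivisionDirectionModel":
        return cls(
            np.array([d["K_p"], d["K_s"], d["K_e"]]),
            objective=d.get("objective"),
            n_observations=d.get("n_observations"),
        )


# -- geometric cues -----------------------------------------------------------


def neighbor_squeeze_vector(cell: Cell, neighbors: Sequence[Cell]) -> np.ndarray:
    """Composite cell-cell squeeze direction: overlap-weighted repulsion.

    Each overlapping neighbor pushes the cell away along their separation,
    weighted by the overlap depth max(0, (r + r_j) - d). Returns the zero
    vector when no neighbor overlaps (nothing squeezes).
    """
    total = np.zeros(3)
    for nb in neighbors:
        sep = cell.position - nb.position
        d = np.linalg.norm(sep)
        if d == 0.0:
            raise DegeneracyError(f"neighbor {nb.name} coincides with {cell.name}")
        w = max(0.0, (cell.radius + nb.radius) - d)
        total += w * sep / d
    n = np.linalg.norm(total)
    if n < 1e-12:
        return np.zeros(3)
    return total / n


def eggshell_squeeze_vector(
    cell: Cell, shell: EggshellEllipsoid, contact_threshold: float = 1.0
) -> np.ndarray:
    """Inward shell normal at the cell's radial projection, if pressing.

    Returns zero when the cell does not reach the shell
    (g + rho <= contact_threshold) or sits exactly at the center, where
    the projection direction is undefined.
    """
    y = cell.position - np.asarray(shell.center)
    d = np.linalg.norm(y)
    if d == 0.0:
        return np.zeros(3)
    g = float(shell.normalized_coord(cell.position))
    if g + shell.normalized_radius(cell.position, cell.radius) <= contact_threshold:
        return np.zeros(3)
    # radial projection onto the shell surface, then the inward unit normal
    q = y / g
    axes = np.asarray(shell.semi_axes)
    outward = q / axes**2
    return -_normalize(outward)


# -- composition and fitting --------------------------------------------------


def compose_direction(
    model: DivisionDirectionModel | np.ndarray, c: DirectionComponents
) -> np.ndarray:
    """normalize(K_p p + K_s s + K_e e)."""
    K = model.K if isinstance(model, DivisionDirectionModel) else np.asarray(model, float)
    v = c.matrix() @ K
    if np.linalg.norm(v) < 1e-12:
        raise DegeneracyError("weighted component combination is zero")
    return v / np.linalg.norm(v)


def angle_error(d_pred: np.ndarray, d_obs: np.ndarray) -> float:
    """Angle in [0, pi/2] between two undirected axes."""
    d_pred = np.asarray(d_pred, float)
    d_obs = np.asarray(d_obs, float)
    for v in (d_pred, d_obs):
        if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
            raise ValueError("angle_error expects unit vectors")
    return float(np.arccos(min(1.0, abs(float(d_pred @ d_obs)))))


def _objective_terms(observations: Sequence[ObservedDivision]):
    M = np.stack([o.components.matrix() for o in observations])  # (n, 3, 3)
    D = np.stack([o.observed_axis for o in observations])  # (n, 3)
    return M, D


def _summed_angle_error(K: np.ndarray, M: np.ndarray, D: np.ndarray) -> float:
    v = M @ K  # (n, 3)
    norms = np.linalg.norm(v, axis=1)
    norms = np.where(norms < 1e-12, np.inf, norms)  # degenerate rows score pi/2
    cosines = np.abs(np.einsum("ij,ij->i", v, D)) / norms
    return float(np.arccos(np.clip(cosines, 0.0, 1.0)).sum())


def fit_coefficients(
    observations: Sequence[ObservedDivision],
    n_starts: int = 16,
    seed: int = 0,
) -> tuple[DivisionDirectionModel, float]:
    """Fit K on the simplex by minimizing the summed angular error.

    Multi-start Nelder-Mead over an unconstrained parametrization
    K = z^2 / ||z^2||_1 (automatically nonnegative and normalized); the
    simplex corners and center are always among the starts, the rest are
    seeded Dirichlet draws. The best objective across starts is kept. The
    objective surface is cone-like near a perfect fit (arccos|cos| is not
    smooth there), which a simplex search handles where gradient methods
    stall.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("need at least one observation")
    kept = []
    for o in observations:
        if np.linalg.norm(o.components.matrix()) < 1e-12:
            warnings.warn(
                f"observation {o.name!r} has all-zero components; rejected",
                UserWarning,
                stacklevel=2,
            )
        else:
            kept.append(o)
    if not kept:
        raise ValueError("no usable observations (all components zero)")
    if len(kept) < 3:
        warnings.warn(
            f"only {len(kept)} observation(s); the coefficient fit is underdetermined",
            UnderdeterminedFitWarning,
            stacklevel=2,
        )
    M, D = _objective_terms(kept)

    def f(z: np.ndarray) -> float:
        K = z**2
        total = K.sum()
        if total < 1e-300:
            return np.pi / 2 * len(kept)
        return _summed_angle_error(K / total, M, D)

    rng = np.random.default_rng(seed)
    starts = [
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
        np.array([0.0, 0.0, 1.0]),
        np.full(3, 1.0 / 3.0),
    ]
    while len(starts) < max(n_starts, len(starts)):
        starts.append(rng.dirichlet(np.ones(3)))

    # coarse pass over all starts, then polish only the winner: the simplex
    # search crawls near the cone-shaped optimum, so tight tolerances on
    # every start would dominate the cost without changing the answer
    best_z, best_obj = None, np.inf
    for K0 in starts[: max(n_starts, 4)]:
        res = minimize(
            f,
            np.sqrt(K0),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 400},
        )
        if res.fun < best_obj:
            best_obj = float(res.fun)
            best_z = res.x
    res = minimize(
        f,
        best_z,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
    )
    if res.fun <= best_obj:
        best_z = res.x
    K = best_z**2
    best_K = K / K.sum()

    # report the objective evaluated at the *returned* (clipped, normalized)
    # K, so recomputing it from the model reproduces it exactly; arccos near
    # a perfect fit amplifies last-bit rounding to ~1e-7, so the optimizer's
    # own best function value can differ from this at that level
    model = DivisionDirectionModel(best_K, n_observations=len(kept))
    objective = _summed_angle_error(model.K, M, D)
    model = DivisionDirectionModel(model.K, objective=objective, n_observations=len(kept))
    return model, objective


def summed_angle_error(
    model: DivisionDirectionModel, observations: Sequence[ObservedDivision]
) -> float:
    """Recompute the fit objective for a given model."""
    M, D = _objective_terms(list(observations))
    return _summed_angle_error(model.K, M, D)


def predict_axis(
    model: DivisionDirectionModel,
    cell: Cell,
    neighbors: Sequence[Cell],
    shell: Optional[EggshellEllipsoid] = None,
) -> np.ndarray:
    """Forward prediction: compose the cues computed from current geometry."""
    if cell.polarity is None:
        raise ValueError(f"{cell.name}: predict_axis requires a polarity")
    s = neighbor_squeeze_vector(cell, neighbors)
    e = np.zeros(3) if shell is None else eggshell_squeeze_vector(cell, shell)
    comps = DirectionComponents(cell.polarity, s, e)
    return compose_direction(model, comps)


# -- observation table --------------------------------------------------------

OBSERVATION_COLUMNS = [
    "name",
    "px", "py", "pz",
    "sx", "sy", "sz",
    "ex", "ey", "ez",
    "dx", "dy", "dz",
]


def save_observations(observations: Sequence[ObservedDivision], path) -> None:
    rows = []
    for o in observations:
        c = o.components
        rows.append(
            dict(
                zip(
                    OBSERVATION_COLUMNS,
                    [o.name, *c.p, *c.s, *c.e, *o.observed_axis],
                )
            )
        )
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, index=False)


def load_observations(path) -> list[ObservedDivision]:
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    out = []
    for r in df.itertuples(index=False):
        comps = DirectionComponents(
            np.array([r.px, r.py, r.pz]),
            np.array([r.sx, r.sy, r.sz]),
            np.array([r.ex, r.ey, r.ez]),
        )
        out.append(ObservedDivision(str(r.name), comps, np.array([r.dx, r.dy, r.dz])))
    return out
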