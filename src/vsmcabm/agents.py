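"""Cell agents and the per-tick reorientation rules.

Each vascular smooth muscle cell is a circular agent with a position (fixed
for its lifetime), an orientation axis, an age in hours and a radius.  Per
tick a cell senses two cues -- the strain-avoidance axis derived from the
applied cyclic strain and the local fiber axis -- blends them into a desired
orientation, and rotates toward it by a bounded step.

The blend weight is a logistic function of the fiber density ``phi_f``: on a
bare elastomer (``phi_f = 0``) strain avoidance dominates, on dense tissue
(``phi_f = 1``) the fiber axis dominates, and ``phi_thres`` / ``slope_m``
place and sharpen the crossover.  The rotation *speed* switches regime at
``phi_thres`` as well: below it the step is ``z_eff * k_rot_c`` (strain
drive), at or above it ``|sin(theta_f - theta_cell)| * k_rot_f`` (fiber
drive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import axial_difference, wrap_axial

__all__ = [
    "CellAgent",
    "ReorientationParams",
    "Population",
    "structure_weight",
    "desired_angle",
    "rotation_step",
    "apply_rotation",
]


@dataclass(frozen=True)
class ReorientationParams:
    """Rate and threshold constants of the reorientation rules.

    ``k_rot_c`` and ``k_rot_f`` are rotation rates (radians per tick) in the
    strain and fiber regimes.  ``eps_thres`` / ``eps_max`` bound the linear
    window of the effective stimulus.  ``phi_thres`` and ``slope_m`` shape the
    strain-vs-fiber crossover; they cannot be constrained by experiments in
    which ``phi_f`` is only ever 0 or 1, so their defaults are placeholders
    for intermediate-density scenarios (see ``docs/methods.md``).
    """

    k_rot_c: float = 0.001
    k_rot_f: float = 0.1
    phi_thres: float = 0.5
    slope_m: float = 10.0
    eps_thres: float = 0.0
    eps_max: float = 0.4

    def __post_init__(self):
        if self.k_rot_c < 0 or self.k_rot_f < 0:
            raise ValueError("rotation constants must be non-negative")
        if not 0.0 <= self.phi_thres <= 1.0:
            raise ValueError("phi_thres must lie in [0, 1]")
        if self.slope_m <= 0:
            raise ValueError("slope_m must be positive")


@dataclass(frozen=True)
class CellAgent:
    """Read-only snapshot of a single cell."""

    cell_id: int
    x: float
    y: float
    theta: float
    age: float
    radius: float


class Population:
    """Struct-of-arrays container for the live cell population.

    Cells are stored in creation (id) order; removals preserve order, which
    fixes the iteration order of every stochastic sweep and hence makes runs
    bit-reproducible under a fixed seed.
    """

    def __init__(self, radius: float):
        if radius <= 0:
            raise ValueError("cell radius must be positive")
        self.radius = float(radius)
        self.ids = np.empty(0, dtype=np.int64)
        self.x = np.empty(0, dtype=float)
        self.y = np.empty(0, dtype=float)
        self.theta = np.empty(0, dtype=float)
        self.age = np.empty(0, dtype=float)
        self.theta_f = np.empty(0, dtype=float)
        self._next_id = 0

    @property
    def n(self) -> int:
        return self.ids.size

    def add(self, x, y, theta, age, theta_f) -> np.ndarray:
        """Append cells; returns their assigned ids."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        k = x.size
        new_ids = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        self._next_id += k
        self.ids = np.concatenate([self.ids, new_ids])
        self.x = np.concatenate([self.x, x])
        self.y = np.concatenate([self.y, np.atleast_1d(np.asarray(y, dtype=float))])
        self.theta = np.concatenate(
            [self.theta, wrap_axial(np.atleast_1d(np.asarray(theta, dtype=float)))]
        )
        self.age = np.concatenate([self.age, np.atleast_1d(np.asarray(age, dtype=float))])
        self.theta_f = np.concatenate(
            [self.theta_f, np.atleast_1d(np.asarray(theta_f, dtype=float))]
        )
        return new_ids

    def keep(self, mask: np.ndarray) -> None:
        """Retain only cells where ``mask`` is True (order preserved)."""
        for name in ("ids", "x", "y", "theta", "age", "theta_f"):
            setattr(self, name, getattr(self, name)[mask])

    def agent(self, index: int) -> CellAgent:
        return CellAgent(
            cell_id=int(self.ids[index]),
            x=float(self.x[index]),
            y=float(self.y[index]),
            theta=float(self.theta[index]),
            age=float(self.age[index]),
            radius=self.radius,
        )

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def min_neighbor_distance(self) -> float:
        """Smallest centre-to-centre distance between any two live cells."""
        if self.n < 2:
            return float("inf")
        from scipy.spatial import cKDTree

        tree = cKDTree(self.positions())
        dists, _ = tree.query(self.positions(), k=2)
        return float(dists[:, 1].min())

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.ids,
                "x": self.x,
                "y": self.y,
                "theta": self.theta,
                "age": self.age,
            }
        )


def structure_weight(phi_f, phi_thres: float, slope_m: float):
    """Weight of the strain cue in the desired-angle blend, in (0, 1).

    ``w = 1 / (1 + M^(10 * (phi_f - phi_thres)))``: close to 1 when fibers
    are sparse (strain dominates) and close to 0 when fibers are dense.
    """
    phi_f = np.asarray(phi_f, dtype=float)
    t = 10.0 * (phi_f - phi_thres) * np.log(slope_m)
    w = 1.0 / (1.0 + np.exp(np.clip(t, -700.0, 700.0)))
    return w if w.ndim else float(w)


def desired_angle(theta_f, theta_csa, phi_f, phi_thres: float, slope_m: float):
    """Orientation a cell is drawn toward given both cues.

    Interpolates from the fiber axis toward the strain-avoidance axis along
    the shortest axial arc, by the fiber-density weight.
    """
    theta_f = np.asarray(theta_f, dtype=float)
    w = structure_weight(phi_f, phi_thres, slope_m)
    out = wrap_axial(theta_f + axial_difference(theta_csa, theta_f) * w)
    return out if np.ndim(out) else float(out)


def rotation_step(theta_cell, theta_f, z_eff, phi_f, params: ReorientationParams):
    """Unsigned magnitude of this tick's rotation (radians).

    Strain regime (``phi_f < phi_thres``): ``z_eff * k_rot_c``.
    Fiber regime (``phi_f >= phi_thres``; the tie goes to the fibers):
    ``|sin(theta_f - theta_cell)| * k_rot_f``, which vanishes smoothly as the
    cell aligns with the local fiber.
    """
    theta_cell = np.asarray(theta_cell, dtype=float)
    fiber = np.asarray(phi_f, dtype=float) >= params.phi_thres
    step = np.where(
        fiber,
        np.abs(np.sin(np.asarray(theta_f, dtype=float) - theta_cell)) * params.k_rot_f,
        np.asarray(z_eff, dtype=float) * params.k_rot_c,
    )
    return step if step.ndim else float(step)


def apply_rotation(theta_cell, theta_final, delta):
    """Rotate by at most ``delta`` toward ``theta_final`` along the shortest arc.

    The step is clamped to the remaining angular distance so a cell settles
    on its target instead of oscillating across it.
    """
    beta = axial_difference(theta_final, theta_cell)
    direction = np.where(np.asarray(beta) >= 0.0, 1.0, -1.0)
    step = np.minimum(np.asarray(delta, dtype=float), np.abs(beta))
    out = wrap_axial(np.asarray(theta_cell, dtype=float) + direction * step)
    return out if np.ndim(out) else float(out)
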