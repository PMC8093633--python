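"""Strain-dependent apoptosis and age-gated proliferation.

Cell turnover couples to the strain a cell actually experiences along its
own axis (its effective strain), which is what produces the headline
selective-turnover mechanism: cells parallel to the stretch see more strain,
die more and divide less; cells perpendicular to it see little strain and
outgrow them.

Apoptosis is a linear percentage probability per check,
``P_AP = (A_apop * eps + B_apop) / 100``; proliferation is gated by a
cumulative-Gaussian probability of the cell's age against its
strain-dependent doubling time ``T_d = A_prolif * eps^2 + B_prolif * eps +
C_prolif``.  Checks run on configurable tick cadences; the shipped cadences
are part of the frozen calibration (see ``docs/methods.md``).

Units: the apoptosis law takes strain in percent (a 10% cycle enters as 10)
and the doubling-time law takes fractional strain (0.10); both are
switchable per law and fixed at calibration time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .agents import Population

__all__ = [
    "TurnoverParams",
    "apoptosis_probability",
    "doubling_time",
    "proliferation_probability",
    "place_daughter",
    "apoptosis_sweep",
]

_UNITS = ("percent", "fraction")


@dataclass(frozen=True)
class TurnoverParams:
    """Constants of the apoptosis and proliferation laws.

    ``a_apop``/``b_apop`` are percent-probability coefficients per check;
    ``a_prolif``/``b_prolif``/``c_prolif`` give the doubling time in hours;
    ``sigma_prolif`` (hours) is its spread.  ``apoptosis_interval`` and
    ``proliferation_interval`` are check cadences in ticks.
    """

    a_apop: float = 1.0
    b_apop: float = 1.64
    a_prolif: float = 3500.0
    b_prolif: float = 500.0
    c_prolif: float = 71.0
    sigma_prolif: float = 9.0
    apop_strain_units: str = "percent"
    prolif_strain_units: str = "fraction"
    apoptosis_interval: int = 4
    proliferation_interval: int = 3
    min_doubling_time: float = 1.0

    def __post_init__(self):
        if self.c_prolif <= 0 or self.sigma_prolif <= 0:
            raise ValueError("c_prolif and sigma_prolif must be positive")
        if self.apop_strain_units not in _UNITS or self.prolif_strain_units not in _UNITS:
            raise ValueError(f"strain units must be one of {_UNITS}")
        if self.apoptosis_interval < 1 or self.proliferation_interval < 1:
            raise ValueError("check intervals must be >= 1 tick")


def _in_units(eps_cyc, units: str):
    eps = np.asarray(eps_cyc, dtype=float)
    return eps * 100.0 if units == "percent" else eps


def apoptosis_probability(eps_cyc, params: TurnoverParams):
    """Probability of apoptosis per check, in [0, 1].

    ``eps_cyc`` is the (fractional) cyclic strain experienced by the cell;
    it enters the linear law in the units ``params.apop_strain_units``.
    """
    e = _in_units(eps_cyc, params.apop_strain_units)
    p = np.clip((params.a_apop * e + params.b_apop) / 100.0, 0.0, 1.0)
    return p if p.ndim else float(p)


def doubling_time(eps_cyc, params: TurnoverParams):
    """Strain-dependent doubling time in hours (floored at a small positive value)."""
    e = _in_units(eps_cyc, params.prolif_strain_units)
    td = params.a_prolif * e**2 + params.b_prolif * e + params.c_prolif
    td = np.maximum(td, params.min_doubling_time)
    return td if td.ndim else float(td)


def proliferation_probability(t_age, td, sigma: float):
    """Cumulative-Gaussian division probability of age against doubling time.

    ``P = (1 + erf((t_age - T_d) / (sigma * sqrt(2)))) / 2`` -- essentially
    zero at age 0, one half at ``t_age = T_d`` and saturating at 1.  Used as
    a Bernoulli gate at each proliferation check.
    """
    t_age = np.asarray(t_age, dtype=float)
    p = 0.5 * (1.0 + erf((t_age - np.asarray(td, float)) / (float(sigma) * np.sqrt(2.0))))
    return p if p.ndim else float(p)


def place_daughter(
    population: Population,
    parent_index: int,
    width: float,
    height: float,
    rng: np.random.Generator,
):
    """Find a position for a daughter cell tangent to its parent.

    Candidate centres sit on the parent's contact circle (distance
    ``2 * R_c``) at one-degree increments.  A candidate is valid if it lies
    inside the domain and at least ``2 * R_c`` from every live cell's centre;
    one valid candidate is chosen uniformly at random.  Returns the ``(x, y)``
    position, or ``None`` when the parent is completely hemmed in -- cells
    only proliferate if there is space to do so.
    """
    r = population.radius
    px, py = population.x[parent_index], population.y[parent_index]
    psi = np.deg2rad(np.arange(360.0))
    cand = np.column_stack([px + 2.0 * r * np.cos(psi), py + 2.0 * r * np.sin(psi)])
    valid = (
        (cand[:, 0] >= 0.0)
        & (cand[:, 0] <= width)
        & (cand[:, 1] >= 0.0)
        & (cand[:, 1] <= height)
    )
    # Only cells within 4*R_c of the parent can conflict with any candidate.
    near = (np.abs(population.x - px) <= 4.0 * r) & (np.abs(population.y - py) <= 4.0 * r)
    if np.any(near):
        nx = population.x[near]
        ny = population.y[near]
        d2 = (cand[:, 0, None] - nx) ** 2 + (cand[:, 1, None] - ny) ** 2
        min_d2 = (2.0 * r) ** 2 * (1.0 - 1e-9)
        valid &= np.all(d2 >= min_d2, axis=1)
    choices = np.flatnonzero(valid)
    if choices.size == 0:
        return None
    return cand[choices[rng.integers(choices.size)]]


def apoptosis_sweep(
    population: Population,
    eps_eff,
    params: TurnoverParams,
    rng: np.random.Generator,
):
    """Remove each live cell independently with its apoptosis probability.

    Cells are evaluated in id order with one uniform draw each, which makes
    the sweep deterministic under a fixed generator state.  Returns the
    records of removed cells as ``(cell_id, x, y, theta, eps_eff)`` tuples.
    """
    if population.n == 0:
        return []
    p = np.broadcast_to(
        np.asarray(apoptosis_probability(eps_eff, params), dtype=float), (population.n,)
    )
    dead = rng.random(population.n) < p
    eps_arr = np.broadcast_to(np.asarray(eps_eff, dtype=float), (population.n,))
    removed = [
        (
            int(population.ids[i]),
            float(population.x[i]),
            float(population.y[i]),
            float(population.theta[i]),
            float(eps_arr[i]),
        )
        for i in np.flatnonzero(dead)
    ]
    population.keep(~dead)
    return removed
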