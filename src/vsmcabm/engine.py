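"""Simulation engine: seed, sense, reorient, apoptose, proliferate, record.

One tick represents one hour, so cell ages and doubling times (both in
hours) are commensurable with the tick counter.  Within a tick the sub-step
order is frozen: (1) every cell senses its cues and rotates, (2) the
apoptosis sweep runs (on its cadence), (3) ages advance and proliferation
trials with daughter placement run (on their cadence), (4) the state is
recorded.  Changing this order changes the stochastic trajectory and is a
breaking change.

Randomness is split into five independent streams (seeding, fiber field,
apoptosis, proliferation, placement) spawned from one seed, so that toggling
one mechanism does not shift the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .agents import (
    Population,
    ReorientationParams,
    apply_rotation,
    desired_angle,
    rotation_step,
)
from .angles import orientation_histogram, wrap_axial
from .fibers import FiberField, build_fiber_field
from .strain import (
    DEFAULT_CONVENTION,
    AppliedStrain,
    PrincipalStrain,
    effective_strain,
    effective_stimulus,
    mohr_decompose,
)
from .turnover import (
    TurnoverParams,
    apoptosis_sweep,
    doubling_time,
    place_daughter,
    proliferation_probability,
)

__all__ = [
    "FiberSpec",
    "SimulationConfig",
    "SimulationResult",
    "seed_population",
    "run",
    "fold_change",
]

_AGE_RULES = ("uniform_c_prolif", "uniform_c_times_sigma")


@dataclass(frozen=True)
class FiberSpec:
    """Recipe for the substrate's fiber field (absent on bare PDMS)."""

    mean_direction: float = 0.0
    kappa: float = 5.0
    density: float = 1.0
    n_interior: int = 200


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulation: geometry, cues, rates, seed.

    ``seeding_density`` is in cells/cm^2 (as cultures are reported);
    the domain is in micrometres.  ``initial_age_rule`` selects the spread of
    starting ages: uniform on ``[0, c_prolif]`` hours (default) or on
    ``[0, c_prolif * sigma_prolif]``.
    """

    width: float = 1000.0
    height: float = 1000.0
    seeding_density: float = 5.5e3
    cell_radius: float = 0.3888
    n_ticks: int = 72
    tick_hours: float = 1.0
    strain: AppliedStrain = field(default_factory=AppliedStrain)
    strain_convention: str = DEFAULT_CONVENTION
    fibers: Optional[FiberSpec] = None
    reorientation: ReorientationParams = field(default_factory=ReorientationParams)
    turnover: TurnoverParams = field(default_factory=TurnoverParams)
    initial_age_rule: str = "uniform_c_prolif"
    per_cell_strain: bool = True
    daughter_orientation: str = "inherit"  # or "uniform"
    seed: int = 0
    record_every: Optional[int] = None

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.n_ticks < 0:
            raise ValueError("n_ticks must be >= 0")
        if self.initial_age_rule not in _AGE_RULES:
            raise ValueError(f"initial_age_rule must be one of {_AGE_RULES}")
        if self.daughter_orientation not in ("inherit", "uniform"):
            raise ValueError("daughter_orientation must be 'inherit' or 'uniform'")
        if self.initial_cell_count() < 1:
            raise ValueError("seeding density times domain area must give >= 1 cell")

    def area_mm2(self) -> float:
        return self.width * self.height / 1.0e6

    def initial_cell_count(self) -> int:
        # cells/cm^2 -> cells/mm^2 is a factor of 100
        return int(round(self.seeding_density / 100.0 * self.area_mm2()))

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        """Build a config from a nested plain-data mapping (YAML-friendly).

        Recognised sections: ``domain`` (width, height, seeding_density,
        cell_radius), ``time`` (n_ticks, tick_hours), ``strain`` (x, y,
        shear two-element ranges plus ``convention``), ``fiber``
        (mean_deg, kappa, density, n_vertices), ``reorientation`` and
        ``turnover`` (field names as in the dataclasses), and top-level
        ``seed``, ``initial_age_rule``, ``record_every``.
        """
        kwargs: dict = {}
        domain = raw.get("domain", {})
        for key in ("width", "height", "seeding_density", "cell_radius"):
            if key in domain:
                kwargs[key] = domain[key]
        time = raw.get("time", {})
        for key in ("n_ticks", "tick_hours"):
            if key in time:
                kwargs[key] = time[key]
        strain = raw.get("strain", {})
        if strain:
            x = strain.get("x", [0.0, 0.0])
            y = strain.get("y", [0.0, 0.0])
            g = strain.get("shear", [0.0, 0.0])
            kwargs["strain"] = AppliedStrain(x[0], x[1], y[0], y[1], g[0], g[1])
            if "convention" in strain:
                kwargs["strain_convention"] = strain["convention"]
        fiber = raw.get("fiber")
        if fiber:
            kwargs["fibers"] = FiberSpec(
                mean_direction=np.deg2rad(fiber.get("mean_deg", 0.0)),
                kappa=fiber.get("kappa", 5.0),
                density=fiber.get("density", 1.0),
                n_interior=fiber.get("n_vertices", 200),
            )
        if "reorientation" in raw:
            kwargs["reorientation"] = ReorientationParams(**raw["reorientation"])
        if "turnover" in raw:
            kwargs["turnover"] = TurnoverParams(**raw["turnover"])
        for key in ("seed", "initial_age_rule", "record_every", "per_cell_strain",
                    "daughter_orientation"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def with_(self, **changes) -> "SimulationConfig":
        """Functional update helper (``dataclasses.replace`` wrapper)."""
        return replace(self, **changes)


@dataclass
class SimulationResult:
    """Recorded output of one run.

    ``counts[t]`` is the live cell count after tick ``t`` (``counts[0]`` is
    the seeded count).  ``events`` reconciles every birth and death;
    ``snapshots`` maps recorded ticks to full cell tables.
    """

    config: SimulationConfig
    seed: int
    principal: PrincipalStrain
    counts: np.ndarray
    events: pd.DataFrame
    snapshots: dict[int, pd.DataFrame]
    population: Population
    fiber_field: Optional[FiberField] = None

    def fold_change(self, tick: int) -> float:
        return fold_change(self, tick)

    def density_per_mm2(self, tick: int) -> float:
        """Live cell density (cells/mm^2) at a recorded tick."""
        return self.counts[self._check_tick(tick)] / self.config.area_mm2()

    def orientation_histogram(self, bin_width_deg: float = 10.0):
        """Histogram of final live-cell orientations (counts, deg edges)."""
        return orientation_histogram(self.population.theta, bin_width_deg)

    def _check_tick(self, tick: int) -> int:
        if not 0 <= tick < len(self.counts):
            raise ValueError(f"tick {tick} was not recorded (run had {len(self.counts) - 1} ticks)")
        return tick


def fold_change(result: SimulationResult, tick: int) -> float:
    """Live count at ``tick`` divided by the seeded count."""
    tick = result._check_tick(tick)
    return float(result.counts[tick]) / float(result.counts[0])


def seed_population(
    config: SimulationConfig,
    rng: np.random.Generator,
    fiber_field: Optional[FiberField] = None,
) -> Population:
    """Seed a monolayer of non-overlapping cells at the configured density.

    Positions are rejection-sampled uniformly; orientations are uniform
    axial angles; ages follow the configured initial-age rule.  Raises if
    the density is not achievable for the configured radius.
    """
    n = config.initial_cell_count()
    pop = Population(config.cell_radius)
    xs = np.empty(n)
    ys = np.empty(n)
    min_d2 = (2.0 * config.cell_radius) ** 2
    placed = 0
    attempts = 0
    max_attempts = 200 * n + 1000
    while placed < n:
        if attempts >= max_attempts:
            achievable = placed / config.area_mm2() * 100.0
            raise ValueError(
                "could not seed "
                f"{n} non-overlapping cells of radius {config.cell_radius} um; "
                f"achievable density is about {achievable:.3g} cells/cm^2"
            )
        attempts += 1
        x = rng.uniform(0.0, config.width)
        y = rng.uniform(0.0, config.height)
        if placed:
            d2 = (xs[:placed] - x) ** 2 + (ys[:placed] - y) ** 2
            if d2.min() < min_d2:
                continue
        xs[placed] = x
        ys[placed] = y
        placed += 1
    theta = wrap_axial(rng.uniform(-np.pi / 2.0, np.pi / 2.0, size=n))
    if config.initial_age_rule == "uniform_c_prolif":
        age_max = config.turnover.c_prolif
    else:
        age_max = config.turnover.c_prolif * config.turnover.sigma_prolif
    ages = rng.uniform(0.0, age_max, size=n)
    if fiber_field is not None:
        theta_f = fiber_field.query(np.column_stack([xs, ys]))
    else:
        theta_f = np.zeros(n)
    pop.add(xs, ys, theta, ages, theta_f)
    return pop


def run(config: SimulationConfig, seed: Optional[int] = None) -> SimulationResult:
    """Execute the tick loop and return the recorded result.

    ``seed`` overrides ``config.seed``.  Identical config and seed give a
    bit-identical result.
    """
    used_seed = int(config.seed if seed is None else seed)
    streams = np.random.SeedSequence(used_seed).spawn(5)
    rng_seed, rng_fiber, rng_apop, rng_prolif, rng_place = (
        np.random.default_rng(s) for s in streams
    )

    principal = mohr_decompose(config.strain, config.strain_convention)
    fiber_field = None
    phi_f = 0.0
    if config.fibers is not None:
        fiber_field = build_fiber_field(
            config.width,
            config.height,
            config.fibers.mean_direction,
            config.fibers.kappa,
            config.fibers.density,
            config.fibers.n_interior,
            rng_fiber,
        )
        phi_f = fiber_field.density

    pop = seed_population(config, rng_seed, fiber_field)
    params_r = config.reorientation
    params_t = config.turnover

    counts = np.empty(config.n_ticks + 1, dtype=np.int64)
    counts[0] = pop.n
    events: list[tuple] = []
    snapshots: dict[int, pd.DataFrame] = {0: pop.as_dataframe()}

    def cell_strain(theta):
        if config.per_cell_strain:
            return effective_strain(principal.eps_max, theta, principal.theta_p)
        return np.full(np.shape(theta), principal.eps_max)

    for tick in range(1, config.n_ticks + 1):
        # --- (1) sense cues and reorient -------------------------------
        if pop.n:
            eps_eff = cell_strain(pop.theta)
            z_eff = effective_stimulus(eps_eff, params_r.eps_thres, params_r.eps_max)
            theta_target = desired_angle(
                pop.theta_f, principal.theta_csa, phi_f, params_r.phi_thres, params_r.slope_m
            )
            delta = rotation_step(pop.theta, pop.theta_f, z_eff, phi_f, params_r)
            pop.theta = np.asarray(apply_rotation(pop.theta, theta_target, delta))

        # --- (2) apoptosis sweep ---------------------------------------
        if pop.n and tick % params_t.apoptosis_interval == 0:
            eps_eff = cell_strain(pop.theta)
            for rec in apoptosis_sweep(pop, eps_eff, params_t, rng_apop):
                events.append((tick, "death") + rec)

        # --- (3) ageing and proliferation ------------------------------
        pop.age = pop.age + config.tick_hours
        if pop.n and tick % params_t.proliferation_interval == 0:
            eps_eff = cell_strain(pop.theta)
            td = doubling_time(eps_eff, params_t)
            p_div = proliferation_probability(pop.age, td, params_t.sigma_prolif)
            dividing = np.flatnonzero(rng_prolif.random(pop.n) < p_div)
            for idx in dividing:
                spot = place_daughter(pop, idx, config.width, config.height, rng_place)
                if spot is None:
                    continue
                if config.daughter_orientation == "inherit":
                    d_theta = pop.theta[idx]
                else:
                    d_theta = wrap_axial(rng_place.uniform(-np.pi / 2.0, np.pi / 2.0))
                d_theta_f = (
                    fiber_field.query(spot[None, :])[0] if fiber_field is not None else 0.0
                )
                pop.age[idx] = 0.0
                new_id = pop.add(spot[0], spot[1], d_theta, 0.0, d_theta_f)[0]
                d_eps = float(cell_strain(np.asarray([d_theta]))[0])
                events.append(
                    (tick, "birth", int(new_id), float(spot[0]), float(spot[1]),
                     float(d_theta), d_eps)
                )

        # --- (4) record -------------------------------------------------
        counts[tick] = pop.n
        if config.record_every and tick % config.record_every == 0:
            snapshots[tick] = pop.as_dataframe()

    snapshots[config.n_ticks] = pop.as_dataframe()
    events_df = pd.DataFrame(
        events, columns=["tick", "event", "cell_id", "x", "y", "theta", "eps_eff"]
    )
    return SimulationResult(
        config=config,
        seed=used_seed,
        principal=principal,
        counts=counts,
        events=events_df,
        snapshots=snapshots,
        population=pop,
        fiber_field=fiber_field,
    )
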