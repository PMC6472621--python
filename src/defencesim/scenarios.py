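"""Stand construction, the daily simulation loop, and treatment suites.

Three named suites cover the factorial designs of the study:

* ``costs_i`` — direct and ecological costs: monostands and 50:50 mixtures
  of defended and undefended plants across five defence investments
  (D = 5..25%) and three herbivory regimes (none / low / high), with the
  defended plants receiving no benefit (d = 0, h = 0.2).
* ``benefits_ii`` — direct and ecological benefits: defended plants that pay
  no metabolic cost, across six damage reductions (d = 0..50%) and three
  herbivore distributions (h = 0.2, 0.5, 0.8), in monostands and mixtures,
  under low and high herbivory.
* ``net_iii`` — costs versus benefits: mixtures only, D = 15%, full
  (d, h) factorial under low and high herbivory.

Replicates differ only in the seeded multiplicative jitter on initial plant
size; everything else is deterministic, so a (config, seed) pair reproduces
a run bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .environment import ThermalClock, WeatherDay, weather_series
from .herbivory_defence import (
    HIGH_C,
    LOW_C,
    DefenceParams,
    HerbivoryParams,
    apply_herbivory,
)
from .params import SimParams
from .plant_growth import (
    Field,
    Genotype,
    Leaf,
    Plant,
    assimilate,
    build_canopy_profile,
    initiate_organs,
    intercept_light,
    maintain_and_allocate,
    rank_potential,
)
from .herbivory_defence import defence_tax

__all__ = [
    "D_GRID",
    "DAMAGE_REDUCTION_GRID",
    "H_GRID",
    "C_LEVELS",
    "STANDS",
    "SUITES",
    "ScenarioConfig",
    "RunResult",
    "build_field",
    "run_simulation",
    "run_cell",
    "suite_cells",
    "run_suite",
]

log = logging.getLogger(__name__)

#: Defence investment levels of the cost suite (% of gross assimilate).
D_GRID = (5.0, 10.0, 15.0, 20.0, 25.0)
#: Damage-reduction levels of the benefit suites (%).
DAMAGE_REDUCTION_GRID = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
#: Herbivore-distribution levels of the benefit suites.
H_GRID = (0.2, 0.5, 0.8)
#: Named herbivory regimes (base removal rate per GDD).
C_LEVELS = {"none": 0.0, "low": LOW_C, "high": HIGH_C}

STANDS = ("monostand_undefended", "monostand_defended", "mixture")
SUITES = ("costs_i", "benefits_ii", "net_iii", "custom")


@dataclass(frozen=True)
class ScenarioConfig:
    """One treatment cell: genotype parameters, stand layout and replication."""

    suite: str = "custom"
    stand: str = "monostand_undefended"
    D: float = 0.0           # defence investment, %
    c: float = 0.0           # herbivore base removal rate, per GDD
    d: float = 0.0           # damage reduction by defence, %
    h: float = 0.2           # herbivore distribution for defended plants
    pay_costs: bool = True   # benefit suite switches the metabolic cost off
    replicates: int = 10
    base_seed: int = 0
    jitter: bool = True
    params: SimParams = dc_field(default_factory=SimParams)

    def __post_init__(self) -> None:
        if self.suite not in SUITES:
            raise ValueError(f"unknown suite {self.suite!r}; expected one of {SUITES}")
        if self.stand not in STANDS:
            raise ValueError(f"unknown stand {self.stand!r}; expected one of {STANDS}")
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        # parameter ranges are validated by DefenceParams
        DefenceParams(D=self.D, d=self.d, h=self.h)
        if self.stand == "mixture" and self.params.plot_size % 2 != 0:
            raise ValueError("mixture stands need an even plot size for a 50:50 split")

    @property
    def regime(self) -> str:
        for name, c in C_LEVELS.items():
            if math.isclose(self.c, c):
                return name
        return "custom"

    @property
    def cell_id(self) -> str:
        return (
            f"{self.stand}|D={self.D:g}|c={self.c:g}|d={self.d:g}"
            f"|h={self.h:g}|pay={int(self.pay_costs)}"
        )

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RunResult:
    """Outcome of one replicate run: yields, trajectories and mass ledger."""

    config: ScenarioConfig
    seed: int
    yields: pd.DataFrame          # plant_id, genotype, seed_yield
    ledger: dict[str, float]      # whole-run mass balance totals
    damage_events: pd.DataFrame   # day, plant_id, rank, removed_g
    field: Field                  # final plant state
    series: pd.DataFrame | None = None   # optional per-day per-plant stream


def build_field(cfg: ScenarioConfig, seed: int) -> Field:
    """Lay out the plot (4x4 by default); mixtures alternate as a checkerboard.

    Initial plant size carries a seeded multiplicative lognormal jitter (the
    only source of replicate-to-replicate variance) unless ``cfg.jitter`` is
    off.
    """
    p = cfg.params
    rng = np.random.default_rng(seed)
    side = math.isqrt(p.plot_size)
    if side * side != p.plot_size:
        side = int(math.ceil(math.sqrt(p.plot_size)))
    defended = Genotype.defended_type(DefenceParams(D=cfg.D, d=cfg.d, h=cfg.h))
    undefended = Genotype.undefended()

    plants: list[Plant] = []
    for idx in range(p.plot_size):
        i, j = divmod(idx, side)
        if cfg.stand == "mixture":
            geno = defended if (i + j) % 2 == 0 else undefended
        elif cfg.stand == "monostand_defended":
            geno = defended
        else:
            geno = undefended
        factor = rng.lognormal(mean=0.0, sigma=p.jitter_sd) if cfg.jitter else 1.0
        stem = p.initial_stem * factor
        plant = Plant(
            genotype=geno,
            stem_biomass=stem,
            height=p.height_coef * stem ** p.height_exp,
            position=(i, j),
        )
        per_leaf = p.initial_biomass * factor / p.initial_leaves
        for rank in range(1, p.initial_leaves + 1):
            plant.leaves.append(
                Leaf(
                    rank_abs=rank,
                    biomass=per_leaf,
                    biomass_pot=rank_potential(rank, p),
                    sla=p.sla,
                    height=plant.height,
                )
            )
        plants.append(plant)
    if cfg.stand == "mixture":
        n_def = sum(pl.genotype.defended for pl in plants)
        if n_def * 2 != p.plot_size:
            raise ValueError("checkerboard layout did not produce a 50:50 mixture")
    return Field(
        plants=plants,
        plot_size=p.plot_size,
        density=p.density,
        clone_factor=p.clone_factor,
    )


def run_simulation(
    field: Field,
    cfg: ScenarioConfig,
    weather: Sequence[WeatherDay] | None = None,
    record_series: bool = False,
    seed: int = 0,
) -> RunResult:
    """Run the daily loop over the full season and return yields plus ledger.

    Daily order: weather -> canopy light partitioning -> assimilation ->
    defence tax (if costs are paid) -> maintenance and allocation -> leaf
    initiation -> herbivory. Herbivory acts after growth within the day.
    """
    p = cfg.params
    days = list(weather) if weather is not None else weather_series(p)
    clock = ThermalClock(t_base=p.t_base)
    hp = HerbivoryParams(c=cfg.c, regime=cfg.regime)
    undef_dp = DefenceParams.undefended()

    totals = {
        "assimilated": 0.0,
        "defence": 0.0,
        "maintenance": 0.0,
        "vegetative": 0.0,
        "seed": 0.0,
        "unallocated": 0.0,
        "herbivory_removed": 0.0,
        "deficit_days": 0.0,
    }
    initial_biomass = sum(pl.standing_biomass + pl.seed_biomass for pl in field.plants)

    series_rows: list[tuple] = []
    damage_rows: list[tuple] = []
    debug = log.isEnabledFor(logging.DEBUG)
    for day, wd in enumerate(days):
        gdd_inc = clock.advance(wd.temp)
        if debug:
            log.debug("day %d doy %d temp %.1f par %.1f gdd %.1f", day, wd.doy, wd.temp, wd.par, clock.gdd_cum)
        for plant in field.plants:
            plant.age_gdd += gdd_inc
            for leaf in plant.leaves:
                leaf.age_gdd += gdd_inc

        profile = build_canopy_profile(field, p.n_layers, p.k_ext)
        intercepted = intercept_light(profile, wd.par, field.ground_area)

        for i, plant in enumerate(field.plants):
            a_total = assimilate(float(intercepted[i]), p.lue)
            D = plant.genotype.defence.D if (plant.genotype.defended and cfg.pay_costs) else 0.0
            a_growth, tax = defence_tax(a_total, D)
            ledger = maintain_and_allocate(plant, a_growth, gdd_inc, p)
            totals["assimilated"] += a_total
            totals["defence"] += tax
            totals["maintenance"] += ledger["maintenance"]
            totals["vegetative"] += ledger["vegetative"]
            totals["seed"] += ledger["seed"]
            totals["unallocated"] += ledger["unallocated"]
            totals["deficit_days"] += ledger["deficit"]

            initiate_organs(plant, p)

            if cfg.c > 0.0:
                dp = plant.genotype.defence if plant.genotype.defended else undef_dp
                for ev in apply_herbivory(plant, hp, dp, gdd_inc, p.pot_reduction_mode):
                    totals["herbivory_removed"] += ev.removed
                    damage_rows.append((day, i, ev.rank, ev.removed))

            if not math.isfinite(plant.seed_biomass + plant.standing_biomass):
                raise RuntimeError(f"non-finite plant state on day {day}, plant {i}")

            if record_series:
                series_rows.append(
                    (
                        day,
                        wd.doy,
                        i,
                        plant.genotype.name,
                        plant.leaf_biomass,
                        plant.stem_biomass,
                        plant.seed_biomass,
                        float(intercepted[i]),
                        plant.height,
                        len(plant.leaves),
                    )
                )

    totals["initial_biomass"] = initial_biomass
    totals["final_biomass"] = sum(pl.standing_biomass + pl.seed_biomass for pl in field.plants)
    totals["gdd_total"] = clock.gdd_cum

    yields = pd.DataFrame(
        {
            "plant_id": range(len(field.plants)),
            "genotype": [pl.genotype.name for pl in field.plants],
            "seed_yield": [pl.seed_biomass for pl in field.plants],
        }
    )
    damage_events = pd.DataFrame(damage_rows, columns=["day", "plant_id", "rank", "removed_g"])
    series = None
    if record_series:
        series = pd.DataFrame(
            series_rows,
            columns=[
                "day",
                "doy",
                "plant_id",
                "genotype",
                "leaf_biomass",
                "stem_biomass",
                "seed_biomass",
                "intercepted_par",
                "height",
                "n_leaves",
            ],
        )
    return RunResult(
        config=cfg,
        seed=seed,
        yields=yields,
        ledger=totals,
        damage_events=damage_events,
        field=field,
        series=series,
    )


def run_cell(cfg: ScenarioConfig, seed: int, record_series: bool = False) -> RunResult:
    """Build the stand for one replicate and run it."""
    field = build_field(cfg, seed)
    return run_simulation(field, cfg, record_series=record_series, seed=seed)


def suite_cells(suite_id: str, params: SimParams | None = None) -> list[ScenarioConfig]:
    """Enumerate the treatment cells (including controls) of a named suite."""
    p = params or SimParams()
    base = ScenarioConfig(suite=suite_id, params=p)
    cells: list[ScenarioConfig] = []
    if suite_id == "costs_i":
        # controls and herbivory baselines: undefended monostands
        for c in C_LEVELS.values():
            cells.append(base.replace(stand="monostand_undefended", c=c))
        # defended monostands and mixtures, no benefit (d = 0, h = 0.2)
        for stand in ("monostand_defended", "mixture"):
            for D in D_GRID:
                for c in C_LEVELS.values():
                    cells.append(base.replace(stand=stand, D=D, c=c, d=0.0, h=0.2))
    elif suite_id == "benefits_ii":
        # undefended monostand baselines under each herbivory regime
        for c in (LOW_C, HIGH_C):
            cells.append(base.replace(stand="monostand_undefended", c=c))
        for stand in ("monostand_defended", "mixture"):
            for c in (LOW_C, HIGH_C):
                for d in DAMAGE_REDUCTION_GRID:
                    for h in H_GRID:
                        cells.append(
                            base.replace(stand=stand, c=c, d=d, h=h, pay_costs=False)
                        )
    elif suite_id == "net_iii":
        for c in (LOW_C, HIGH_C):
            for d in DAMAGE_REDUCTION_GRID:
                for h in H_GRID:
                    cells.append(base.replace(stand="mixture", D=15.0, c=c, d=d, h=h))
    else:
        raise ValueError(f"unknown suite {suite_id!r}")
    return cells


def run_suite(
    suite_id: str,
    replicates: int = 10,
    base_seed: int = 0,
    params: SimParams | None = None,
    cells: Sequence[ScenarioConfig] | None = None,
) -> pd.DataFrame:
    """Run every cell of a suite for all replicates; return a tidy plant table.

    One row per plant per replicate run, with the cell parameters attached.
    Per-replicate seeds derive from ``base_seed`` via a counter-based scheme
    (cell index, replicate index), so any cell can be re-run independently.
    """
    from .interface import derive_run_seed

    if cells is None:
        cells = suite_cells(suite_id, params)
    rows: list[dict] = []
    for cell_idx, cell in enumerate(cells):
        cfg = cell.replace(replicates=replicates, base_seed=base_seed)
        for rep in range(replicates):
            seed = derive_run_seed(base_seed, cell_idx, rep)
            result = run_cell(cfg, seed)
            for rec in result.yields.itertuples(index=False):
                rows.append(
                    {
                        "suite": suite_id,
                        "cell_id": cfg.cell_id,
                        "stand": cfg.stand,
                        "D": cfg.D,
                        "c": cfg.c,
                        "d": cfg.d,
                        "h": cfg.h,
                        "pay_costs": cfg.pay_costs,
                        "replicate": rep,
                        "seed": seed,
                        "plant_id": rec.plant_id,
                        "genotype": rec.genotype,
                        "seed_yield": rec.seed_yield,
                    }
                )
    return pd.DataFrame(rows)
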