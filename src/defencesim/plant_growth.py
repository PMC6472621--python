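"""Source-sink plant growth with mean-field layered-canopy light competition.

Each plant carries an ordered stack of ranked leaves, a stem and a seed pool.
Daily carbon gain is driven by light interception in a horizontally
homogeneous, vertically layered canopy: within each layer light attenuates by
Beer-Lambert extinction and the absorbed fraction is shared among plants in
proportion to their leaf area in that layer. Because taller plants place
leaves in higher layers, light competition is size-asymmetric: a plant that
falls behind in height loses light share faster than leaf-area share.

Assimilate is spent in a strict order each day: maintenance of standing
biomass first, then vegetative demands (leaf expansion toward each leaf's
potential biomass, stem growth), shifting progressively toward seed filling
after flowering. Every gram is accounted for in a ledger so whole-simulation
mass balance can be checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .herbivory_defence import DefenceParams
from .params import SimParams

__all__ = [
    "Leaf",
    "Genotype",
    "Plant",
    "Field",
    "CanopyProfile",
    "leaf_potential_growth",
    "rank_potential",
    "build_canopy_profile",
    "intercept_light",
    "assimilate",
    "maintain_and_allocate",
    "initiate_organs",
]


@dataclass
class Leaf:
    """A ranked lamina; the unit on which herbivore damage acts.

    ``biomass`` is realised lamina biomass (g), ``biomass_pot`` its ceiling.
    Herbivory lowers both, so regrowth can never exceed the reduced ceiling.
    Area is strictly proportional to biomass through SLA.
    """

    rank_abs: int            # 1 = oldest leaf
    biomass: float           # g
    biomass_pot: float       # g, potential (ceiling) biomass
    sla: float               # m^2 g^-1
    height: float = 0.0      # insertion height (m)
    age_gdd: float = 0.0     # thermal age since initiation

    @property
    def area(self) -> float:
        """Lamina area (m^2) = biomass * SLA."""
        return self.biomass * self.sla


@dataclass(frozen=True)
class Genotype:
    """Defended/undefended identity plus its defence parameters."""

    name: str
    defended: bool
    defence: DefenceParams

    @classmethod
    def undefended(cls) -> "Genotype":
        return cls(name="undefended", defended=False, defence=DefenceParams.undefended())

    @classmethod
    def defended_type(cls, defence: DefenceParams) -> "Genotype":
        return cls(name="defended", defended=True, defence=defence)


@dataclass
class Plant:
    """One individual: ordered leaves, stem, seed pool and phenology state."""

    genotype: Genotype
    leaves: list[Leaf] = dc_field(default_factory=list)
    stem_biomass: float = 0.0
    seed_biomass: float = 0.0
    height: float = 0.0
    age_gdd: float = 0.0       # thermal time since emergence
    position: tuple[int, int] = (0, 0)

    @property
    def leaf_biomass(self) -> float:
        return sum(leaf.biomass for leaf in self.leaves)

    @property
    def leaf_area(self) -> float:
        return sum(leaf.area for leaf in self.leaves)

    @property
    def standing_biomass(self) -> float:
        """Maintenance-bearing biomass: leaves plus stem (seeds excluded)."""
        return self.leaf_biomass + self.stem_biomass


@dataclass
class Field:
    """A spatial stand of plants; light is computed mean-field over the plot.

    The plot is conceptually replicated ``clone_factor`` times to form a large
    light field; here that clone-averaging is realised directly as horizontal
    homogeneity within the plot, which removes border effects by construction.
    """

    plants: list[Plant]
    plot_size: int = 16
    density: float = 100.0
    clone_factor: int = 625

    def __post_init__(self) -> None:
        if len(self.plants) != self.plot_size:
            raise ValueError(
                f"field holds {len(self.plants)} plants but plot_size is {self.plot_size}"
            )

    @property
    def ground_area(self) -> float:
        return self.plot_size / self.density

    @property
    def light_field_size(self) -> int:
        """Number of plant instances represented in the light calculation."""
        return self.plot_size * self.clone_factor


@dataclass
class CanopyProfile:
    """Per-layer, per-plant leaf area of the stand plus extinction coefficient.

    ``areas[l, i]`` is plant i's leaf area (m^2) in layer l; layer 0 is the
    lowest. Column sums equal each plant's total leaf area.
    """

    layer_edges: np.ndarray     # shape (n_layers + 1,), ascending heights (m)
    areas: np.ndarray           # shape (n_layers, n_plants)
    k_ext: float

    @property
    def n_layers(self) -> int:
        return self.areas.shape[0]


def leaf_potential_growth(leaf: Leaf, gdd_inc: float, tau: float = 80.0) -> float:
    """Biomass demand (g) of one leaf for one thermal-time step.

    Demand is the remaining headroom (biomass_pot - biomass) scaled by a
    saturating expansion kernel 1 - exp(-gdd_inc / tau); zero at full
    potential or with no thermal time.
    """
    if gdd_inc < 0:
        raise ValueError("gdd_inc must be non-negative")
    headroom = max(0.0, leaf.biomass_pot - leaf.biomass)
    if headroom == 0.0 or gdd_inc == 0.0:
        return 0.0
    return headroom * (1.0 - math.exp(-gdd_inc / tau))


def build_canopy_profile(field: Field, n_layers: int, k_ext: float = 0.7) -> CanopyProfile:
    """Bin every leaf's area into the canopy layer containing its insertion height."""
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    top = max((leaf.height for p in field.plants for leaf in p.leaves), default=0.0)
    top = max(top, 1e-9)
    edges = np.linspace(0.0, top, n_layers + 1)
    areas = np.zeros((n_layers, len(field.plants)))
    for i, plant in enumerate(field.plants):
        for leaf in plant.leaves:
            if leaf.biomass <= 0.0:
                continue
            layer = min(int(np.searchsorted(edges, leaf.height, side="right")) - 1, n_layers - 1)
            layer = max(layer, 0)
            areas[layer, i] += leaf.area
    return CanopyProfile(layer_edges=edges, areas=areas, k_ext=k_ext)


def intercept_light(profile: CanopyProfile, par0: float, ground_area: float) -> np.ndarray:
    """Per-plant intercepted PAR (MJ d^-1) from top-down Beer-Lambert extinction.

    Light enters at the canopy top; each layer absorbs 1 - exp(-k * LAI_layer)
    of the flux reaching it and plants within the layer split the absorbed
    amount in proportion to their leaf-area share of that layer. Plants whose
    leaves sit higher therefore intercept disproportionately.
    """
    if par0 < 0:
        raise ValueError("par0 must be non-negative")
    if ground_area <= 0:
        raise ValueError("ground_area must be positive")
    n_layers, n_plants = profile.areas.shape
    intercepted = np.zeros(n_plants)
    flux = par0 * ground_area
    for layer in range(n_layers - 1, -1, -1):
        layer_areas = profile.areas[layer]
        total = layer_areas.sum()
        if total <= 0.0:
            continue
        lai = total / ground_area
        absorbed = flux * (1.0 - math.exp(-profile.k_ext * lai))
        intercepted += absorbed * (layer_areas / total)
        flux -= absorbed
    return intercepted


def assimilate(par_intercepted: float, lue: float) -> float:
    """Gross daily assimilation A_total (g): linear light-use efficiency."""
    if par_intercepted < 0:
        raise ValueError("par_intercepted must be non-negative")
    return lue * par_intercepted


def maintain_and_allocate(
    plant: Plant, a_growth: float, gdd_inc: float, params: SimParams
) -> dict[str, float]:
    """Spend one day's growth assimilate; return a fully closed ledger.

    Order of spending: maintenance of standing biomass first (capped at
    income — biomass is never respired away), then a seed share that ramps
    from 0 at flowering to 1 over ``seed_ramp_gdd``, then vegetative demands
    (leaf expansion plus proportional stem growth). Ledger keys sum exactly
    to ``a_growth``; ``deficit`` flags days where income failed to cover
    maintenance.
    """
    if a_growth < 0:
        raise ValueError("a_growth must be non-negative")
    maint_req = params.maint_coef * plant.standing_biomass
    maintenance = min(a_growth, maint_req)
    remaining = a_growth - maintenance

    # phenology gate: seed filling ramps up after flowering
    past_flowering = plant.age_gdd - params.flowering_gdd
    if past_flowering > 0.0 and params.seed_ramp_gdd > 0.0:
        seed_frac = min(1.0, past_flowering / params.seed_ramp_gdd)
    elif past_flowering > 0.0:
        seed_frac = 1.0
    else:
        seed_frac = 0.0
    seed_alloc = seed_frac * remaining
    veg_pool = remaining - seed_alloc

    leaf_demands = [
        leaf_potential_growth(leaf, gdd_inc, params.leaf_expansion_tau) for leaf in plant.leaves
    ]
    leaf_total = sum(leaf_demands)
    # stem demands a fixed share of satisfied vegetative growth
    sf = params.stem_fraction
    stem_demand = leaf_total * sf / (1.0 - sf) if sf < 1.0 else 0.0
    total_demand = leaf_total + stem_demand

    if veg_pool > 0.0:
        scale = min(1.0, veg_pool / total_demand) if total_demand > 0.0 else 0.0
        for leaf, demand in zip(plant.leaves, leaf_demands):
            leaf.biomass += scale * demand
        # the stem is an indeterminate sink: beyond its share of demand it
        # takes part of the vegetative surplus (bolting growth); the rest
        # goes below ground, outside the aboveground canopy model
        surplus = veg_pool - scale * total_demand
        plant.stem_biomass += scale * stem_demand + params.surplus_stem_fraction * surplus
        veg_alloc = scale * total_demand + params.surplus_stem_fraction * surplus
    else:
        veg_alloc = 0.0

    plant.seed_biomass += seed_alloc
    plant.height = params.height_coef * plant.stem_biomass ** params.height_exp
    unallocated = a_growth - maintenance - seed_alloc - veg_alloc
    return {
        "a_growth": a_growth,
        "maintenance": maintenance,
        "vegetative": veg_alloc,
        "seed": seed_alloc,
        "unallocated": unallocated,
        "deficit": 1.0 if maintenance < maint_req else 0.0,
    }


def rank_potential(rank: int, params: SimParams) -> float:
    """Potential lamina biomass (g) of a leaf at a given absolute rank.

    Later (higher-rank) leaves have larger potential laminas, as in bolting
    crucifers: a linear factor from ``leaf_pot_rank_min`` to
    ``leaf_pot_rank_max`` across the vegetative rank span, so the canopy is
    top-heavy at maturity while the stand-level mean stays near
    ``leaf_pot_biomass``.
    """
    max_rank = params.initial_leaves + int(params.flowering_gdd / params.phyllochron)
    if max_rank <= 1:
        factor = 1.0
    else:
        frac = min(1.0, (rank - 1) / (max_rank - 1))
        factor = params.leaf_pot_rank_min + (params.leaf_pot_rank_max - params.leaf_pot_rank_min) * frac
    return params.leaf_pot_biomass * factor


def initiate_organs(plant: Plant, params: SimParams) -> int:
    """Initiate new leaves on the phyllochron schedule; none after flowering.

    The target leaf count is the initial count plus one leaf per completed
    phyllochron of pre-flowering thermal age. New leaves appear at the
    current plant height with zero biomass (growth fills them), so organ
    initiation creates no mass. Returns the number of leaves initiated.
    """
    veg_age = min(plant.age_gdd, params.flowering_gdd)
    target = params.initial_leaves + int(veg_age / params.phyllochron)
    created = 0
    while len(plant.leaves) < target:
        next_rank = max((leaf.rank_abs for leaf in plant.leaves), default=0) + 1
        plant.leaves.append(
            Leaf(
                rank_abs=next_rank,
                biomass=0.0,
                biomass_pot=rank_potential(next_rank, params),
                sla=params.sla,
                height=plant.height,
            )
        )
        created += 1
    return created
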