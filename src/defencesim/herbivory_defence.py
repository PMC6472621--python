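"""Defence allocation and rank-structured herbivore damage.

Defended plants divert a fixed percentage ``D`` of gross assimilate to the
biosynthesis and maintenance of defence before any growth allocation:

    A_growth = (1 - D/100) * A_total

Herbivore damage is a leaf-level removal rate per growing degree day (GDD),
shaped over relative leaf rank ``r`` (0 = oldest, 1 = youngest leaf) by a
logistic whose slope depends on the herbivore-distribution parameter ``h``:

    dmg = c * (1 - d/100) * b / (1 + exp(10*(h - (1 - h)) * (r - 0.5)))

with ``b`` the leaf biomass (g), ``c`` the base removal rate (fraction of
leaf biomass per GDD) and ``d`` the damage reduction by defence (%). At the
undefended baseline h = 0.2 the slope is exactly -6, concentrating damage on
young leaves; h = 0.5 is uniform; h = 0.8 mirrors the profile toward old
leaves. Damage removes both realised leaf biomass and the leaf's potential
(ceiling) biomass, so a damaged leaf never regrows past its reduced ceiling.

Damage depends on each plant's own leaf biomass only: herbivores do not
move between plants in response to defence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .plant_growth import Plant

__all__ = [
    "DefenceParams",
    "HerbivoryParams",
    "DamageEvent",
    "UNDEFENDED_H",
    "LOW_C",
    "HIGH_C",
    "logistic_slope",
    "defence_tax",
    "relative_rank",
    "damage_rate",
    "apply_herbivory",
]

#: Herbivore-distribution parameter of undefended plants (preference for
#: young leaves in the absence of defence).
UNDEFENDED_H = 0.2
#: Base removal rates of the low and high herbivory regimes (per GDD).
LOW_C = 0.005
HIGH_C = 0.01


@dataclass(frozen=True)
class DefenceParams:
    """Genotype-level defence parameters.

    D : defence investment, % of gross assimilate taxed.
    d : herbivore damage reduction, %.
    h : herbivore-distribution parameter in [0, 1].
    """

    D: float = 0.0
    d: float = 0.0
    h: float = UNDEFENDED_H

    def __post_init__(self) -> None:
        if not 0.0 <= self.D <= 100.0:
            raise ValueError(f"defence investment D must be in [0, 100], got {self.D}")
        if not 0.0 <= self.d <= 100.0:
            raise ValueError(f"damage reduction d must be in [0, 100], got {self.d}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"herbivore distribution h must be in [0, 1], got {self.h}")

    @classmethod
    def undefended(cls) -> "DefenceParams":
        return cls(D=0.0, d=0.0, h=UNDEFENDED_H)


@dataclass(frozen=True)
class HerbivoryParams:
    """Stand-level herbivore pressure: base removal rate c (per GDD)."""

    c: float = 0.0
    regime: str = "none"

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("base removal rate c must be non-negative")

    @classmethod
    def none(cls) -> "HerbivoryParams":
        return cls(c=0.0, regime="none")

    @classmethod
    def low(cls) -> "HerbivoryParams":
        return cls(c=LOW_C, regime="low")

    @classmethod
    def high(cls) -> "HerbivoryParams":
        return cls(c=HIGH_C, regime="high")


@dataclass(frozen=True)
class DamageEvent:
    """Record of herbivore removal from one leaf over one thermal-time step."""

    rank: int
    removed: float       # g of realised biomass removed
    pot_removed: float   # g removed from the potential (ceiling) biomass
    gdd_inc: float       # deg C d over which the rate was applied


def logistic_slope(h: float) -> float:
    """Slope of the rank-logistic exponent: 10*(h - (1 - h)) = 10*(2h - 1)."""
    return 10.0 * (h - (1.0 - h))


def defence_tax(a_total: float, D: float) -> tuple[float, float]:
    """Split gross assimilate into growth share and defence expenditure.

    Returns ``(a_growth, taxed)`` with a_growth = (1 - D/100) * a_total.
    """
    if a_total < 0:
        raise ValueError("a_total must be non-negative")
    if not 0.0 <= D <= 100.0:
        raise ValueError(f"defence investment D must be in [0, 100], got {D}")
    a_growth = (1.0 - D / 100.0) * a_total
    return a_growth, a_total - a_growth


def relative_rank(r_a: int, r_min: int, r_max: int) -> float:
    """Rescale an absolute leaf rank to [0, 1] along the main stem.

    0 is the oldest (lowest) leaf, 1 the youngest. A single-leaf plant
    (r_min == r_max) takes the least-informative midpoint value 0.5.
    """
    if r_min == r_max:
        if r_a != r_min:
            raise ValueError("rank out of range")
        return 0.5
    if not r_min <= r_a <= r_max:
        raise ValueError(f"rank {r_a} outside [{r_min}, {r_max}]")
    return (r_a - r_min) / (r_max - r_min)


def damage_rate(b: float, r: float, c: float, d: float = 0.0, h: float = UNDEFENDED_H) -> float:
    """Leaf-level herbivore removal rate (g biomass per GDD).

    ``dmg = c*(1 - d/100)*b / (1 + exp(s*(r - 0.5)))`` with slope
    ``s = 10*(2h - 1)``; bounded in [0, c*b).
    """
    if b < 0:
        raise ValueError("leaf biomass must be non-negative")
    if c < 0:
        raise ValueError("base removal rate c must be non-negative")
    if not 0.0 <= d <= 100.0:
        raise ValueError(f"damage reduction d must be in [0, 100], got {d}")
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"herbivore distribution h must be in [0, 1], got {h}")
    s = logistic_slope(h)
    return c * (1.0 - d / 100.0) * b / (1.0 + math.exp(s * (r - 0.5)))


def apply_herbivory(
    plant: "Plant",
    hp: HerbivoryParams,
    dp: DefenceParams,
    gdd_inc: float,
    pot_reduction_mode: str = "absolute",
) -> list[DamageEvent]:
    """Remove herbivore damage from every leaf of a plant over one step.

    Removal per leaf is ``min(b, dmg * gdd_inc)``; both realised and potential
    biomass drop. In ``absolute`` mode the potential drops by the same grams
    as the realised biomass; in ``proportional`` mode it drops by the same
    fraction. The plant is mutated in place and the events are returned.
    """
    if gdd_inc < 0:
        raise ValueError("gdd_inc must be non-negative")
    if hp.c == 0.0 or gdd_inc == 0.0 or not plant.leaves:
        return []

    ranks = [leaf.rank_abs for leaf in plant.leaves]
    r_min, r_max = min(ranks), max(ranks)
    events: list[DamageEvent] = []
    for leaf in plant.leaves:
        r = relative_rank(leaf.rank_abs, r_min, r_max)
        rate = damage_rate(leaf.biomass, r, hp.c, dp.d, dp.h)
        removed = min(leaf.biomass, rate * gdd_inc)
        if removed <= 0.0:
            continue
        if pot_reduction_mode == "proportional":
            frac = removed / leaf.biomass
            pot_removed = leaf.biomass_pot * frac
        else:
            pot_removed = removed
        leaf.biomass -= removed
        leaf.biomass_pot = max(leaf.biomass, leaf.biomass_pot - pot_removed)
        events.append(
            DamageEvent(rank=leaf.rank_abs, removed=removed, pot_removed=pot_removed, gdd_inc=gdd_inc)
        )
    return events
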