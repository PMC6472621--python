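"""Default physiological and environmental parameters for the simulator.

All values are config-overridable; they describe a fast-growing annual
(Brassica-type) grown at high density in a temperate (Dutch) spring-summer
season. Units are noted per field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class SimParams:
    """Bundle of stand, weather, growth and canopy parameters.

    The simulation window runs from 31 March to 2 August (124 daily steps,
    non-leap calendar), matching a spring-sown annual's season.
    """

    # --- stand geometry ---
    plot_size: int = 16            # plants per plot (4 x 4 grid)
    density: float = 100.0         # plants m^-2
    clone_factor: int = 625        # plot replication factor for light averaging

    # --- simulation window ---
    start_doy: int = 90            # 31 March, non-leap year
    n_days: int = 124              # 31 March -> 2 August

    # --- weather drivers (deterministic seasonal sinusoids) ---
    temp_mean: float = 10.0        # deg C, annual mean
    temp_amp: float = 8.0          # deg C, seasonal amplitude
    temp_peak_doy: int = 196       # mid July
    par_mean: float = 6.0          # MJ m^-2 d^-1, annual mean PAR
    par_amp: float = 4.0           # MJ m^-2 d^-1, seasonal amplitude
    par_peak_doy: int = 172        # midsummer
    t_base: float = 0.0            # deg C, base temperature for thermal time

    # --- canopy / light ---
    k_ext: float = 0.7             # Beer-Lambert extinction coefficient
    n_layers: int = 20             # canopy discretisation layers

    # --- carbon economy ---
    sla: float = 0.02              # m^2 g^-1, specific leaf area
    lue: float = 3.0               # g MJ^-1, light-use efficiency
    maint_coef: float = 0.015      # g g^-1 d^-1, maintenance per unit standing biomass

    # --- development ---
    phyllochron: float = 30.0      # deg C d between successive leaves
    flowering_gdd: float = 600.0   # deg C d from emergence to flowering
    seed_ramp_gdd: float = 300.0   # deg C d over which allocation shifts to seeds
    leaf_expansion_tau: float = 80.0   # deg C d, leaf expansion time constant
    leaf_pot_biomass: float = 0.12  # g, mean potential lamina biomass of an undamaged leaf
    # lamina potential grows with rank (later leaves larger, as in bolting
    # crucifers): linear factor from rank_min_frac to rank_max_frac across
    # the vegetative rank span, mean ~1 so stand LAI is unchanged
    leaf_pot_rank_min: float = 0.5
    leaf_pot_rank_max: float = 1.5
    initial_leaves: int = 2        # leaves present at emergence
    initial_biomass: float = 0.02  # g, seedling lamina biomass (total)
    initial_stem: float = 0.01     # g, seedling stem biomass

    # --- architecture ---
    stem_fraction: float = 0.3     # share of demand-driven vegetative allocation going to stem
    # share of the vegetative surplus (beyond leaf + stem demand) that feeds
    # further stem/bolting growth; the remainder goes below ground (roots,
    # reserves), outside the aboveground canopy model
    surplus_stem_fraction: float = 0.25
    height_coef: float = 0.25      # m g^-0.5, stem-biomass -> height allometry
    height_exp: float = 0.5        # allometric exponent

    # --- stochasticity ---
    jitter_sd: float = 0.05        # lognormal sigma of initial-size jitter

    # --- herbivory bookkeeping ---
    pot_reduction_mode: str = "proportional"   # "proportional" | "absolute"

    def __post_init__(self) -> None:
        if self.plot_size < 1:
            raise ValueError("plot_size must be >= 1")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.pot_reduction_mode not in ("absolute", "proportional"):
            raise ValueError("pot_reduction_mode must be 'absolute' or 'proportional'")

    @property
    def ground_area(self) -> float:
        """Plot ground area in m^2 (plants / density)."""
        return self.plot_size / self.density

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
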