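import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from defencesim.params import SimParams
from defencesim.plant_growth import (
    Field,
    Genotype,
    Leaf,
    Plant,
    assimilate,
    build_canopy_profile,
    initiate_organs,
    intercept_light,
    leaf_potential_growth,
    maintain_and_allocate,
    rank_potential,
)


def make_leaf(biomass=0.05, pot=0.1, height=0.2, rank=1, sla=0.02):
    return Leaf(rank_abs=rank, biomass=biomass, biomass_pot=pot, sla=sla, height=height)


def make_plant(leaf_heights, biomass=0.1, sla=0.02):
    plant = Plant(genotype=Genotype.undefended())
    for k, h in enumerate(leaf_heights, start=1):
        plant.leaves.append(make_leaf(biomass=biomass, pot=biomass, height=h, rank=k, sla=sla))
    return plant


class TestLeafPotentialGrowth:
    def test_no_headroom_no_demand(self):
        assert leaf_potential_growth(make_leaf(biomass=0.1, pot=0.1), gdd_inc=15.0) == 0.0

    def test_no_thermal_time_no_demand(self):
        assert leaf_potential_growth(make_leaf(), gdd_inc=0.0) == 0.0

    def test_demand_capped_by_reduced_ceiling(self):
        leaf = make_leaf(biomass=0.04, pot=0.1)
        leaf.biomass_pot = 0.05  # herbivory halved the ceiling
        demand = leaf_potential_growth(leaf, gdd_inc=1e6)
        assert demand <= 0.05 - 0.04 + 1e-15

    def test_demand_scales_with_headroom(self):
        small = leaf_potential_growth(make_leaf(biomass=0.08, pot=0.1), 10.0)
        large = leaf_potential_growth(make_leaf(biomass=0.02, pot=0.1), 10.0)
        assert large == pytest.approx(4.0 * small)


class TestCanopyProfile:
    def test_single_plant_conserves_area(self):
        plant = make_plant([0.1, 0.3, 0.5])
        field = Field(plants=[plant], plot_size=1, density=100.0)
        profile = build_canopy_profile(field, n_layers=1)
        assert profile.areas.sum() == pytest.approx(plant.leaf_area)

    @pytest.mark.parametrize("n_layers", [1, 7, 50])
    def test_per_plant_totals_invariant_to_discretisation(self, n_layers):
        plants = [make_plant([0.1, 0.4]), make_plant([0.2, 0.6], biomass=0.2)]
        field = Field(plants=plants, plot_size=2, density=100.0)
        profile = build_canopy_profile(field, n_layers=n_layers)
        totals = profile.areas.sum(axis=0)
        for i, plant in enumerate(plants):
            assert totals[i] == pytest.approx(plant.leaf_area)

    def test_identical_plants_identical_columns(self):
        plants = [make_plant([0.1, 0.4]), make_plant([0.1, 0.4])]
        field = Field(plants=plants, plot_size=2, density=100.0)
        profile = build_canopy_profile(field, n_layers=10)
        np.testing.assert_allclose(profile.areas[:, 0], profile.areas[:, 1])


def sequential_interception_oracle(plants, par0, ground_area, k):
    """Independent fine-layer oracle: attenuate leaf by leaf from the top."""
    leaves = sorted(
        ((leaf.height, i, leaf.area) for i, p in enumerate(plants) for leaf in p.leaves),
        reverse=True,
    )
    flux = par0 * ground_area
    out = [0.0] * len(plants)
    for _, i, area in leaves:
        absorbed = flux * (1.0 - math.exp(-k * area / ground_area))
        out[i] += absorbed
        flux -= absorbed
    return out


class TestInterceptLight:
    def test_single_plant_closed_form(self):
        plant = make_plant([0.2], biomass=0.5)
        field = Field(plants=[plant], plot_size=1, density=100.0)
        profile = build_canopy_profile(field, n_layers=1, k_ext=0.7)
        got = intercept_light(profile, par0=8.0, ground_area=field.ground_area)
        lai = plant.leaf_area / field.ground_area
        expected = 8.0 * field.ground_area * (1.0 - math.exp(-0.7 * lai))
        assert got[0] == pytest.approx(expected)

    def test_identical_plants_share_equally(self):
        plants = [make_plant([0.1, 0.3]) for _ in range(4)]
        field = Field(plants=plants, plot_size=4, density=100.0)
        profile = build_canopy_profile(field, n_layers=5)
        got = intercept_light(profile, 8.0, field.ground_area)
        np.testing.assert_allclose(got, got[0])

    def test_zero_leaf_area_intercepts_nothing(self):
        plant = Plant(genotype=Genotype.undefended())
        field = Field(plants=[plant], plot_size=1, density=100.0)
        profile = build_canopy_profile(field, n_layers=3)
        assert intercept_light(profile, 8.0, field.ground_area).sum() == 0.0

    def test_taller_plant_overshares_matching_fine_oracle(self):
        """Stratified leaves: the tall plant's light share must exceed its
        area share and converge to the leaf-sequential closed form."""
        tall = make_plant([0.6, 0.7, 0.8])
        short = make_plant([0.1, 0.2, 0.3])
        field = Field(plants=[tall, short], plot_size=2, density=100.0)
        profile = build_canopy_profile(field, n_layers=10_000, k_ext=0.7)
        got = intercept_light(profile, 8.0, field.ground_area)
        oracle = sequential_interception_oracle([tall, short], 8.0, field.ground_area, 0.7)
        np.testing.assert_allclose(got, oracle, rtol=1e-9)
        area_share = tall.leaf_area / (tall.leaf_area + short.leaf_area)
        assert got[0] / got.sum() > area_share

    @given(
        heights=st.lists(st.floats(0.01, 2.0), min_size=1, max_size=6),
        par0=st.floats(0.0, 12.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_interception_never_exceeds_incident(self, heights, par0):
        plants = [make_plant(heights), make_plant([h / 2 for h in heights])]
        field = Field(plants=plants, plot_size=2, density=100.0)
        profile = build_canopy_profile(field, n_layers=13)
        got = intercept_light(profile, par0, field.ground_area)
        assert got.sum() <= par0 * field.ground_area + 1e-12


class TestAssimilate:
    def test_linear_in_light(self):
        assert assimilate(0.0, 3.0) == 0.0
        assert assimilate(2.0, 3.0) == pytest.approx(6.0)
        assert assimilate(4.0, 3.0) == pytest.approx(2 * assimilate(2.0, 3.0))


class TestMaintainAndAllocate:
    def test_zero_income_flags_deficit_without_shrinking(self, params):
        plant = make_plant([0.1], biomass=0.5)
        before = plant.standing_biomass
        ledger = maintain_and_allocate(plant, 0.0, 12.0, params)
        assert ledger["deficit"] == 1.0
        assert plant.standing_biomass == before

    def test_no_seed_growth_before_flowering(self, params):
        plant = make_plant([0.1])
        plant.age_gdd = params.flowering_gdd / 2
        maintain_and_allocate(plant, 1.0, 12.0, params)
        assert plant.seed_biomass == 0.0

    def test_seed_growth_after_flowering(self, params):
        plant = make_plant([0.1])
        plant.age_gdd = params.flowering_gdd + params.seed_ramp_gdd
        maintain_and_allocate(plant, 1.0, 12.0, params)
        assert plant.seed_biomass > 0.0

    @pytest.mark.parametrize("a_growth", [0.0, 0.003, 0.5, 4.0])
    def test_ledger_closes_exactly(self, params, a_growth):
        plant = make_plant([0.1, 0.2], biomass=0.05)
        plant.leaves[0].biomass_pot = 0.2
        plant.age_gdd = params.flowering_gdd + 50.0
        ledger = maintain_and_allocate(plant, a_growth, 14.0, params)
        total = ledger["maintenance"] + ledger["vegetative"] + ledger["seed"] + ledger["unallocated"]
        assert total == pytest.approx(a_growth, abs=1e-12)


class TestInitiateOrgans:
    def test_no_leaf_before_first_phyllochron(self, params):
        plant = make_plant([0.0, 0.0])
        plant.age_gdd = params.phyllochron - 1.0
        assert initiate_organs(plant, params) == 0

    def test_three_phyllochrons_three_leaves(self, params):
        plant = make_plant([0.0, 0.0])
        plant.age_gdd = 3.0 * params.phyllochron
        assert initiate_organs(plant, params) == 3
        assert [leaf.rank_abs for leaf in plant.leaves] == [1, 2, 3, 4, 5]

    def test_no_initiation_after_flowering(self, params):
        plant = make_plant([0.0, 0.0])
        plant.age_gdd = params.flowering_gdd
        initiate_organs(plant, params)
        count = len(plant.leaves)
        plant.age_gdd = params.flowering_gdd + 10 * params.phyllochron
        assert initiate_organs(plant, params) == 0
        assert len(plant.leaves) == count

    def test_rank_potential_increases_with_rank(self, params):
        pots = [rank_potential(r, params) for r in range(1, 23)]
        assert pots == sorted(pots)
        assert pots[0] == pytest.approx(params.leaf_pot_biomass * params.leaf_pot_rank_min)
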