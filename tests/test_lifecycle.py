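"""Life-cycle engine: spawning, recruitment, growth, smolting, sea phase."""

import numpy as np
import pytest
from scipy import stats

from salmosim import ModelParams
from salmosim.genetics import GENOME_SHAPE
from salmosim.lifecycle import (
    FARMED,
    FEMALE,
    MALE,
    WILD,
    EggFamilies,
    Fishes,
    PopulationState,
    decide_return,
    grow_freshwater,
    marine_transition,
    recruit_juveniles,
    select_mature_parr,
    smoltify,
    spawn,
    step_year,
    survive_freshwater,
)
from salmosim.scenarios import no_intrusion_scenario

from conftest import make_fishes


class TestSpawn:
    def test_single_pair_egg_count_is_weight_times_fecundity(self, params, rng):
        female = make_fishes(1, sex=FEMALE, length=60.0)
        male = make_fishes(1, sex=MALE, length=60.0)
        fams = spawn(female, male, Fishes.empty(), params, rng)
        expected = params.fecundity_per_g * params.weight_of(60.0)
        assert len(fams) == 1
        assert fams.eggs[0] == pytest.approx(float(expected))

    def test_farmed_female_produces_30_percent_of_wild_eggs(self, params, rng):
        females = Fishes.concat(
            [make_fishes(1, sex=FEMALE, length=60.0, origin=WILD),
             make_fishes(1, sex=FEMALE, length=60.0, origin=FARMED)]
        )
        male = make_fishes(1, sex=MALE, length=60.0)
        fams = spawn(females, male, Fishes.empty(), params, rng)
        assert fams.eggs[1] / fams.eggs[0] == pytest.approx(0.30)

    def test_sire_lottery_weights_wild_vs_farmed_male_20_to_1(self, params, rng):
        """Equal-length wild and farmed males sire at odds 1 : 0.05."""
        wild_male = make_fishes(1, sex=MALE, length=60.0, origin=WILD, allele=1)
        farm_male = make_fishes(1, sex=MALE, length=60.0, origin=FARMED, allele=0)
        males = Fishes.concat([wild_male, farm_male])
        n = 3_000
        females = make_fishes(n, sex=FEMALE, length=60.0)
        fams = spawn(females, males, Fishes.empty(), params, rng)
        farmed_sired = int((fams.father_genomes.sum(axis=(1, 2, 3)) == 0).sum())
        p_farm = 0.05 / 1.05
        lo, hi = stats.binom.interval(0.999, n, p_farm)
        assert lo <= farmed_sired <= hi

    def test_no_males_is_reproductive_failure_not_error(self, params, rng):
        females = make_fishes(5, sex=FEMALE)
        fams = spawn(females, Fishes.empty(), Fishes.empty(), params, rng)
        assert len(fams) == 0 and fams.total_eggs == 0

    def test_mature_parr_can_sire_alone(self, params, rng):
        females = make_fishes(3, sex=FEMALE)
        parr = make_fishes(2, sex=MALE, length=9.0, allele=0)
        fams = spawn(females, Fishes.empty(), parr, params, rng)
        assert len(fams) == 3
        assert fams.father_genomes.sum() == 0


class TestRecruit:
    def test_zero_families_zero_recruits(self, params, rng):
        assert len(recruit_juveniles(EggFamilies.empty(), params, rng)) == 0

    def test_low_density_survival_matches_beverton_holt_formula(self, params, rng):
        """Far below saturation, realized egg->recruit survival is the baseline."""
        mothers = make_fishes(4, sex=FEMALE, length=60.0)  # all-wild genomes, S=1
        eggs = np.full(4, 250.0)
        fams = EggFamilies(eggs=eggs, mother_genomes=mothers.genomes,
                           father_genomes=mothers.genomes)
        counts = [len(recruit_juveniles(fams, params, rng)) for _ in range(100)]
        total_eggs = 1000.0
        expected = params.egg_max_survival * total_eggs / (1 + total_eggs / params.egg_half_saturation)
        # mean of 100 Poisson draws around `expected`
        assert np.mean(counts) == pytest.approx(expected, rel=0.15)

    def test_family_share_follows_embryo_survival_modifier(self, params, rng):
        """Equal egg counts, embryo modifiers 1.0 vs 0.5 -> 2:1 recruit ratio."""
        wildm = make_fishes(1, sex=FEMALE, allele=1)
        farmm = make_fishes(1, sex=FEMALE, allele=0)
        fams = EggFamilies(
            eggs=np.array([5000.0, 5000.0]),
            mother_genomes=np.concatenate([wildm.genomes, farmm.genomes]),
            father_genomes=np.concatenate([wildm.genomes, farmm.genomes]),
        )
        rec = recruit_juveniles(fams, params, rng)
        # wild-family offspring are all-1 homozygotes
        from salmosim.genetics import scaled_allelic_value, build_locus_weights

        s = scaled_allelic_value(rec.genomes, "embryo", build_locus_weights())
        n_wild = int((s > 0.5).sum())
        lo, hi = stats.binom.interval(0.999, len(rec), 2.0 / 3.0)
        assert lo <= n_wild <= hi

    def test_recruits_are_fresh_0plus_parr(self, params, rng):
        mothers = make_fishes(2, sex=FEMALE)
        fams = EggFamilies(eggs=np.array([3000.0, 3000.0]),
                           mother_genomes=mothers.genomes, father_genomes=mothers.genomes)
        rec = recruit_juveniles(fams, params, rng)
        assert np.all(rec.fw_age == 0)
        assert np.all(rec.length == params.emergence_length)
        frac_male = rec.sex.mean()
        assert 0.4 < frac_male < 0.6


class TestFreshwater:
    def test_growth_increment_is_baseline_at_negligible_density(self, rng):
        p = ModelParams(parr_growth_sigma=0.0)
        parr = make_fishes(1, fw_age=1, length=6.0, allele=1)
        grown = grow_freshwater(parr, p, rng)
        density_factor = 1 / (1 + (1 / p.habitat_area) / p.parr_density_half)
        expected = 6.0 + p.parr_growth_increments[1] * 1.0 * density_factor
        assert grown.length[0] == pytest.approx(expected)

    def test_farmed_genotype_grows_faster(self, rng):
        p = ModelParams(parr_growth_sigma=0.0)
        wild = make_fishes(1, fw_age=0, length=5.0, allele=1)
        farm = make_fishes(1, fw_age=0, length=5.0, allele=0)
        g_wild = grow_freshwater(wild, p, rng).length[0]
        g_farm = grow_freshwater(farm, p, rng).length[0]
        assert g_farm > g_wild

    def test_wild_genotype_survives_better(self, params):
        n = 8_000
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
        wild = make_fishes(n, fw_age=1, length=8.0, allele=1)
        farm = make_fishes(n, fw_age=1, length=8.0, allele=0)
        s_wild = len(survive_freshwater(wild, params, rng1)) / n
        s_farm = len(survive_freshwater(farm, params, rng2)) / n
        assert s_wild > s_farm
        # farmed survival multiplier is at_s0 = 0.5 of the map
        assert s_farm / s_wild == pytest.approx(0.5, abs=0.06)

    def test_growth_density_factor_decreases_with_density(self, rng):
        p = ModelParams(parr_growth_sigma=0.0, habitat_area=100.0, parr_density_half=1.0)
        sparse = make_fishes(1, fw_age=1, length=6.0)
        dense = make_fishes(200, fw_age=1, length=6.0)
        g_sparse = grow_freshwater(sparse, p, np.random.default_rng(0)).length[0]
        g_dense = grow_freshwater(dense, p, np.random.default_rng(0)).length[0]
        assert g_sparse > g_dense


class TestSmolting:
    def test_threshold_boundary_inclusive(self, params, rng):
        at = make_fishes(1, fw_age=2, length=params.smolt_threshold)
        below = make_fishes(1, fw_age=2, length=params.smolt_threshold - 0.01)
        smolts, stay = smoltify(Fishes.concat([at, below]), params, rng)
        assert len(smolts) == 1 and len(stay) == 1
        assert smolts.length[0] == params.smolt_threshold

    def test_overaged_parr_die(self, params, rng):
        old = make_fishes(3, fw_age=params.max_freshwater_age, length=5.0)
        smolts, stay = smoltify(old, params, rng)
        assert len(smolts) == 0 and len(stay) == 0


class TestMarine:
    def test_wild_survives_better_farmed_grows_faster(self, params):
        n = 6_000
        wild = make_fishes(n, sea_age=0, length=12.0, allele=1)
        farm = make_fishes(n, sea_age=0, length=12.0, allele=0)
        out_w = marine_transition(wild, params, np.random.default_rng(3))
        out_f = marine_transition(farm, params, np.random.default_rng(3))
        assert len(out_w) > len(out_f)
        assert out_f.length.mean() > out_w.length.mean()
        assert np.all(out_w.sea_age == 1)

    def test_first_sea_year_harsher_than_later(self, params):
        n = 6_000
        first = make_fishes(n, sea_age=0, length=12.0)
        later = make_fishes(n, sea_age=1, length=50.0)
        s1 = len(marine_transition(first, params, np.random.default_rng(5))) / n
        s2 = len(marine_transition(later, params, np.random.default_rng(5))) / n
        assert s1 < s2

    def test_empty_sea_passes_through(self, params, rng):
        assert len(marine_transition(Fishes.empty(), params, rng)) == 0

    def test_terminal_sea_age_always_returns(self, params, rng):
        sea = make_fishes(50, sea_age=3, length=80.0, allele=0)
        back, remaining = decide_return(sea, params, rng)
        assert len(back) == 50 and len(remaining) == 0

    def test_wild_cohort_returns_younger(self):
        """Matched smolt cohorts at equal marine survival: wild mean sea age
        at return is below the farmed cohort's (earlier maturation)."""
        from salmosim.phenotypes import TraitMap

        params = ModelParams(adult_survival_map=TraitMap(1.0, 1.0))

        def mean_return_age(allele, seed):
            sea = make_fishes(4_000, sea_age=0, length=12.0, allele=allele)
            rng = np.random.default_rng(seed)
            ages = []
            for _ in range(3):
                sea = marine_transition(sea, params, rng)
                back, sea = decide_return(sea, params, rng)
                ages.extend(back.sea_age.tolist())
            return np.mean(ages)

        assert mean_return_age(1, 7) < mean_return_age(0, 7)


class TestMatureParr:
    def test_only_large_males_eligible(self, params, rng):
        small = make_fishes(2_000, sex=MALE, length=params.parr_mature_min_length - 1)
        females = make_fishes(2_000, sex=FEMALE, length=20.0)
        assert len(select_mature_parr(small, params, rng)) == 0
        assert len(select_mature_parr(females, params, rng)) == 0
        big = make_fishes(2_000, sex=MALE, length=9.0)
        picked = select_mature_parr(big, params, rng)
        lo, hi = stats.binom.interval(0.999, 2_000, params.parr_mature_prob)
        assert lo <= len(picked) <= hi


class TestStepYear:
    def test_extinct_state_is_noop_with_zero_record(self, params, rng):
        state = PopulationState(extinct=True)
        cfg = no_intrusion_scenario()
        state, rec = step_year(state, cfg, 7, params, rng)
        assert state.extinct
        assert rec["ret_n_total"] == 0 and rec["egg_n"] == 0
        assert np.isnan(rec["s_adult"])

    def test_empty_state_becomes_extinct(self, params, rng):
        state = PopulationState()
        state, rec = step_year(state, no_intrusion_scenario(), 1, params, rng)
        assert state.extinct

    def test_one_year_cycle_produces_consistent_censuses(self, params, rng):
        parr = make_fishes(500, fw_age=0, length=7.0, freq=0.9, rng=rng)
        sea = make_fishes(200, sea_age=1, length=50.0, freq=0.9, rng=rng)
        sea.sex = (np.arange(200) % 2).astype(np.uint8)
        state = PopulationState(parr=parr, sea=sea)
        state, rec = step_year(state, no_intrusion_scenario(), 1, params, rng)
        assert rec["ret_n_total"] == rec["ret_n_1"] + rec["ret_n_2"] + rec["ret_n_3"]
        assert rec["egg_n"] >= 0
        assert not state.extinct
        assert np.all(state.parr.length > 0)
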