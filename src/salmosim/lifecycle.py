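"""Annual individual-based life-cycle engine.

One simulated year runs through a fixed event order:

1. spring — freshwater ageing, smolting (May smolt census), emergence of the
   previous autumn's eggs into 0+ parr under Beverton–Holt density-dependent
   recruitment (May juvenile census);
2. summer — density- and genotype-dependent freshwater growth, October parr
   census;
3. winter — size- and genotype-dependent freshwater survival;
4. sea — marine survival and growth (first sea year harsher than later ones),
   sea-age increment, maturation decision, return of maturing adults
   (returner census, sea age 1–3, forced return at 3);
5. autumn — injection of escapee/strayer cohorts, spawning by returners,
   injected adults and precocious mature male parr.  All adult spawners die
   after spawning (semelparous closure); eggs are carried as family counts to
   the next spring.

Cohorts are held as struct-of-arrays (:class:`Fishes`); eggs are never
instantiated as individuals — each family records its parents' genomes and an
egg count, and offspring genomes are realized only for the recruits that
survive to 0+ parr.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import genetics
from .genetics import ADULT, EMBRYO, JUVENILE
from .phenotypes import maturation_probability, trait_value

# sex codes
FEMALE, MALE = 0, 1
# origin codes
WILD, FARMED, STRAYER = 0, 1, 2
ORIGIN_NAMES = ("wild", "farmed", "strayer")


@dataclass
class Fishes:
    """A cohort of fish as parallel arrays (one row per individual)."""

    sex: np.ndarray        # uint8, 0 = F, 1 = M
    origin: np.ndarray     # uint8, 0 wild-focal, 1 farmed escapee, 2 strayer
    fw_age: np.ndarray     # freshwater age in years
    sea_age: np.ndarray    # sea winters
    length: np.ndarray     # cm
    genomes: np.ndarray    # (n, 3, 21, 2) uint8

    def __len__(self) -> int:
        return len(self.length)

    @classmethod
    def empty(cls) -> "Fishes":
        return cls(
            sex=np.empty(0, np.uint8),
            origin=np.empty(0, np.uint8),
            fw_age=np.empty(0, np.int32),
            sea_age=np.empty(0, np.int32),
            length=np.empty(0, float),
            genomes=np.empty((0, *genetics.GENOME_SHAPE), np.uint8),
        )

    def take(self, index) -> "Fishes":
        """Subset by boolean mask or integer index array."""
        return Fishes(
            sex=self.sex[index],
            origin=self.origin[index],
            fw_age=self.fw_age[index],
            sea_age=self.sea_age[index],
            length=self.length[index],
            genomes=self.genomes[index],
        )

    @staticmethod
    def concat(cohorts: list["Fishes"]) -> "Fishes":
        cohorts = [c for c in cohorts if len(c) > 0]
        if not cohorts:
            return Fishes.empty()
        return Fishes(
            sex=np.concatenate([c.sex for c in cohorts]),
            origin=np.concatenate([c.origin for c in cohorts]),
            fw_age=np.concatenate([c.fw_age for c in cohorts]),
            sea_age=np.concatenate([c.sea_age for c in cohorts]),
            length=np.concatenate([c.length for c in cohorts]),
            genomes=np.concatenate([c.genomes for c in cohorts]),
        )

    def weight(self, params) -> np.ndarray:
        return params.weight_coeff * self.length ** params.weight_exponent

    def s_value(self, gene_set, weights) -> np.ndarray:
        return genetics.scaled_allelic_value(self.genomes, gene_set, weights)


@dataclass
class EggFamilies:
    """Egg families from one autumn's spawning: counts plus parental genomes."""

    eggs: np.ndarray             # egg count per family
    mother_genomes: np.ndarray   # (nf, 3, 21, 2)
    father_genomes: np.ndarray

    def __len__(self) -> int:
        return len(self.eggs)

    @property
    def total_eggs(self) -> float:
        return float(self.eggs.sum()) if len(self.eggs) else 0.0

    @classmethod
    def empty(cls) -> "EggFamilies":
        return cls(
            eggs=np.empty(0, float),
            mother_genomes=np.empty((0, *genetics.GENOME_SHAPE), np.uint8),
            father_genomes=np.empty((0, *genetics.GENOME_SHAPE), np.uint8),
        )


@dataclass
class PopulationState:
    """All living fish plus the egg bank, indexed by scenario year."""

    year: int = 0
    parr: Fishes = field(default_factory=Fishes.empty)
    sea: Fishes = field(default_factory=Fishes.empty)
    families: EggFamilies = field(default_factory=EggFamilies.empty)
    extinct: bool = False

    def n_alive(self) -> int:
        return len(self.parr) + len(self.sea)

    def all_genomes(self) -> np.ndarray:
        return np.concatenate([self.parr.genomes, self.sea.genomes])


def _survival_modifier(trait_map, s, params):
    if params.selection_disabled:
        return 1.0
    return trait_value(trait_map, s)


# ---------------------------------------------------------------------------
# spawning and recruitment
# ---------------------------------------------------------------------------

def _female_success(origin: np.ndarray, params) -> np.ndarray:
    mult = np.ones(len(origin))
    mult[origin == FARMED] = params.success.female_relative
    return mult


def _male_success(origin: np.ndarray, params) -> np.ndarray:
    mult = np.ones(len(origin))
    mult[origin == FARMED] = params.success.male_relative
    return mult


def spawn(females: Fishes, males: Fishes, mature_parr: Fishes, params, rng) -> EggFamilies:
    """Autumn spawning: weight-dependent fertility, length-dependent siring.

    Each female deposits ``fecundity_per_g * weight`` eggs, discounted by the
    escapee success multiplier for farmed females.  For every female one sire
    is drawn from the male lottery with probability proportional to
    ``length x male success multiplier``; precocious mature male parr enter
    the lottery at a small fixed competitive weight.  Years with no males and
    no mature parr produce no eggs (reproductive failure, not an error).
    """
    if len(females) == 0:
        return EggFamilies.empty()

    sire_weights = []
    sire_genomes = []
    if len(males):
        sire_weights.append(males.length * _male_success(males.origin, params))
        sire_genomes.append(males.genomes)
    if len(mature_parr):
        sire_weights.append(np.full(len(mature_parr), params.parr_sire_weight))
        sire_genomes.append(mature_parr.genomes)
    if not sire_weights:
        return EggFamilies.empty()

    w = np.concatenate(sire_weights)
    if w.sum() <= 0:
        return EggFamilies.empty()
    genomes = np.concatenate(sire_genomes)
    sire_idx = rng.choice(len(w), size=len(females), p=w / w.sum())

    eggs = (
        params.fecundity_per_g
        * females.weight(params)
        * _female_success(females.origin, params)
    )
    return EggFamilies(
        eggs=eggs,
        mother_genomes=females.genomes.copy(),
        father_genomes=genomes[sire_idx].copy(),
    )


def recruit_juveniles(families: EggFamilies, params, rng) -> Fishes:
    """Spring emergence: Beverton–Holt recruitment of eggs to 0+ parr.

    The effective egg pool weights each family's eggs by the embryo-survival
    modifier of its mid-parent embryo genotype; total recruits are a Poisson
    draw around ``S_max * E / (1 + E / E_half)``.  Each recruit's family is
    drawn proportionally to its weighted egg contribution and its genome is
    realized by Mendelian gametes from the recorded parents.  Sexes 50:50.
    """
    if len(families) == 0 or families.total_eggs <= 0:
        return Fishes.empty()

    weights = genetics.build_locus_weights()
    s_mother = genetics.scaled_allelic_value(families.mother_genomes, EMBRYO, weights)
    s_father = genetics.scaled_allelic_value(families.father_genomes, EMBRYO, weights)
    modifier = _survival_modifier(params.embryo_survival_map, (s_mother + s_father) / 2.0, params)
    weighted = families.eggs * modifier
    effective_eggs = weighted.sum()
    if effective_eggs <= 0:
        return Fishes.empty()

    mean_recruits = (
        params.egg_max_survival
        * effective_eggs
        / (1.0 + effective_eggs / params.egg_half_saturation)
    )
    n = int(rng.poisson(mean_recruits))
    if n == 0:
        return Fishes.empty()

    fam = rng.choice(len(families), size=n, p=weighted / effective_eggs)
    mat = genetics.make_gametes(families.mother_genomes[fam], rng)
    pat = genetics.make_gametes(families.father_genomes[fam], rng)
    return Fishes(
        sex=rng.integers(0, 2, n).astype(np.uint8),
        origin=np.full(n, WILD, np.uint8),
        fw_age=np.zeros(n, np.int32),
        sea_age=np.zeros(n, np.int32),
        length=np.full(n, params.emergence_length, float),
        genomes=genetics.fertilize(mat, pat),
    )


# ---------------------------------------------------------------------------
# freshwater stage
# ---------------------------------------------------------------------------

def grow_freshwater(parr: Fishes, params, rng) -> Fishes:
    """Summer growth of parr: genotype-, density- and age-dependent."""
    if len(parr) == 0:
        return parr
    weights = genetics.build_locus_weights()
    s = parr.s_value(JUVENILE, weights)
    if params.selection_disabled:
        gmod = 1.0
    else:
        gmod = trait_value(params.juvenile_growth_map, s)
    density = len(parr) / params.habitat_area
    density_factor = 1.0 / (1.0 + density / params.parr_density_half)
    base = np.asarray(params.parr_growth_increments)[np.clip(parr.fw_age, 0, len(params.parr_growth_increments) - 1)]
    noise = rng.lognormal(mean=0.0, sigma=params.parr_growth_sigma, size=len(parr))
    parr.length = parr.length + base * gmod * density_factor * noise
    return parr


def survive_freshwater(parr: Fishes, params, rng) -> Fishes:
    """Overwinter parr survival: baseline x genotype modifier x size factor."""
    if len(parr) == 0:
        return parr
    weights = genetics.build_locus_weights()
    s = parr.s_value(JUVENILE, weights)
    smod = _survival_modifier(params.juvenile_survival_map, s, params)
    base = np.asarray(params.parr_survival_base)[np.clip(parr.fw_age, 0, len(params.parr_survival_base) - 1)]
    size_factor = parr.length / (parr.length + params.parr_size_half)
    prob = np.clip(base * smod * size_factor, 0.0, 1.0)
    return parr.take(rng.random(len(parr)) < prob)


def grow_and_survive_freshwater(parr: Fishes, params, rng) -> Fishes:
    """One freshwater year: summer growth followed by overwinter survival."""
    return survive_freshwater(grow_freshwater(parr, params, rng), params, rng)


def smoltify(parr: Fishes, params, rng) -> tuple[Fishes, Fishes]:
    """May smolting: parr at or above the length threshold leave the river.

    The boundary is inclusive (length == threshold smolts).  Parr that reach
    the maximum freshwater age without smolting die.  Returns
    ``(smolts, remaining_parr)``.
    """
    if len(parr) == 0:
        return Fishes.empty(), parr
    is_smolt = parr.length >= params.smolt_threshold
    too_old = (parr.fw_age >= params.max_freshwater_age) & ~is_smolt
    smolts = parr.take(is_smolt)
    remaining = parr.take(~is_smolt & ~too_old)
    return smolts, remaining


# ---------------------------------------------------------------------------
# marine stage
# ---------------------------------------------------------------------------

def marine_transition(sea: Fishes, params, rng) -> Fishes:
    """One sea year: survival, growth and sea-age increment.

    Mortality in the first sea year is higher than in later years; both
    survival and the growth increment are scaled by the adult gene set.
    """
    if len(sea) == 0:
        return sea
    weights = genetics.build_locus_weights()
    s = sea.s_value(ADULT, weights)
    smod = _survival_modifier(params.adult_survival_map, s, params)
    base = np.where(sea.sea_age == 0, params.marine_survival_first, params.marine_survival_later)
    prob = np.clip(base * smod, 0.0, 1.0)
    survivors = sea.take(rng.random(len(sea)) < prob)
    if len(survivors) == 0:
        return survivors

    s = survivors.s_value(ADULT, weights)
    if params.selection_disabled:
        gmod = 1.0
    else:
        gmod = trait_value(params.adult_growth_map, s)
    inc = np.asarray(params.marine_growth_increments)[
        np.clip(survivors.sea_age, 0, len(params.marine_growth_increments) - 1)
    ]
    noise = rng.lognormal(0.0, params.marine_growth_sigma, len(survivors))
    survivors.length = survivors.length + inc * gmod * noise
    survivors.sea_age = survivors.sea_age + 1
    return survivors


def decide_return(sea: Fishes, params, rng) -> tuple[Fishes, Fishes]:
    """Maturation decision: maturing fish return to the river to spawn.

    Each fish matures with :func:`maturation_probability`; fish at the
    maximum sea age always return.  Returns ``(returners, remaining_sea)``.
    """
    if len(sea) == 0:
        return Fishes.empty(), sea
    weights = genetics.build_locus_weights()
    s = sea.s_value(ADULT, weights)
    prob = maturation_probability(s, sea.sea_age, sea.length, params)
    mature = rng.random(len(sea)) < prob
    return sea.take(mature), sea.take(~mature)


def select_mature_parr(parr: Fishes, params, rng) -> Fishes:
    """Precocious mature male parr joining the autumn sire lottery."""
    if len(parr) == 0:
        return Fishes.empty()
    eligible = (parr.sex == MALE) & (parr.length >= params.parr_mature_min_length)
    mature = eligible & (rng.random(len(parr)) < params.parr_mature_prob)
    return parr.take(mature)


# ---------------------------------------------------------------------------
# annual orchestrator
# ---------------------------------------------------------------------------

def step_year(state: PopulationState, scenario, year: int, params, rng):
    """Advance the population by one year and record the annual censuses.

    ``scenario`` provides the intrusion/straying rules (may be ``None`` for a
    closed population).  Returns ``(state, record)`` where ``record`` is the
    census dict consumed by :mod:`salmosim.outputs`.  Stepping an extinct
    population is a no-op that yields a zero-filled record.
    """
    from . import migration
    from .outputs import empty_record

    record = empty_record(year)
    if state.extinct:
        state.year = year
        return state, record

    weights = genetics.build_locus_weights()

    # --- spring: ageing, smolting, emergence -------------------------------
    parr = state.parr
    parr.fw_age = parr.fw_age + 1
    smolts, parr = smoltify(parr, params, rng)

    recruits = recruit_juveniles(state.families, params, rng)
    if len(recruits):
        record["juv_len_may"] = float(recruits.length.mean())
        record["s_embryo"] = float(recruits.s_value(EMBRYO, weights).mean())
    parr = Fishes.concat([parr, recruits])

    for age in (1, 2, 3):
        grp = smolts.take(smolts.fw_age == age)
        record[f"smolt_n_{age}"] = len(grp)
        if len(grp):
            record[f"smolt_len_{age}"] = float(grp.length.mean())
    if len(smolts):
        record["s_smolt"] = float(smolts.s_value(JUVENILE, weights).mean())

    # --- summer growth and October parr census -----------------------------
    parr = grow_freshwater(parr, params, rng)
    for age in (0, 1, 2, 3):
        grp = parr.take(parr.fw_age == age)
        record[f"parr_n_{age}"] = len(grp)
        if len(grp):
            record[f"parr_len_{age}"] = float(grp.length.mean())
    if len(parr):
        record["s_parr"] = float(parr.s_value(JUVENILE, weights).mean())

    # --- winter freshwater survival ----------------------------------------
    parr = survive_freshwater(parr, params, rng)

    # --- marine year and maturation ----------------------------------------
    sea = Fishes.concat([state.sea, smolts])
    sea = marine_transition(sea, params, rng)
    returners, sea = decide_return(sea, params, rng)

    record["ret_n_total"] = len(returners)
    for age in (1, 2, 3):
        grp = returners.take(returners.sea_age == age)
        record[f"ret_n_{age}"] = len(grp)
        if len(grp):
            record[f"ret_len_{age}"] = float(grp.length.mean())
    if len(returners):
        record["s_adult"] = float(returners.s_value(ADULT, weights).mean())

    # --- migration injection ------------------------------------------------
    n_escapees = n_strayers = 0
    escapees = strayers = Fishes.empty()
    if scenario is not None:
        n_escapees = migration.escapee_count(scenario.intrusion, len(returners), year)
        n_strayers = migration.strayer_count(scenario.straying, len(returners), year)
        if len(returners):
            focal_freq = genetics.allele_frequency(returners.genomes)
        elif state.n_alive():
            focal_freq = genetics.allele_frequency(state.all_genomes())
        else:
            focal_freq = params.wild_freq
        stray_freq = migration.strayer_allele_freq(scenario.straying, focal_freq, params)
        escapees = migration.make_escapee_cohort(n_escapees, params, rng)
        strayers = migration.make_strayer_cohort(n_strayers, stray_freq, params, rng)
    record["escapees_in"] = n_escapees
    record["strayers_in"] = n_strayers

    # --- autumn spawning ----------------------------------------------------
    spawners = Fishes.concat([returners, escapees, strayers])
    mature_parr = select_mature_parr(parr, params, rng)
    families = spawn(
        spawners.take(spawners.sex == FEMALE),
        spawners.take(spawners.sex == MALE),
        mature_parr,
        params,
        rng,
    )
    record["egg_n"] = families.total_eggs
    record["egg_per_m2"] = families.total_eggs / params.habitat_area

    # neutral-locus tracer over all living fish
    state.parr, state.sea, state.families = parr, sea, families
    state.year = year
    if state.n_alive():
        record["neutral_freq"] = genetics.neutral_locus_frequency(state.all_genomes())
    state.extinct = state.n_alive() == 0 and families.total_eggs <= 0
    return state, record
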