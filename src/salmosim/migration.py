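"""External cohorts: domesticated escapees and wild strayers.

Escapee intrusion is expressed relative to the number of wild adults
returning to the focal river: either a fixed count per year (e.g. 250, which
equals 50% of a 500-fish baseline return) or a fixed fraction of the current
wild return (so the cohort shrinks as the focal population declines).
Escapees are injected only during the intrusion phase (years 1–200 by
default); strayers — wild fish from a neighbouring population — continue
through the recovery phase, since straying is a natural process.

Strayer genotypes come either from a fixed, non-admixed neighbour (allele
frequency 0.8, slightly below the locally adapted 0.9) or from a neighbour
that is domestication-admixed to the same degree as the focal population
(the "tracked" rule, scaling the 0.8 baseline by the focal population's
current mean admixture relative to its pristine 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import genetics
from .lifecycle import FARMED, STRAYER, Fishes


@dataclass(frozen=True)
class IntrusionRule:
    """Escapee injection rule: fixed count or fixed fraction of wild returners."""

    mode: str                      # "fixed_n" | "fixed_fraction"
    value: float
    active_years: tuple = (1, 200)

    def __post_init__(self):
        if self.mode not in ("fixed_n", "fixed_fraction"):
            raise ValueError(f"unknown intrusion mode {self.mode!r}")
        if self.mode == "fixed_n" and (self.value < 0 or self.value != int(self.value)):
            raise ValueError("fixed_n value must be a non-negative integer")
        if self.mode == "fixed_fraction" and not 0.0 <= self.value <= 1.0:
            raise ValueError("fixed_fraction value must be in [0, 1]")


@dataclass(frozen=True)
class StrayerRule:
    """Strayer injection rule plus the admixture state of the neighbour."""

    mode: str                      # "fixed_n" | "fixed_fraction"
    value: float
    admixture: str = "fixed_0.8"   # "fixed_0.8" | "tracked"
    active_years: tuple = (1, 400)

    def __post_init__(self):
        if self.mode not in ("fixed_n", "fixed_fraction"):
            raise ValueError(f"unknown strayer mode {self.mode!r}")
        if self.admixture not in ("fixed_0.8", "tracked"):
            raise ValueError(f"unknown admixture rule {self.admixture!r}")
        if self.mode == "fixed_n" and (self.value < 0 or self.value != int(self.value)):
            raise ValueError("fixed_n value must be a non-negative integer")
        if self.mode == "fixed_fraction" and not 0.0 <= self.value <= 1.0:
            raise ValueError("fixed_fraction value must be in [0, 1]")


def _count(rule, wild_returners: int, year: int) -> int:
    if wild_returners < 0:
        raise ValueError("wild returner count must be non-negative")
    lo, hi = rule.active_years
    if not lo <= year <= hi:
        return 0
    if rule.mode == "fixed_n":
        return int(rule.value)
    # round-half-to-even, clamped at zero
    return max(0, int(np.round(rule.value * wild_returners)))


def escapee_count(rule: IntrusionRule, wild_returners: int, year: int) -> int:
    """Number of escapees entering the river in ``year`` (0 outside years 1–200)."""
    return _count(rule, wild_returners, year)


def strayer_count(rule: StrayerRule, wild_returners: int, year: int) -> int:
    """Number of strayers entering the river in ``year`` (continues in recovery)."""
    return _count(rule, wild_returners, year)


def strayer_allele_freq(rule: StrayerRule, focal_mean_freq: float, params) -> float:
    """Allele frequency of this year's strayer cohort.

    Non-admixed neighbours stay at the 0.8 baseline.  Tracked neighbours scale
    the baseline by the focal population's current mean frequency relative to
    its pristine 0.9, preserving the 0.8/0.9 local-adaptation deficit while
    following the focal admixture; the result is clamped to [0.1, 0.8].
    """
    if not 0.0 <= focal_mean_freq <= 1.0:
        raise ValueError("focal mean frequency must be in [0, 1]")
    if rule.admixture == "fixed_0.8":
        return params.strayer_freq
    scaled = params.strayer_freq * focal_mean_freq / params.wild_freq
    return float(np.clip(scaled, params.farmed_freq, params.strayer_freq))


def _make_adult_cohort(n: int, freq: float, origin: int, params, rng) -> Fishes:
    if n < 0:
        raise ValueError("cohort size must be non-negative")
    if n == 0:
        return Fishes.empty()
    length = np.maximum(
        rng.normal(params.injected_length_mean, params.injected_length_sd, n), 30.0
    )
    # alternate sexes for an exactly balanced cohort, shuffled for pairing
    sex = (np.arange(n) % 2).astype(np.uint8)
    rng.shuffle(sex)
    return Fishes(
        sex=sex,
        origin=np.full(n, origin, np.uint8),
        fw_age=np.zeros(n, np.int32),
        sea_age=np.full(n, 2, np.int32),
        length=length,
        genomes=genetics.draw_genomes(n, freq, rng),
    )


def make_escapee_cohort(n: int, params, rng) -> Fishes:
    """``n`` adult escapees: farmed origin, 50:50 sexes, allele frequency 0.1.

    Escapees receive adult sizes drawn from the wild-returner length
    distribution of the modal sea age — their farm growth history is not
    modelled; their effect is genetic (frequency 0.1) plus the reduced
    spawning-success multipliers.
    """
    return _make_adult_cohort(n, params.farmed_freq, FARMED, params, rng)


def make_strayer_cohort(n: int, freq: float, params, rng) -> Fishes:
    """``n`` adult wild strayers at the given allele frequency, full success."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    return _make_adult_cohort(n, freq, STRAYER, params, rng)
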