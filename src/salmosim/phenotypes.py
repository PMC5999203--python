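"""Genotype-to-phenotype maps and escapee spawning success.

Each gene set's scaled allelic value S in [0, 1] is converted into a trait
multiplier through an affine map anchored at the two genetic extremes:
S = 0 is the fully domesticated genotype, S = 1 the fully wild one.  Survival
maps increase with S (wild alleles confer higher survival at every stage);
growth maps decrease with S (domestication selected for fast growth); the
maturation-probability map increases with S (wild alleles confer earlier
maturation, domestication selects for delayed onset of maturation).

Domesticated escapees additionally suffer reduced spawning success relative
to wild fish of the same sex: 30% for females and 5% for males.  Under equal
sex ratios this means an intrusion level of fraction ``q`` contributes
``q * (0.30 + 0.05) / 2`` of the gene pool per year — 1.75% at 10% intrusion
and 8.75% at 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SEXES = ("F", "M")
ORIGINS = ("wild", "farmed", "strayer")


@dataclass(frozen=True)
class TraitMap:
    """Affine genotype–phenotype map anchored at the two genetic extremes.

    ``at_s0`` is the trait multiplier of the fully domesticated genotype,
    ``at_s1`` that of the fully wild genotype.
    """

    at_s0: float
    at_s1: float

    @property
    def increasing(self) -> bool:
        return self.at_s1 > self.at_s0


@dataclass(frozen=True)
class SpawningSuccess:
    """Escapee spawning success relative to wild spawners of the same sex."""

    female_relative: float = 0.30
    male_relative: float = 0.05

    def __post_init__(self) -> None:
        for v in (self.female_relative, self.male_relative):
            if not 0.0 < v <= 1.0:
                raise ValueError("relative spawning success must be in (0, 1]")


def trait_value(trait_map: TraitMap, s):
    """Evaluate an affine trait map at scaled allelic value(s) ``s``.

    Accepts scalars or arrays; raises if any value falls outside [0, 1].
    """
    s = np.asarray(s, dtype=float)
    if s.size and (np.nanmin(s) < 0.0 or np.nanmax(s) > 1.0):
        raise ValueError("scaled allelic value must be in [0, 1]")
    out = trait_map.at_s0 + s * (trait_map.at_s1 - trait_map.at_s0)
    return out if out.ndim else float(out)


def effective_gene_flow(intrusion_fraction: float, success: SpawningSuccess) -> float:
    """Per-year proportional genetic contribution of escapees.

    With equal sex ratios among intruders, the expected gene-pool share is the
    intrusion fraction times the mean of the two sex-specific relative
    spawning-success multipliers.
    """
    if not 0.0 <= intrusion_fraction <= 1.0:
        raise ValueError("intrusion fraction must be in [0, 1]")
    return intrusion_fraction * (success.female_relative + success.male_relative) / 2.0


def escapee_success_multiplier(sex: str, origin: str, success: SpawningSuccess) -> float:
    """Spawning-success multiplier for one spawner.

    Farmed escapees pay the sex-specific penalty; wild fish and wild strayers
    spawn at full success.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    if origin not in ORIGINS:
        raise ValueError(f"unknown origin {origin!r}")
    if origin != "farmed":
        return 1.0
    return success.female_relative if sex == "F" else success.male_relative


def maturation_probability(s, sea_age, length, params):
    """Probability that a sea fish matures and returns this year.

    The per-sea-winter baseline rises with sea age and is multiplied by the
    maturation trait map (wild genotypes mature earlier) and by a gentle
    logistic length term (larger fish are more likely to mature).  Fish at the
    maximum sea age (3 sea winters) always return, so no fish exceeds three
    sea winters.  Vectorized over individuals.
    """
    s = np.asarray(s, dtype=float)
    sea_age = np.asarray(sea_age)
    length = np.asarray(length, dtype=float)
    if np.any(sea_age < 1):
        raise ValueError("maturation decisions apply to fish with sea age >= 1")
    if length.size and np.nanmin(length) <= 0:
        raise ValueError("length must be positive")

    base = np.ones(np.broadcast_shapes(s.shape, sea_age.shape, length.shape))
    for age, b in enumerate(params.maturation_base, start=1):
        base = np.where(sea_age == age, b, base)
    if params.selection_disabled:
        mod = 1.0
    else:
        mod = trait_value(params.maturation_map, s)
    size_term = 1.0 / (
        1.0
        + np.exp(-(length - params.maturation_length_mid) / params.maturation_length_scale)
    )
    prob = np.clip(base * mod * size_term, 0.0, 1.0)
    prob = np.where(sea_age >= params.max_sea_age, 1.0, prob)
    return prob if prob.ndim else float(prob)
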