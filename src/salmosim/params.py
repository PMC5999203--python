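"""Model parameters: habitat constants, stage baselines, and trait-map anchors.

All rates and capacities live in one dataclass so a run is fully specified by
(parameters, scenario, seed).  Defaults are the calibrated baseline: with no
intrusion and no straying they yield a demographically stable wild population
returning roughly 500 adults per year, with 0+ the largest parr age class and
2+ the largest smolt age class — the life-history profile of a small Norwegian
salmon river.  Parameters can be overridden from a YAML config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phenotypes import SpawningSuccess, TraitMap


@dataclass
class ModelParams:
    # --- habitat -----------------------------------------------------------
    #: wetted habitat area of the focal river, m^2
    habitat_area: float = 10_000.0

    # --- allometry (single rule for all stages) ----------------------------
    #: weight (g) = weight_coeff * length(cm) ** weight_exponent
    weight_coeff: float = 0.010
    weight_exponent: float = 3.0

    # --- initial allele frequencies ----------------------------------------
    wild_freq: float = 0.9
    farmed_freq: float = 0.1
    strayer_freq: float = 0.8

    # --- spawning ----------------------------------------------------------
    #: eggs per gram of female body weight
    fecundity_per_g: float = 1.4
    success: SpawningSuccess = field(default_factory=SpawningSuccess)
    #: competitive weight of a mature male parr in the sire lottery,
    #: in cm-equivalents of adult male length
    parr_sire_weight: float = 2.0
    #: minimum length (cm) and probability for a male parr to mature precociously
    parr_mature_min_length: float = 8.0
    parr_mature_prob: float = 0.4

    # --- genotype -> phenotype maps (multipliers on stage baselines) -------
    embryo_survival_map: TraitMap = field(default_factory=lambda: TraitMap(0.5, 1.0))
    juvenile_survival_map: TraitMap = field(default_factory=lambda: TraitMap(0.5, 1.0))
    adult_survival_map: TraitMap = field(default_factory=lambda: TraitMap(0.5, 1.0))
    juvenile_growth_map: TraitMap = field(default_factory=lambda: TraitMap(1.2, 1.0))
    adult_growth_map: TraitMap = field(default_factory=lambda: TraitMap(1.2, 1.0))
    maturation_map: TraitMap = field(default_factory=lambda: TraitMap(0.5, 1.0))
    #: flatten every map to a constant 1.0 multiplier (drift-only runs)
    selection_disabled: bool = False

    # --- egg-to-parr recruitment (Beverton–Holt) ----------------------------
    #: maximum egg-to-0+ survival at low density (before the genetic modifier)
    egg_max_survival: float = 0.02
    #: effective egg pool at which recruitment is half-saturated
    egg_half_saturation: float = 320_000.0
    #: fry length (cm) at spring emergence
    emergence_length: float = 3.5

    # --- freshwater (parr) stage -------------------------------------------
    #: summer length increment (cm) at low density, by freshwater age 0..3
    parr_growth_increments: tuple = (3.25, 2.75, 2.3, 2.0)
    #: lognormal sigma of individual growth variation per summer
    parr_growth_sigma: float = 0.18
    #: parr density (fish / m^2) at which the growth factor halves
    parr_density_half: float = 20.0
    #: baseline annual parr survival by freshwater age 0..3
    parr_survival_base: tuple = (0.55, 0.60, 0.65, 0.65)
    #: half-saturation length (cm) of the size–survival factor L/(L + h)
    parr_size_half: float = 1.5
    #: parr at or above this May length (cm) smolt and leave the river
    smolt_threshold: float = 9.0
    #: parr still in the river past this freshwater age die
    max_freshwater_age: int = 3

    # --- marine stage -------------------------------------------------------
    #: survival of the first sea year and of later sea years
    marine_survival_first: float = 0.70
    marine_survival_later: float = 0.80
    #: marine length increment (cm) by sea age at entry 0, 1, 2
    marine_growth_increments: tuple = (40.0, 15.0, 10.0)
    marine_growth_sigma: float = 0.08
    #: per-sea-winter baseline maturation probability at sea ages 1, 2
    maturation_base: tuple = (0.45, 0.60)
    #: logistic length term of maturation: midpoint (cm) and scale (cm)
    maturation_length_mid: float = 40.0
    maturation_length_scale: float = 5.0
    max_sea_age: int = 3

    # --- injected adult phenotype -------------------------------------------
    #: length distribution (cm) assigned to injected escapees and strayers,
    #: matching wild returners of the modal sea age
    injected_length_mean: float = 62.0
    injected_length_sd: float = 4.0

    # --- initialization ------------------------------------------------------
    init_parr: tuple = (5000, 2000, 800)
    init_parr_length: tuple = (7.5, 11.0, 14.0)
    init_sea: tuple = (700, 250)
    init_sea_length: tuple = (50.0, 62.0)
    init_spawning_females: int = 250

    def weight_of(self, length):
        """Allometric weight (g) for length(s) in cm."""
        import numpy as np

        return self.weight_coeff * np.asarray(length, dtype=float) ** self.weight_exponent

    # --- (de)serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["success"] = dataclasses.asdict(self.success)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(fields)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        kwargs = {}
        for name, value in d.items():
            if name == "success":
                value = SpawningSuccess(**value) if isinstance(value, dict) else value
            elif name.endswith("_map") and isinstance(value, (dict, list, tuple)):
                value = TraitMap(**value) if isinstance(value, dict) else TraitMap(*value)
            elif isinstance(value, list):
                value = tuple(value)
            kwargs[name] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)
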