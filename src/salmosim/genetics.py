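"""Multilocus genetic architecture of the simulated salmon.

Every individual carries three independent gene sets — one influencing the
embryo stage (egg to early parr), one the juvenile freshwater stage (parr to
smolt), and one the adult/marine stage.  Each gene set consists of 21 unlinked
diploid biallelic loci (alleles 0/1).  Loci 1–20 influence the phenotype with
an exponentially declining weight, from 15% for the first locus to 1% for the
20th; locus 21 carries no weight and serves as a selectively neutral
introgression tracer.

The scaled average allelic value ``S`` of a gene set is the weighted mean
allele-1 dose across the 20 active loci, scaled to [0, 1]: an individual that
is homozygous "11" at every active locus has S = 1 (the wild extreme), a "00"
homozygote has S = 0 (the domesticated extreme).

Genomes are stored as a stacked ``uint8`` array of shape ``(n, 3, 21, 2)``
(individual, gene set, locus, allele copy) so that whole cohorts are drawn,
recombined and scored with vectorized operations.
"""

from __future__ import annotations

import numpy as np

#: Names of the three gene sets, in storage order.
GENE_SETS = ("embryo", "juvenile", "adult")
EMBRYO, JUVENILE, ADULT = 0, 1, 2

N_GENE_SETS = 3
N_LOCI = 21          # loci per gene set, incl. the neutral one
N_ACTIVE_LOCI = 20   # phenotypically active loci
NEUTRAL_LOCUS = 20   # 0-based index of the neutral (21st) locus
PLOIDY = 2

GENOME_SHAPE = (N_GENE_SETS, N_LOCI, PLOIDY)


def gene_set_index(gene_set: str | int) -> int:
    """Resolve a gene-set name or index to the storage axis index."""
    if isinstance(gene_set, (int, np.integer)):
        if not 0 <= int(gene_set) < N_GENE_SETS:
            raise ValueError(f"gene set index out of range: {gene_set}")
        return int(gene_set)
    try:
        return GENE_SETS.index(gene_set)
    except ValueError:
        raise ValueError(
            f"unknown gene set {gene_set!r}; expected one of {GENE_SETS}"
        ) from None


def build_locus_weights(
    n_active: int = N_ACTIVE_LOCI,
    w_first: float = 0.15,
    w_last: float = 0.01,
) -> np.ndarray:
    """Locus-influence weights: a geometric decline, renormalized to sum 1.

    The raw sequence runs from ``w_first`` (15% by default) down to ``w_last``
    (1%) over ``n_active`` loci with a constant successive ratio.  The printed
    endpoints sum to slightly more than one, so the vector is renormalized;
    this makes the scaled allelic value exactly 0 and 1 at the two homozygous
    extremes.
    """
    if n_active < 2:
        raise ValueError("need at least two active loci")
    if not (0.0 < w_last < w_first):
        raise ValueError("weights must satisfy 0 < w_last < w_first")
    ratio = (w_last / w_first) ** (1.0 / (n_active - 1))
    weights = w_first * ratio ** np.arange(n_active, dtype=float)
    return weights / weights.sum()


def validate_genomes(genomes: np.ndarray) -> np.ndarray:
    """Check shape and allele alphabet; returns the array unchanged."""
    genomes = np.asarray(genomes)
    if genomes.ndim != 4 or genomes.shape[1:] != GENOME_SHAPE:
        raise ValueError(
            f"genome array must have shape (n, {N_GENE_SETS}, {N_LOCI}, {PLOIDY}); "
            f"got {genomes.shape}"
        )
    if genomes.size and not np.isin(genomes, (0, 1)).all():
        raise ValueError("alleles must be 0 or 1")
    return genomes


def draw_genomes(n: int, allele_freq: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` genomes with independent alleles at P(allele = 1) = freq.

    Every allele copy, including the neutral locus, is an independent
    Bernoulli draw, so a cohort drawn at frequency ``f`` carries the same
    expected frequency at the neutral tracer locus as at the active loci.
    """
    if not 0.0 <= allele_freq <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1]; got {allele_freq}")
    return (rng.random((n, *GENOME_SHAPE)) < allele_freq).astype(np.uint8)


def scaled_allelic_value(
    genomes: np.ndarray,
    gene_set: str | int,
    weights: np.ndarray,
) -> np.ndarray:
    """Scaled average allelic value S of one gene set, per individual.

    S = sum_i w_i * (allele-1 dose at locus i) / 2 over the active loci;
    the neutral locus is ignored.  Returns a vector of length n in [0, 1].
    """
    genomes = np.asarray(genomes)
    idx = gene_set_index(gene_set)
    weights = np.asarray(weights, dtype=float)
    n_active = len(weights)
    dose = genomes[:, idx, :n_active, 0] + genomes[:, idx, :n_active, 1]
    return (dose.astype(np.float64) @ weights) / PLOIDY


def make_gametes(genomes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One haploid gamete per parent genome, by free assortment.

    All loci are unlinked: at each locus one of the parent's two allele
    copies is chosen independently with probability 1/2.  Returns an array of
    shape ``(n, 3, 21)``.
    """
    genomes = np.asarray(genomes)
    if genomes.ndim != 4 or genomes.shape[1:] != GENOME_SHAPE:
        raise ValueError(f"invalid genome array shape {genomes.shape}")
    pick = rng.random(genomes.shape[:3]) < 0.5
    return np.where(pick, genomes[..., 0], genomes[..., 1])


def fertilize(maternal: np.ndarray, paternal: np.ndarray) -> np.ndarray:
    """Pair maternal and paternal haploid sets into diploid offspring genomes."""
    maternal = np.asarray(maternal)
    paternal = np.asarray(paternal)
    expected = (N_GENE_SETS, N_LOCI)
    if maternal.shape[1:] != expected or paternal.shape[1:] != expected:
        raise ValueError("haploid sets must have shape (n, 3, 21)")
    if maternal.shape != paternal.shape:
        raise ValueError("maternal and paternal sets differ in size")
    return np.stack([maternal, paternal], axis=-1).astype(np.uint8)


def allele_frequency(
    genomes: np.ndarray,
    gene_set: str | int | None = None,
    locus: int | None = None,
) -> float:
    """Mean fraction of allele-1 copies across a population.

    With ``gene_set``/``locus`` given, restricted to that locus; with both
    omitted, averaged over all active (non-neutral) loci of all gene sets —
    the population-mean admixture level used to condition tracked strayers.
    """
    genomes = np.asarray(genomes)
    if genomes.shape[0] == 0:
        raise ValueError("cannot compute allele frequency of an empty population")
    if gene_set is None and locus is None:
        return float(genomes[:, :, :N_ACTIVE_LOCI, :].mean())
    if gene_set is None or locus is None:
        raise ValueError("specify both gene_set and locus, or neither")
    idx = gene_set_index(gene_set)
    if not 0 <= locus < N_LOCI:
        raise ValueError(f"locus index out of range: {locus}")
    return float(genomes[:, idx, locus, :].mean())


def neutral_locus_frequency(genomes: np.ndarray) -> float:
    """Allele-1 frequency at the neutral 21st locus, averaged over gene sets."""
    genomes = np.asarray(genomes)
    if genomes.shape[0] == 0:
        raise ValueError("cannot compute allele frequency of an empty population")
    return float(genomes[:, :, NEUTRAL_LOCUS, :].mean())
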