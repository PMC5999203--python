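# Methods

## Scope and design

`salmosim` is a forward-time, individual-based eco-genetic model of one
focal wild Atlantic salmon river receiving two external cohorts each
autumn: domesticated farm escapees and wild strayers from an implicit
neighbouring population. The model tracks every living fish (vectorized as
struct-of-arrays cohorts) through a fixed annual event order; eggs are
carried as family counts and individual genomes are realized only for
recruits that survive to the 0+ parr stage, which keeps a 400-year,
10-replicate scenario batch inside a desktop memory and time budget.

## Genetic architecture

Three independent gene sets control the embryo (egg→early parr), juvenile
(parr→smolt) and adult (marine) stages. Each set has 21 unlinked diploid
biallelic loci. Loci 1–20 carry geometrically declining influence weights
with a 15:1 first-to-last ratio; because the raw 15%…1% sequence sums to
≈1.064, the weights are renormalized to sum to exactly 1 so that the scaled
average allelic value S (the weighted mean allele-1 dose) is exactly 0 and
1 at the "00" and "11" homozygous extremes. Locus 21 carries no weight and
is selectively neutral; it is initialized at the same cohort frequency as
the weighted loci (0.9 wild / 0.1 escapee / 0.8 strayer) so that it acts as
a selection-free introgression tracer. Inheritance is by free assortment:
one of the parent's two allele copies is drawn independently at each locus
(no linkage, no mutation).

## Genotype–phenotype maps

Each map is affine in S between the domesticated anchor (S = 0) and the
wild anchor (S = 1) and acts as a multiplier on a calibrated stage
baseline:

| map                     | at S = 0 | at S = 1 | direction           |
|-------------------------|---------:|---------:|---------------------|
| survival (all 3 stages) |     0.50 |     1.00 | wild survive better |
| growth (juv., adult)    |     1.20 |     1.00 | farmed grow faster  |
| maturation probability  |     0.50 |     1.00 | wild mature earlier |

The maturation direction deserves a note: domestication selects for fast
growth and *delayed* maturation, so the wild genotype has the higher
per-sea-winter maturation probability. The anchor magnitudes are model
design choices (the precursor model's stage equations are not public): with
survival acting at roughly five stage-years per generation, a pure
domesticated genotype has a lifetime fitness of roughly 5–10% of wild,
matching the field-experiment range reported for farm offspring in the
wild. The survival anchor also interacts with the recruitment asymptote
(below) so that a fully introgressed population is below demographic
replacement — without this property the model cannot reproduce the
extinction of the most extreme global-introgression scenario, which is a
central qualitative outcome of the study design.

Escapee spawning success is 30% (females) and 5% (males) of wild success;
wild strayers spawn at full success. With equal sex ratios this yields the
analytic gene-flow identity: intrusion fraction q contributes
q·(0.30+0.05)/2 per year (1.75% at q = 0.10, 8.75% at q = 0.50).

## Life cycle

One simulated year, in order:

1. **May — smolting.** Parr age one year; parr whose length ≥ 9.0 cm leave
   as smolts (boundary inclusive); parr still in the river past freshwater
   age 3 die. Under the calibrated baseline the realized smolt ages are
   1+–3+ with 2+ the largest class.
2. **May — emergence.** The previous autumn's egg families recruit to 0+
   parr under a Beverton–Holt cap: recruits ~ Poisson(S_max·E/(1+E/E_half))
   with S_max = 0.02 (maximum egg-to-0+ survival) and E_half = 320,000 eggs,
   where E weights each family's eggs by the embryo-survival multiplier of
   the mid-parent embryo genotype. Each recruit draws its family
   proportionally to that weighted contribution and receives a fresh
   Mendelian genome from the recorded parents; sexes 50:50.
3. **Summer — freshwater growth.** Length increment = age-specific baseline
   (3.25/2.75/2.3/2.0 cm for ages 0–3) × growth map × density factor
   1/(1 + D/20) (D = parr/m², area 10,000 m²) × lognormal individual noise
   (σ = 0.18). October parr census by age.
4. **Winter — freshwater survival.** Baseline (0.55/0.60/0.65/0.65 by age)
   × juvenile survival map × size factor L/(L+1.5).
5. **Sea year.** Survival 0.70 (first sea year) or 0.80 (later) × adult
   survival map; growth increment 40/15/10 cm × adult growth map × noise;
   sea age increments.
6. **Maturation.** P(return) = base (0.45 at 1SW, 0.60 at 2SW) × maturation
   map × a logistic length term (midpoint 40 cm, scale 5 cm); forced at 3
   sea winters. Returners are censused by sea age.
7. **Autumn — migration and spawning.** Escapee and strayer cohorts are
   injected (counts per the scenario rules, computed on the number of wild
   adults returning that year); returners, injected adults and precocious
   mature male parr spawn. Female eggs = 1.4 per g body weight (weight =
   0.01·L³ g) × the escapee success multiplier; one sire per female drawn
   with probability ∝ length × male success multiplier, mature parr entering
   at a fixed 2 cm-equivalent weight. All adult spawners die (semelparous
   closure; the effect of iteroparous kelts is not modelled).

Escapees are injected in years 1–200 only; strayers continue through the
recovery phase (straying is a natural process and the neighbouring
population is not assumed to vanish). Injected adults receive lengths from
the wild modal-returner distribution (62 ± 4 cm) — the farm growth history
of escapees is deliberately not modelled; their effect is genetic (allele
frequency 0.1) plus the success multipliers. "Tracked" strayer admixture
scales the 0.8 baseline by the focal population's current mean frequency
relative to its pristine 0.9 (multiplicative rule, clamped to [0.1, 0.8]),
preserving the local-adaptation deficit while following focal admixture.

## Calibration

The closed (no intrusion, no straying) population must return ≈500 adults
per year (the reference point that makes 250 escapees "50% intrusion" and
25 strayers "5%"), persist 400 years in 10/10 replicates, and show modal
parr age 0+ and modal smolt age 2+ with all three sea-age return classes
occupied. `calibrate_baseline` verifies these targets and, if the return is
off, adjusts the egg-pool half-saturation (which scales the equilibrium
roughly linearly) over a deterministic multiplicative search; the packaged
defaults already satisfy every target (mean return ≈ 515, zero
extinctions), so the search is a verification pass. A 50-year burn-in from
a rough stage-structured initial profile precedes every recorded run; burn-in
years are discarded.

The deliberate choice of a low recruitment asymptote (S_max = 0.02, i.e.
weak low-density compensation) is what separates the two central scenario
outcomes: under local introgression (fixed 25 non-admixed strayers) the
population equilibrates at roughly 200–230 returning adults, while under
global introgression (admixed, proportional strayers) sustained intrusion
pushes the mean genotype low enough that the population is below
replacement and goes extinct. With a high asymptote the same genetic
trajectories produced demographic recovery instead of extinction.

## Outputs and summaries

Each year records: eggs deposited (count and per m²), May juvenile size,
October parr count and mean length by age, May smolt count and mean length
by age, wild adult returns and mean length by sea age, the mean S of the
stage-appropriate gene set for each censused stage, and the neutral-locus
frequency. Empty classes record count 0 and a *missing* (not zero) mean.
Replicate averaging is element-wise per year; counts of extinct replicates
contribute zeros, size means are averaged over the replicates in which the
class exists.

Scalar summaries use declared windows (config-exposed): stabilization =
mean wild return over years 150–200; abundance ratio = mean(190–200) /
mean(1–10) × 100; size-at-age change per class = |Δ mean length| between
those windows / early mean × 100; extinction year = first year with zero
fish at every stage and no eggs; genetic recovery = S̄(adult set) over the
final decade minus over years 191–200.

## Numerical and reproducibility choices

All stochastic draws of a replicate flow from a single
`numpy.random.Generator` seeded `root_seed + replicate`, so batches are
bit-for-bit reproducible. Survival probabilities are clamped to [0, 1]
after composing baseline, genetic and size/density factors. Fractional
injection counts round half-to-even and clamp at ≥0. Cohort sizes from the
Beverton–Holt expectation are Poisson-distributed (demographic
stochasticity). Empty spawner lists yield reproductive failure, not errors;
stepping an extinct population is a no-op emitting a zero-count record.

## What the simulator does and does not emulate

The generator *is* the study system — no field data enter the analysis. It
reproduces the study conditions: a ~500-adult river with the stated allele
frequencies, success differentials, scenario rules and horizons. It does
not emulate: linkage or mutation; escapee river-entry timing and
farm-growth phenotypes; explicit dynamics of the neighbouring donor
population; fisheries, predation or environmental trends; iteroparity; or
within-year sub-monthly dynamics. Because the precursor model's stage
equations are not reprinted anywhere public, the stage baselines here are
re-specified and calibrated rather than copied: scenario outcomes should be
read as property-level reproductions (stabilization vs extinction,
global-vs-local ordering, bounded size change, post-intrusion recovery),
not curve-level ones. One known strength difference: the 30% fixed-N global
run declines more steeply here (to well under half of initial abundance,
with extinction in some replicates) than the original's "less than half".

## Problem sizes

Default scenario batches are 10 replicates × (50 burn-in + 200 intrusion +
200 recovery) years with populations of order 10⁴ individuals; a batch
runs in tens of seconds. The test suite uses the full design for the
acceptance-level checks and smaller closed populations (10²–10⁴
individuals, ≤ 60 years or ≤ 50 generations) for unit-level statistical
oracles.
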