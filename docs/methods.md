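# Methods

This document describes the models and algorithms implemented by `boa`, the
parameters they expose, and the design choices made where the underlying
method leaves room for interpretation.

## Overview

`boa` assigns a breed origin to every SNP allele of a crossbred animal using
only SNP genotypes and the animal's known breed composition — no pedigree and
no pre-phased reference panels. The procedure has three stages:

1. **Phasing.** Genotypes of all animals (purebred and crossbred together)
   are phased with a long-range-phasing and haplotype-library-imputation
   algorithm, repeated for a suite of core/tail window configurations.
2. **Breed haplotype library.** Within each phasing analysis and core window,
   every fully phased haplotype carried by purebred animals is counted per
   breed, and haplotypes are assigned to a breed subject to a relaxation
   factor `f_r`.
3. **Allele assignment.** Each allele of each crossbred animal receives one
   vote per phasing analysis from the breed-assigned library haplotypes that
   it carries; votes are resolved per SNP with plurality rules constrained by
   the animal's breed composition and genotype zygosity. Three optional
   post-processing rules fill in remaining unassigned alleles.

A forward-in-time simulator of a three-way crossbreeding program, with
per-allele breed-origin truth, provides the validation data, and an
evaluation module scores assignments and computes the population-genetic
summaries used to characterise the simulated breeds.

## Simulation model (`boa.simdata`)

### Genome

The default genome has two chromosomes shaped like pig chromosomes SSC1 and
SSC18: 3.20 Morgan with 6700 candidate loci and 0.61 Morgan with 1353
candidate loci, positions drawn uniformly on the genetic map
(`boa.genome.default_candidate_map`). After simulation, loci with a minor
allele frequency below 0.10 in the last historic generation are discarded
(`select_snps`), leaving a density of roughly 10–15 SNPs per cM.
`scaled_candidate_map(rng, scale)` shrinks lengths and locus counts
proportionally for desk-scale runs.

### Populations

`SimConfig` defaults encode the study conditions this package targets:

- **Historic population:** 1000 generations of random mating at census 1000,
  then 50 generations at census 100 (a bottleneck that builds linkage
  disequilibrium), then 8 generations at 60 males + 750 females. Candidate
  loci start at Bernoulli(0.5) per haplotype.
- **Breeds:** three breeds (A, B, C) are founded by sampling disjoint sets of
  20 males + 250 females from the last historic generation, then diverge by
  5, 20 or 50 generations of within-breed random mating — the
  `close`, `distant` and `unrelated` scenarios (`SCENARIOS`).
- **Crossbreeding program:** five generations run in parallel with the
  purebred populations. Each generation produces BC two-way crossbreds from
  breed-B sires and breed-C dams (10 males + 100 females kept) and A(BC)
  three-way crossbreds from breed-A sires on BC dams of the same generation
  (110 kept). The paternal/maternal haplotype of every animal is tracked, and
  crossbred gametes carry a per-locus breed-origin label propagated through
  the same crossover masks as the allele values, so the truth is exact by
  construction.
- **Panel:** 75 % of each cohort is sampled at random as the genotyped panel;
  the exported dataset contains genotypes, cohort labels and breed
  composition only (no parent identities). All purebred animals of the
  program are also exported for the F_ST characterisation.

### Meiosis

Gametes are dense `uint8` rows over all loci. Each meiosis draws, per
chromosome, a Poisson number of crossovers with mean equal to the genetic
length in Morgan (no interference) at uniform map positions, plus a fair coin
for which parental haplotype starts the chromosome; the crossover mask is
evaluated at the SNP positions by parity of crossovers to the left.
Recurrent symmetric mutation flips each transmitted allele with probability
2.5e-5. A breakpoint-segment representation would be equivalent; the dense
representation was chosen because vectorised numpy operations make the full
burn-in (1058 generations × 2000 gametes × ~8000 loci) run in minutes on one
CPU, and because every downstream stage consumes per-locus arrays anyway.
`meiosis(..., return_masks=True)` exposes the masks so tests can verify the
gamete/mask/mutation identity directly.

### Reproducibility

All stages draw from child generators spawned from a single
`numpy.random.SeedSequence(master_seed)`, so the genome, historic stage,
breed divergence, crossbreeding and panel sampling are individually
reproducible, and a precomputed historic population can be shared across
scenarios without perturbing the other streams.

## Phasing (`boa.phasing`)

Each analysis is configured by `AnalysisSettings(core_length, tail_length,
offset)`. Cores tile each chromosome consecutively (the final partial core is
retained); an *offset* analysis shifts all cores by half a core length so
core boundaries interleave with the non-offset run. The default suite
(`default_suite()`) contains nine core/tail combinations — (150,200),
(200,200), (250,100), (250,200), (300,100), (300,200), (350,50), (350,100),
(350,200) SNPs — each with and without offset: 18 analyses.

For each core, phasing proceeds per focal animal:

1. **Surrogate parents.** Any other animal with at most
   `floor(0.01 × window)` opposing homozygous genotypes across the core+tail
   window qualifies as a surrogate parent (the allowance absorbs genotype
   errors; opposing homozygotes are impossible between haplotype sharers
   without error).
2. **Side partition.** Surrogates are split into two groups, one per focal
   haplotype. The conflict graph (an edge between surrogates whose own
   opposing-homozygote count exceeds the allowance) is 2-coloured by
   breadth-first search, refined by two local sweeps, and then polished by a
   signed rank-one power iteration on the ±1 homozygosity-evidence matrix
   over the focal animal's heterozygous SNPs in the window. The power
   iteration is this package's design choice: the grouping criterion is
   otherwise under-determined, and the rank-one refinement measurably reduces
   within-side disagreement (het-phase error 3.9 % → 1.1 % on a full-census
   chromosome in internal measurements). At most 300 surrogates (the closest
   by opposing count) are used per focal animal.
3. **Declaration.** For each side and each heterozygous core SNP, surrogates
   homozygous at that SNP vote for the allele carried by the shared
   haplotype. The allele is declared if at least 10 surrogates are
   informative and at most 10 % of them disagree; the other haplotype
   receives the genotype complement. Homozygous SNPs are trivially phased.
4. **Library imputation.** Within each analysis, partially phased haplotypes
   are completed from the set of fully phased core haplotypes: a unique
   exactly-matching library haplotype is adopted if it does not create
   opposing homozygotes against the animal's current other haplotype; if the
   genotype-complement of a library haplotype is itself in the library the
   pair is adopted; and when several (≤500) matching library haplotypes all
   agree at a locus and the value is genotype-consistent, that locus is
   filled by consensus. Iterated to a fixed point (≤5 rounds). The
   pair-consistency recheck and the consensus fill are conservative
   extensions of plain unique-match imputation; both preserve the invariant
   that resolved haplotype pairs sum to the genotype.

`run_phasing_suite` returns per-analysis `PhasedAnalysis` objects (cores and
`(n, 2, L)` haplotype arrays per chromosome, `-1` for unresolved alleles).
Runs are deterministic: no randomness is used anywhere in phasing.

### Compiled kernels

The per-focal partition/declaration loop (`boa._kernels.phase_window`) and
the meiosis crossover-mask builder (`boa._kernels.crossover_fill`) are
numba-compiled ports of pure-numpy reference implementations, which remain
in the code base (`_phase_chromosome(..., use_kernel=False)` and
`crossover_masks(..., use_kernel=False)`). Every operation in both kernels
is exact small-integer arithmetic (including the float32 mat-vec, whose
operands are −1/0/+1 with sums far below 2⁻²⁴-loss territory), so compiled
and reference paths produce bit-identical output; the test-suite asserts
this equivalence directly. The kernels exist purely so full-census panels
(~3850 animals) phase in seconds per analysis on one CPU.

## Breed haplotype library (`boa.breedlib`)

For every analysis × core window, each *fully* resolved core haplotype
observed in purebred panel animals is counted per breed. A haplotype is
assigned to its single most frequent breed if the copies observed in the
other breeds are strictly below `f_r` percent of its total count
(`assign_haplotype_origins`). With `f_r = 0` the haplotype must be entirely
absent from the other breeds. Larger `f_r` assigns more haplotypes (fewer
unknowns downstream) at the cost of occasionally assigning a shared
haplotype, which matters most for closely related breeds. The library is
therefore parameterised by `f_r ∈ [0, 50)`, with 0, 10 and 20 % as the
values studied.

## Allele assignment (`boa.assignment`)

For each crossbred animal and each phasing analysis, the animal's phased core
haplotypes are looked up in the breed-assigned library. Each SNP allele
receives at most one vote per analysis (so at most 2 × 18 votes per
genotype): the breed of the library haplotype carrying it, provided the
haplotype is fully resolved and assigned. Votes are then resolved per SNP:

- **Zygosity constraint.** The unphased genotype is authoritative: at a
  heterozygous genotype the two alleles are the two observed values; vote
  stacks that would imply the wrong zygosity are inadmissible.
- **Two-way crossbreds** (composition {B, C}): each allele takes the breed
  with a strict plurality of its votes. If both alleles of a heterozygous
  genotype resolve to the same breed, the allele with the weaker support is
  reverted to unknown (the composition admits one allele per breed at
  most in a first-generation cross only for conflicting evidence; reverting
  the weaker claim avoids compounding an error).
- **Three-way crossbreds** (A sire on BC dam): the paternal allele is breed A
  by composition; the slot carrying A-votes is identified first (paternal
  first), the remaining slot is assigned B or C by strict plurality. At
  homozygous genotypes the first slot is A by composition alone (recorded
  with a distinct provenance code), and the second is put to the vote.
- Ties leave the allele unknown; every assignment records a provenance code
  (core vote, composition, or post-rule 1–3).

### Post-processing rules (`apply_post_rules`)

1. If the maternal allele of a SNP is assigned and the paternal is not, the
   paternal allele of a three-way crossbred is assigned the paternal breed
   (and correspondingly for two-way crossbreds via rule 2).
2. For animals of two breeds, an unassigned allele opposite an assigned one
   takes the other breed of the composition.
3. An unassigned stretch flanked on both sides by alleles assigned the same
   breed is filled with that breed if both flanking alleles occur in one
   library haplotype — with that breed assigned, spanning the stretch, from
   the analysis with the smallest core length — whose allele values are used
   to orient heterozygous genotypes inside the stretch.

Rules 1–2 add assignments that are correct whenever the original assignment
was; rule 3 interpolates within a haplotype match. All three raise %correct
and (slightly) %incorrect, and are off by default.

## Evaluation (`boa.evaluation`)

- `assignment_stats` scores assigned origins against simulated truth per
  animal and chromosome (%correct / %incorrect / %unknown, summing to 100
  exactly). At heterozygous genotypes, assignment slots are matched to truth
  by allele value; at homozygous genotypes the orientation is unordered, so
  the slot pairing that agrees most with truth is used (composition-forced
  paternal slots in three-way animals are honoured).
- `global_fst` implements the Weir–Cockerham (1984) variance-components
  estimator, accumulated as a ratio of sums across loci, on genotype dosage
  matrices with population labels; monomorphic and single-population loci
  are excluded. This is hand-implemented (and verified against an
  independent scalar implementation in the tests) because no installed
  package exposes the estimator on genotype matrices.
- `expected_correct_het(q_B, q_C)` is the closed-form expected %correct for
  heterozygous genotypes of a two-way crossbred when assignment uses breed
  minor-allele frequencies only:
  `100 · max((1−q_B)q_C, (1−q_C)q_B) / ((1−q_B)q_C + (1−q_C)q_B)`.
  It equals exactly 50 when `q_B = q_C` and exactly 100 when either
  frequency is 0. `observed_het_correct` computes the matching observable
  (per-SNP %correct among heterozygous genotypes, averaged across SNPs).
- `forward_select_analyses` greedily orders phasing analyses by any
  user-supplied criterion; `spearman_vs_predefined` compares the resulting
  order against the predefined ranking by decreasing total (core+tail)
  length, ties by decreasing core length, offset runs adjacent to their
  non-offset partners.

## File formats and CLI (`boa.io`, `boa.cli`)

Genotype panels travel as PLINK PED/MAP (alleles coded 1/2, cohort label in
the family column, genetic lengths in a sidecar TSV), as a TSV dosage matrix,
or as VCF (biallelic, placeholder alleles, read through pysam; `./.` maps to
missing). Phased analyses can be exported as phased VCFs (`.` for unresolved
alleles). Breed compositions, truth origins, assigned origins and libraries
are header-rowed TSVs. The `boa` command exposes per-stage subcommands
(`simulate`, `phase`, `build-library`, `assign`, `evaluate`, `fst`, `select`,
`run`); `boa run` writes all artefacts plus a manifest with SHA-256 digests,
and identical configurations reproduce identical files.

## Desk-scale choices

The validation suite and the reproduction script must run on one CPU in
minutes, so they scale the *problem size*, never the method:

- the full-scale simulation (two chromosomes, full census) is used for the
  F_ST characterisation, which needs no phasing;
- accuracy experiments run one replicate per scenario (the study conditions
  average 10) and restrict to the short chromosome with a subset of the
  analysis suite where stated; tolerances quoted alongside each target
  account for single-replicate sampling noise;
- the long-chromosome heterozygous-site accuracy number is computed on a
  quarter-length clone of chromosome 1 (0.80 M, same per-Morgan SNP density,
  so local LD structure matches); per-SNP accuracy is insensitive to
  chromosome length at fixed density;
- the four-analysis validation suite is (150,200) and (250,100), each with
  and without offset — the pairing that maximised mean %correct among five
  candidate four-analysis suites on a development replicate;
- the unit-test suite uses a miniature genome (5 % scale) exercising every
  code path in seconds.

With the printed census and filter parameters the simulator retains roughly
3700–3900 SNPs on chr1 and 730–820 on chr2 after the MAF ≥ 0.10 filter
(the exact count varies by seed); accuracy metrics are per-allele
percentages and are insensitive to this density within wide limits.
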