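"""Forward-in-time simulation of a three-way crossbreeding program.

The simulator produces the study conditions used throughout this package:

1. a historic population (long random-mating burn-in, a bottleneck, and an
   expansion) that shapes the allele-frequency spectrum and linkage
   disequilibrium;
2. three breeds (A, B, C) founded by sampling the last historic generation and
   diverged by 5, 20 or 50 generations of within-breed random mating
   (the closely-related / distantly-related / unrelated scenarios);
3. a crossbreeding program run for five generations in parallel with the
   purebred populations: BC two-way crossbreds (B x C) and A(BC) three-way
   crossbreds (A sire on a BC dam), with the breed origin of every transmitted
   allele recorded from the simulated meioses.

Genomes are stored as dense haplotype arrays (one ``uint8`` row per gamete
over all loci).  Meiosis draws a Poisson number of crossovers per chromosome
(mean equal to the genetic length in Morgan, no interference) at uniform map
positions, and recurrent mutation flips each transmitted allele with a small
per-locus probability.  Crossbred gametes additionally carry a per-locus breed
origin row propagated through the same crossover masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import SnpMap, default_candidate_map

__all__ = [
    "SimConfig",
    "Population",
    "Cohort",
    "GenotypeMatrix",
    "TruthOrigins",
    "SimulatedDataset",
    "SCENARIOS",
    "meiosis",
    "simulate_historic",
    "found_breeds",
    "run_cross_scheme",
    "select_snps",
    "sample_genotype_panel",
    "simulate_dataset",
]

#: scenario name -> generations of within-breed divergence
SCENARIOS = {"close": 5, "distant": 20, "unrelated": 50}

BREEDS = ("A", "B", "C")


class ExtinctionError(RuntimeError):
    """Raised when a simulated generation has no males or no females."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated populations and crossbreeding program.

    Defaults reproduce the published study conditions; ``divergence_generations``
    in {5, 20, 50} selects the closely-related / distantly-related / unrelated
    scenario.  All counts are animals per generation unless noted.
    """

    n_historic_generations: int = 1000
    historic_size: int = 1000
    bottleneck_generations: int = 50
    bottleneck_size: int = 100
    expansion_generations: int = 8
    expansion_final_males: int = 60
    expansion_final_females: int = 750
    breed_sample_males: int = 20
    breed_sample_females: int = 250
    divergence_generations: int = 20
    cross_generations: int = 5
    bc_males_per_gen: int = 10
    bc_females_per_gen: int = 100
    abc_per_gen: int = 110
    sampling_fraction: float = 0.75
    mutation_rate: float = 2.5e-5
    maf_threshold: float = 0.10
    master_seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_historic_generations,
            self.historic_size,
            self.bottleneck_generations,
            self.bottleneck_size,
            self.expansion_generations,
            self.expansion_final_males,
            self.expansion_final_females,
            self.breed_sample_males,
            self.breed_sample_females,
            self.cross_generations,
            self.bc_males_per_gen,
            self.bc_females_per_gen,
            self.abc_per_gen,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all census counts must be positive")
        if self.divergence_generations < 0:
            raise ValueError("divergence_generations must be >= 0")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0, 1]")
        if not 0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5]")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")


@dataclass
class Population:
    """A single generation: haplotypes (rows ``2i``, ``2i+1`` belong to animal
    ``i``; row ``2i`` is the paternally inherited haplotype) and sexes
    (0 = male, 1 = female)."""

    haps: np.ndarray  # (2N, L) uint8
    sex: np.ndarray  # (N,) uint8

    @property
    def size(self) -> int:
        return int(self.sex.size)

    @property
    def males(self) -> np.ndarray:
        return np.nonzero(self.sex == 0)[0]

    @property
    def females(self) -> np.ndarray:
        return np.nonzero(self.sex == 1)[0]

    def genotypes(self) -> np.ndarray:
        """Allele dosages (N, L) int8: count of the '1' allele."""
        return (self.haps[0::2].astype(np.int8) + self.haps[1::2]).astype(np.int8)


@dataclass
class Cohort(Population):
    """A labelled group of contemporaneous animals.

    ``origins`` (crossbreds only) stores, row-aligned with ``haps``, the breed
    code (index into :data:`BREEDS`) each transmitted allele descends from.
    """

    label: str = ""
    generation: int = 0
    origins: np.ndarray | None = None

    def ids(self) -> list[str]:
        return [f"{self.label}_g{self.generation}_{i}" for i in range(self.size)]


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _global_positions(snp_map: SnpMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenated positions with per-chromosome offsets, plus chromosome
    start coordinates and lengths (all in Morgan on one line)."""
    pos_parts, starts, lengths = [], [], []
    offset = 0.0
    for c in snp_map.chromosomes:
        starts.append(offset)
        lengths.append(c.length_morgan)
        pos_parts.append(c.positions + offset)
        offset += c.length_morgan + 1.0  # gap; never recombined across
    return np.concatenate(pos_parts), np.asarray(starts), np.asarray(lengths)


def crossover_masks(
    n_gametes: int,
    snp_map: SnpMap,
    rng: np.random.Generator,
    use_kernel: bool = True,
) -> np.ndarray:
    """Boolean (n_gametes, L): True where the gamete copies the first parental
    haplotype.  Crossover counts are Poisson with mean = chromosome length in
    Morgan, positions uniform; each chromosome independently starts from either
    parental haplotype with probability 1/2.

    All random draws happen up front, so the compiled and pure-numpy mask
    builders consume the stream identically and give identical masks.
    """
    pos, starts, lengths = _global_positions(snp_map)
    n_chrom = starts.size
    counts = rng.poisson(lam=lengths, size=(n_gametes, n_chrom))
    start_flip = rng.random((n_gametes, n_chrom)) < 0.5
    total = counts.sum(axis=1)
    u = rng.random(int(total.sum()))
    masks = np.empty((n_gametes, pos.size), dtype=bool)
    if use_kernel:
        from ._kernels import crossover_fill

        crossover_fill(pos, starts, lengths, counts, start_flip, u, masks)
        return masks
    off = 0
    for i in range(n_gametes):
        events = []
        for c in range(n_chrom):
            k = counts[i, c]
            if start_flip[i, c]:
                events.append(starts[c : c + 1])
            if k:
                events.append(starts[c] + u[off : off + k] * lengths[c])
                off += k
        if events:
            ev = np.sort(np.concatenate(events))
            masks[i] = (np.searchsorted(ev, pos, side="right") % 2) == 0
        else:
            masks[i] = True
    return masks


def _apply_mutation(
    gametes: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip count of mutated positions; returns flat indices mutated."""
    if rate <= 0:
        return np.empty(0, dtype=np.int64)
    n_mut = rng.binomial(gametes.size, rate)
    if n_mut == 0:
        return np.empty(0, dtype=np.int64)
    idx = np.unique(rng.integers(0, gametes.size, size=n_mut))
    flat = gametes.reshape(-1)
    flat[idx] ^= 1
    return idx


def meiosis(
    haps: np.ndarray,
    parents: np.ndarray,
    snp_map: SnpMap,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
    return_masks: bool = False,
):
    """Produce one gamete per entry of ``parents`` (animal indices into a
    population whose haplotypes are ``haps``).

    With ``return_masks`` the crossover masks and mutated flat indices are
    returned as well, so a caller can verify that every transmitted allele is
    the chosen parental allele XOR its mutation flip, or propagate per-locus
    origin labels through the identical recombination events.
    """
    parents = np.asarray(parents)
    masks = crossover_masks(parents.size, snp_map, rng)
    g = np.where(masks, haps[2 * parents], haps[2 * parents + 1]).astype(np.uint8)
    mut = _apply_mutation(g, mutation_rate, rng)
    if return_masks:
        return g, masks, mut
    return g


def _random_union_generation(
    pop: Population,
    n_males: int,
    n_females: int,
    snp_map: SnpMap,
    rng: np.random.Generator,
    mutation_rate: float,
    generation: int,
) -> Population:
    """Next generation by random union of gametes from the sex-specific pools."""
    males, females = pop.males, pop.females
    if males.size == 0 or females.size == 0:
        raise ExtinctionError(
            f"population extinct at generation {generation}: "
            f"{males.size} males, {females.size} females"
        )
    n = n_males + n_females
    sires = males[rng.integers(0, males.size, size=n)]
    dams = females[rng.integers(0, females.size, size=n)]
    pat = meiosis(pop.haps, sires, snp_map, rng, mutation_rate)
    mat = meiosis(pop.haps, dams, snp_map, rng, mutation_rate)
    haps = np.empty((2 * n, pat.shape[1]), dtype=np.uint8)
    haps[0::2] = pat
    haps[1::2] = mat
    sex = np.ones(n, dtype=np.uint8)
    sex[:n_males] = 0
    return Population(haps, sex)


# ---------------------------------------------------------------------------
# stage 1: historic population
# ---------------------------------------------------------------------------


def simulate_historic(
    cfg: SimConfig,
    snp_map: SnpMap,
    rng: np.random.Generator,
    init_freq: float | np.ndarray = 0.5,
) -> Population:
    """Burn-in, bottleneck and expansion; returns the final historic generation.

    Founder haplotype alleles are i.i.d. Bernoulli(``init_freq``); the long
    burn-in then shapes the frequency spectrum.  Sexes are half/half until the
    expansion generations, which carry the final male/female census.
    """
    L = snp_map.n_snps
    n0 = cfg.historic_size
    haps = (rng.random((2 * n0, L)) < init_freq).astype(np.uint8)
    sex = np.ones(n0, dtype=np.uint8)
    sex[: n0 // 2] = 0
    pop = Population(haps, sex)

    schedule: list[tuple[int, int]] = []
    half = cfg.historic_size // 2
    schedule += [(half, cfg.historic_size - half)] * cfg.n_historic_generations
    halfb = cfg.bottleneck_size // 2
    schedule += [(halfb, cfg.bottleneck_size - halfb)] * cfg.bottleneck_generations
    schedule += [
        (cfg.expansion_final_males, cfg.expansion_final_females)
    ] * cfg.expansion_generations

    for gen, (nm, nf) in enumerate(schedule, start=1):
        pop = _random_union_generation(
            pop, nm, nf, snp_map, rng, cfg.mutation_rate, gen
        )
    return pop


# ---------------------------------------------------------------------------
# SNP selection
# ---------------------------------------------------------------------------


def select_snps(
    historic: Population, snp_map: SnpMap, maf_threshold: float
) -> tuple[SnpMap, np.ndarray]:
    """Keep loci segregating in the last historic generation with minor allele
    frequency >= ``maf_threshold`` (inclusive).  Returns the filtered map and
    the retained global indices."""
    freq = historic.haps.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (maf >= maf_threshold) & (freq > 0) & (freq < 1)
    if not keep.any():
        raise RuntimeError("no SNPs survive the MAF filter")
    return snp_map.subset(keep), np.nonzero(keep)[0]


# ---------------------------------------------------------------------------
# stage 2: breed founding and divergence
# ---------------------------------------------------------------------------


def _litter_generation(
    pop: Population,
    n_males: int,
    snp_map: SnpMap,
    rng: np.random.Generator,
    mutation_rate: float,
    generation: int,
) -> Population:
    """One divergence generation: every female produces one litter of two (one
    male, one female) by a randomly drawn sire; the next generation keeps all
    daughters and ``n_males`` randomly chosen sons."""
    males, females = pop.males, pop.females
    if males.size == 0 or females.size == 0:
        raise ExtinctionError(f"breed extinct at generation {generation}")
    litter_sires = males[rng.integers(0, males.size, size=females.size)]
    # two offspring per litter, same sire and dam
    sires = np.repeat(litter_sires, 2)
    dams = np.repeat(females, 2)
    pat = meiosis(pop.haps, sires, snp_map, rng, mutation_rate)
    mat = meiosis(pop.haps, dams, snp_map, rng, mutation_rate)
    # within each litter: first offspring male, second female
    sex = np.tile(np.array([0, 1], dtype=np.uint8), females.size)
    keep_sons = rng.choice(females.size, size=n_males, replace=False)
    son_rows = 2 * keep_sons  # litter i male is offspring index 2i
    daughter_rows = 2 * np.arange(females.size) + 1
    keep = np.concatenate([son_rows, daughter_rows])
    haps = np.empty((2 * keep.size, pat.shape[1]), dtype=np.uint8)
    haps[0::2] = pat[keep]
    haps[1::2] = mat[keep]
    return Population(haps, sex[keep])


def found_breeds(
    historic: Population,
    cfg: SimConfig,
    snp_map: SnpMap,
    rng: np.random.Generator,
) -> dict[str, Population]:
    """Sample three disjoint breed foundations from the last historic
    generation and run ``divergence_generations`` of within-breed mating."""
    males, females = historic.males, historic.females
    need_m = 3 * cfg.breed_sample_males
    need_f = 3 * cfg.breed_sample_females
    if males.size < need_m or females.size < need_f:
        raise RuntimeError(
            f"historic population too small to found breeds: "
            f"{males.size} males (< {need_m}) or {females.size} females (< {need_f})"
        )
    perm_m = rng.permutation(males)
    perm_f = rng.permutation(females)
    breeds: dict[str, Population] = {}
    for k, name in enumerate(BREEDS):
        take = np.concatenate(
            [
                perm_m[k * cfg.breed_sample_males : (k + 1) * cfg.breed_sample_males],
                perm_f[k * cfg.breed_sample_females : (k + 1) * cfg.breed_sample_females],
            ]
        )
        rows = np.empty(2 * take.size, dtype=np.int64)
        rows[0::2] = 2 * take
        rows[1::2] = 2 * take + 1
        pop = Population(historic.haps[rows].copy(), historic.sex[take].copy())
        for g in range(cfg.divergence_generations):
            pop = _litter_generation(
                pop, cfg.breed_sample_males, snp_map, rng, cfg.mutation_rate, g + 1
            )
        breeds[name] = pop
    return breeds


# ---------------------------------------------------------------------------
# stage 3: crossbreeding program with truth tracking
# ---------------------------------------------------------------------------


@dataclass
class CrossResult:
    """All animals produced during the crossbreeding program."""

    purebred: dict[str, list[Cohort]]  # breed -> cohorts of generations 1..G
    bc: list[Cohort]  # two-way B x C crossbreds, origins tracked
    abc: list[Cohort]  # three-way A(BC) crossbreds, origins tracked


def run_cross_scheme(
    breeds: dict[str, Population],
    cfg: SimConfig,
    snp_map: SnpMap,
    rng: np.random.Generator,
) -> CrossResult:
    """Five (by default) generations of parallel purebred and crossbred matings.

    Per generation: purebred populations continue by random union of gametes
    at constant census; 110 BC animals come from random B x C matings (sire
    breed drawn at random per animal); 110 A(BC) animals come from a random
    A sire on a random BC dam of the current generation.  Breed origin of every
    transmitted allele is recorded through the crossover masks.
    """
    code = {b: i for i, b in enumerate(BREEDS)}
    current = dict(breeds)
    purebred: dict[str, list[Cohort]] = {b: [] for b in BREEDS}
    bc_cohorts: list[Cohort] = []
    abc_cohorts: list[Cohort] = []
    n_bc = cfg.bc_males_per_gen + cfg.bc_females_per_gen

    for gen in range(1, cfg.cross_generations + 1):
        parents = current
        # purebred continuation
        nxt: dict[str, Population] = {}
        for b in BREEDS:
            pop = _random_union_generation(
                parents[b],
                cfg.breed_sample_males,
                cfg.breed_sample_females,
                snp_map,
                rng,
                cfg.mutation_rate,
                gen,
            )
            nxt[b] = pop
            purebred[b].append(
                Cohort(pop.haps, pop.sex, label=b, generation=gen)
            )

        # BC crossbreds: random B x C matings, sire breed random per animal
        sire_is_b = rng.random(n_bc) < 0.5
        bc_haps = np.empty((2 * n_bc, snp_map.n_snps), dtype=np.uint8)
        bc_orig = np.empty_like(bc_haps)
        popB, popC = parents["B"], parents["C"]
        sires_b = popB.males[rng.integers(0, popB.males.size, size=n_bc)]
        sires_c = popC.males[rng.integers(0, popC.males.size, size=n_bc)]
        dams_b = popB.females[rng.integers(0, popB.females.size, size=n_bc)]
        dams_c = popC.females[rng.integers(0, popC.females.size, size=n_bc)]
        pat_b = meiosis(popB.haps, sires_b, snp_map, rng, cfg.mutation_rate)
        pat_c = meiosis(popC.haps, sires_c, snp_map, rng, cfg.mutation_rate)
        mat_b = meiosis(popB.haps, dams_b, snp_map, rng, cfg.mutation_rate)
        mat_c = meiosis(popC.haps, dams_c, snp_map, rng, cfg.mutation_rate)
        sel = sire_is_b[:, None]
        bc_haps[0::2] = np.where(sel, pat_b, pat_c)
        bc_haps[1::2] = np.where(sel, mat_c, mat_b)
        bc_orig[0::2] = np.where(sel, code["B"], code["C"])
        bc_orig[1::2] = np.where(sel, code["C"], code["B"])
        bc_sex = np.ones(n_bc, dtype=np.uint8)
        bc_sex[: cfg.bc_males_per_gen] = 0
        bc = Cohort(bc_haps, bc_sex, label="BC", generation=gen, origins=bc_orig)
        bc_cohorts.append(bc)

        # A(BC): A sire x BC dam of this generation
        n_abc = cfg.abc_per_gen
        popA = parents["A"]
        sires_a = popA.males[rng.integers(0, popA.males.size, size=n_abc)]
        bc_dams = bc.females[rng.integers(0, bc.females.size, size=n_abc)]
        pat_a = meiosis(popA.haps, sires_a, snp_map, rng, cfg.mutation_rate)
        mat, masks, _ = meiosis(
            bc.haps, bc_dams, snp_map, rng, cfg.mutation_rate, return_masks=True
        )
        mat_orig = np.where(
            masks, bc.origins[2 * bc_dams], bc.origins[2 * bc_dams + 1]
        ).astype(np.uint8)
        abc_haps = np.empty((2 * n_abc, snp_map.n_snps), dtype=np.uint8)
        abc_haps[0::2] = pat_a
        abc_haps[1::2] = mat
        abc_orig = np.empty_like(abc_haps)
        abc_orig[0::2] = code["A"]
        abc_orig[1::2] = mat_orig
        abc_sex = (np.arange(n_abc) % 2).astype(np.uint8)
        abc_cohorts.append(
            Cohort(abc_haps, abc_sex, label="ABC", generation=gen, origins=abc_orig)
        )

        current = nxt

    return CrossResult(purebred=purebred, bc=bc_cohorts, abc=abc_cohorts)


# ---------------------------------------------------------------------------
# panel sampling and the analysis-facing dataset
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Animals x SNPs allele dosages (0/1/2, -1 missing) with cohort labels."""

    genotypes: np.ndarray  # (n, L) int8
    animal_ids: list[str]
    cohorts: np.ndarray  # (n,) of str labels, e.g. 'A', 'B', 'C', 'BC', 'ABC'
    snp_map: SnpMap

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def restrict_chromosomes(self, names: list[str]) -> "GenotypeMatrix":
        sub_map, idx = self.snp_map.restrict_chromosomes(names)
        return GenotypeMatrix(
            self.genotypes[:, idx], list(self.animal_ids), self.cohorts.copy(), sub_map
        )


@dataclass
class TruthOrigins:
    """True breed origin and true allele value per crossbred allele slot.

    Slot 0 is the paternally inherited allele, slot 1 the maternal one.
    """

    animal_ids: list[str]
    origins: np.ndarray  # (n, L, 2) int8, breed codes into `breeds`
    hap_values: np.ndarray  # (n, L, 2) uint8
    breeds: tuple[str, ...] = BREEDS

    def restrict(self, idx: np.ndarray, snp_idx: np.ndarray | None = None) -> "TruthOrigins":
        o, v = self.origins[idx], self.hap_values[idx]
        if snp_idx is not None:
            o, v = o[:, snp_idx], v[:, snp_idx]
        return TruthOrigins([self.animal_ids[i] for i in idx], o, v, self.breeds)


@dataclass
class SimulatedDataset:
    """One replicate of one scenario, ready for analysis and scoring."""

    config: SimConfig
    snp_map: SnpMap
    genotypes: GenotypeMatrix  # the sampled 75 % panel
    composition: pd.DataFrame  # animal_id, cross_type, breeds, paternal_breed
    truth: TruthOrigins  # panel crossbreds only, aligned with panel order
    purebred_all: GenotypeMatrix  # all purebreds of the program (for F_ST)
    panel_hap_values: np.ndarray  # (n_panel, L, 2) true phases of panel animals

    @property
    def crossbred_index(self) -> np.ndarray:
        return np.nonzero(np.isin(self.genotypes.cohorts, ["BC", "ABC"]))[0]

    @property
    def purebred_index(self) -> np.ndarray:
        return np.nonzero(np.isin(self.genotypes.cohorts, list(BREEDS)))[0]


def _cohort_table(cohorts: list[Cohort]):
    """Stack cohorts: ids, genotypes, cohort label, hap values, origins."""
    ids, labels, geno, vals, origs = [], [], [], [], []
    for c in cohorts:
        ids.extend(c.ids())
        labels.extend([c.label] * c.size)
        geno.append(c.genotypes())
        v = np.stack([c.haps[0::2], c.haps[1::2]], axis=2)
        vals.append(v)
        if c.origins is not None:
            origs.append(np.stack([c.origins[0::2], c.origins[1::2]], axis=2))
        else:
            origs.append(None)
    return ids, labels, np.concatenate(geno), np.concatenate(vals), origs


def sample_genotype_panel(
    cross: CrossResult,
    cfg: SimConfig,
    snp_map: SnpMap,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthOrigins, GenotypeMatrix, np.ndarray]:
    """Randomly select ``sampling_fraction`` of each cohort (per cohort and
    generation, without replacement) and export the analysis-facing dataset:
    genotypes, cohort labels and breed composition only — no parent identities.

    Also returns the complete purebred genotype table of the program (used for
    the genetic-differentiation statistic) and the panel's true phases.
    """
    frac = cfg.sampling_fraction
    all_cohorts: list[Cohort] = []
    for b in BREEDS:
        all_cohorts.extend(cross.purebred[b])
    all_cohorts.extend(cross.bc)
    all_cohorts.extend(cross.abc)

    sel_ids: list[str] = []
    sel_labels: list[str] = []
    sel_geno: list[np.ndarray] = []
    sel_vals: list[np.ndarray] = []
    truth_ids: list[str] = []
    truth_orig: list[np.ndarray] = []
    truth_vals: list[np.ndarray] = []

    for c in all_cohorts:
        n_take = int(round(frac * c.size))
        take = np.sort(rng.choice(c.size, size=n_take, replace=False))
        ids = c.ids()
        sel_ids.extend(ids[i] for i in take)
        sel_labels.extend([c.label] * n_take)
        sel_geno.append(c.genotypes()[take])
        v = np.stack([c.haps[0::2], c.haps[1::2]], axis=2)
        sel_vals.append(v[take])
        if c.origins is not None:
            truth_ids.extend(ids[i] for i in take)
            o = np.stack([c.origins[0::2], c.origins[1::2]], axis=2)
            truth_orig.append(o[take].astype(np.int8))
            truth_vals.append(v[take])

    gm = GenotypeMatrix(
        np.concatenate(sel_geno).astype(np.int8),
        sel_ids,
        np.asarray(sel_labels, dtype=object),
        snp_map,
    )
    panel_vals = np.concatenate(sel_vals)

    rows = []
    for aid, label in zip(sel_ids, sel_labels):
        if label == "BC":
            rows.append((aid, "two_way", "B,C", ""))
        elif label == "ABC":
            rows.append((aid, "three_way", "B,C", "A"))
    comp = pd.DataFrame(rows, columns=["animal_id", "cross_type", "breeds", "paternal_breed"])

    truth = TruthOrigins(
        truth_ids,
        np.concatenate(truth_orig) if truth_orig else np.empty((0, snp_map.n_snps, 2), np.int8),
        np.concatenate(truth_vals) if truth_vals else np.empty((0, snp_map.n_snps, 2), np.uint8),
    )

    pb_ids, pb_labels, pb_geno, _, _ = _cohort_table(
        [c for b in BREEDS for c in cross.purebred[b]]
    )
    purebred_all = GenotypeMatrix(
        pb_geno.astype(np.int8), pb_ids, np.asarray(pb_labels, dtype=object), snp_map
    )
    return gm, comp, truth, purebred_all, panel_vals


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------


def simulate_dataset(
    cfg: SimConfig,
    candidate_map: SnpMap | None = None,
    historic: Population | None = None,
    filtered: tuple[SnpMap, np.ndarray] | None = None,
) -> SimulatedDataset:
    """Run the full simulation for one replicate of one scenario.

    Independent child random streams are derived from ``cfg.master_seed`` for
    the genome, the historic stage, breed divergence, the crossbreeding
    program and panel sampling, so each stage is individually reproducible.
    A precomputed ``historic`` population (with its ``filtered`` map) may be
    passed to share the expensive burn-in across scenarios.
    """
    ss = np.random.SeedSequence(cfg.master_seed)
    s_map, s_hist, s_div, s_cross, s_panel = [
        np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(5)
    ]
    if candidate_map is None:
        candidate_map = default_candidate_map(s_map)
    if historic is None:
        historic = simulate_historic(cfg, candidate_map, s_hist)
        snp_map, keep = select_snps(historic, candidate_map, cfg.maf_threshold)
        historic = Population(historic.haps[:, keep], historic.sex)
    else:
        if filtered is None:
            snp_map, keep = select_snps(historic, candidate_map, cfg.maf_threshold)
            historic = Population(historic.haps[:, keep], historic.sex)
        else:
            snp_map, _ = filtered
    breeds = found_breeds(historic, cfg, snp_map, s_div)
    cross = run_cross_scheme(breeds, cfg, snp_map, s_cross)
    gm, comp, truth, purebred_all, panel_vals = sample_genotype_panel(
        cross, cfg, snp_map, s_panel
    )
    return SimulatedDataset(
        config=cfg,
        snp_map=snp_map,
        genotypes=gm,
        composition=comp,
        truth=truth,
        purebred_all=purebred_all,
        panel_hap_values=panel_vals,
    )
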