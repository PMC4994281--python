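"""Readers and writers for the package's file formats.

Genotype panels travel as PLINK PED/MAP (alleles coded 1/2), as a TSV dosage
matrix, or as VCF (biallelic records with placeholder alleles A/B standing for
the 1/2 codes).  Genetic maps use the PLINK MAP layout plus a sidecar with
per-chromosome genetic lengths in Morgan.  Compositions, truth origins,
assigned origins and haplotype libraries are TSVs with a header row.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .assignment import BreedComposition, OriginMatrix, compositions_from_frame
from .breedlib import BreedHaplotypeLibrary
from .genome import ChromosomeMap, SnpMap
from .simdata import GenotypeMatrix, TruthOrigins

__all__ = [
    "write_snp_map",
    "read_snp_map",
    "write_ped_map",
    "read_ped_map",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_vcf",
    "read_vcf",
    "write_phased_vcf",
    "write_composition",
    "read_composition",
    "write_truth_origins",
    "read_truth_origins",
    "write_origins",
    "write_library",
    "read_genotypes",
]

MISSING = -1


def _snp_ids(snp_map: SnpMap) -> list[str]:
    ids = []
    for c in snp_map.chromosomes:
        ids.extend(f"{c.name}_{i}" for i in range(c.n_snps))
    return ids


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------


def write_snp_map(snp_map: SnpMap, prefix: str) -> None:
    """Write ``<prefix>.map`` (PLINK: chrom, id, cM, bp) and
    ``<prefix>.lengths.tsv`` (chrom, genetic length in Morgan)."""
    with open(prefix + ".map", "w") as fh:
        for c in snp_map.chromosomes:
            bp = _bp_positions(c)
            for i, (pos, b) in enumerate(zip(c.positions, bp)):
                fh.write(f"{c.name}\t{c.name}_{i}\t{100.0 * pos:.6f}\t{b}\n")
    with open(prefix + ".lengths.tsv", "w") as fh:
        fh.write("chrom\tlength_morgan\n")
        for c in snp_map.chromosomes:
            fh.write(f"{c.name}\t{c.length_morgan:.6f}\n")


def _bp_positions(c: ChromosomeMap) -> np.ndarray:
    """Strictly increasing integer pseudo-positions (1 Mb per Morgan)."""
    bp = np.round(c.positions * 1e6).astype(np.int64) + 1
    return np.maximum.accumulate(bp + np.arange(bp.size))


def read_snp_map(prefix: str) -> SnpMap:
    mp = pd.read_csv(
        prefix + ".map", sep="\t", header=None, names=["chrom", "snp", "cm", "bp"],
        dtype={"chrom": str},
    )
    lengths = pd.read_csv(prefix + ".lengths.tsv", sep="\t", dtype={"chrom": str})
    lens = dict(zip(lengths["chrom"], lengths["length_morgan"]))
    chroms = []
    for name, grp in mp.groupby("chrom", sort=False):
        chroms.append(ChromosomeMap(name, float(lens[name]), grp["cm"].to_numpy() / 100.0))
    return SnpMap(chroms)


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

_PED_CODES = {0: "1 1", 1: "1 2", 2: "2 2", MISSING: "0 0"}


def write_ped_map(gm: GenotypeMatrix, prefix: str) -> None:
    """PLINK text fileset: ``.ped`` (family = cohort label), ``.map`` and the
    genetic-length sidecar.  Dosages count copies of the '2' allele."""
    write_snp_map(gm.snp_map, prefix)
    with open(prefix + ".ped", "w") as fh:
        for i, aid in enumerate(gm.animal_ids):
            row = gm.genotypes[i]
            alleles = " ".join(_PED_CODES[int(v)] for v in row)
            fh.write(f"{gm.cohorts[i]} {aid} 0 0 0 -9 {alleles}\n")


def read_ped_map(prefix: str) -> GenotypeMatrix:
    snp_map = read_snp_map(prefix)
    ids, cohorts, rows = [], [], []
    decode = {("1", "1"): 0, ("1", "2"): 1, ("2", "1"): 1, ("2", "2"): 2, ("0", "0"): MISSING}
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * snp_map.n_snps:
                raise ValueError(f"{prefix}.ped line {ln}: malformed record")
            cohorts.append(parts[0])
            ids.append(parts[1])
            try:
                rows.append(
                    [decode[(parts[6 + 2 * k], parts[7 + 2 * k])] for k in range(snp_map.n_snps)]
                )
            except KeyError as e:
                raise ValueError(f"{prefix}.ped line {ln}: bad allele code {e}") from None
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate animal ids in PED file")
    return GenotypeMatrix(
        np.asarray(rows, dtype=np.int8), ids, np.asarray(cohorts, dtype=object), snp_map
    )


# ---------------------------------------------------------------------------
# TSV matrix
# ---------------------------------------------------------------------------


def write_genotype_tsv(gm: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(gm.genotypes, columns=_snp_ids(gm.snp_map))
    df.insert(0, "cohort", gm.cohorts)
    df.insert(0, "animal_id", gm.animal_ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str, snp_map: SnpMap) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    geno = df.drop(columns=["animal_id", "cohort"]).to_numpy(dtype=np.int8)
    if geno.shape[1] != snp_map.n_snps:
        raise ValueError("TSV column count does not match the SNP map")
    bad = ~np.isin(geno, [0, 1, 2, MISSING])
    if bad.any():
        raise ValueError("TSV contains dosages outside {0,1,2,-1}")
    return GenotypeMatrix(
        geno,
        df["animal_id"].astype(str).tolist(),
        df["cohort"].astype(str).to_numpy(dtype=object),
        snp_map,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _vcf_header(gm: GenotypeMatrix, extra_format: str = "") -> str:
    lines = ["##fileformat=VCFv4.2", "##source=boa"]
    for c in gm.snp_map.chromosomes:
        bp = _bp_positions(c)
        ln = int(bp[-1]) + 1 if c.n_snps else 1
        lines.append(f"##contig=<ID={c.name},length={ln}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if extra_format:
        lines.append(extra_format)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.animal_ids)
    )
    return "\n".join(lines) + "\n"


_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Unphased VCF with placeholder alleles (REF=A is the '1' allele,
    ALT=B the '2' allele)."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(gm))
        k = 0
        for c in gm.snp_map.chromosomes:
            bp = _bp_positions(c)
            for i in range(c.n_snps):
                gts = "\t".join(_GT_CODES[int(v)] for v in gm.genotypes[:, k])
                fh.write(
                    f"{c.name}\t{bp[i]}\t{c.name}_{i}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n"
                )
                k += 1


def read_vcf(path: str) -> tuple[GenotypeMatrix, SnpMap]:
    """Read a biallelic VCF through pysam; multi-allelic records are rejected
    by variant id.  ``./.`` becomes the missing code.  Genetic positions are
    reconstructed from bp at 1 Mb per Morgan."""
    import pysam

    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        by_chrom: dict[str, list[float]] = {}
        rows = []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"multi-allelic variant {rec.id or rec.pos} rejected")
            by_chrom.setdefault(rec.chrom, []).append((rec.pos - 1) / 1e6)
            col = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    col.append(MISSING)
                else:
                    col.append(int(sum(gt)))
            rows.append(col)
    chroms = [
        ChromosomeMap(
            name,
            (max(pos) if pos else 0.0) + 1e-6,
            np.maximum.accumulate(np.asarray(pos) + np.arange(len(pos)) * 1e-9),
        )
        for name, pos in by_chrom.items()
    ]
    snp_map = SnpMap(chroms)
    geno = np.asarray(rows, dtype=np.int8).T
    return (
        GenotypeMatrix(geno, samples, np.asarray(["?"] * len(samples), dtype=object), snp_map),
        snp_map,
    )


def write_phased_vcf(
    gm: GenotypeMatrix, haps: dict[str, np.ndarray], path: str
) -> None:
    """Phased VCF for one analysis: ``h1|h2`` with ``.`` for unresolved."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(gm))
        for c in gm.snp_map.chromosomes:
            bp = _bp_positions(c)
            h = haps[c.name]
            for i in range(c.n_snps):
                cols = []
                for a in range(h.shape[0]):
                    x, y = h[a, 0, i], h[a, 1, i]
                    cols.append(
                        f"{'.' if x < 0 else int(x)}|{'.' if y < 0 else int(y)}"
                    )
                fh.write(
                    f"{c.name}\t{bp[i]}\t{c.name}_{i}\tA\tB\t.\tPASS\t.\tGT\t"
                    + "\t".join(cols)
                    + "\n"
                )


# ---------------------------------------------------------------------------
# composition / truth / origins / library tables
# ---------------------------------------------------------------------------


def write_composition(comp: pd.DataFrame, path: str) -> None:
    comp.to_csv(path, sep="\t", index=False)


def read_composition(
    path: str, gm: GenotypeMatrix | None = None, crossbred_labels: tuple[str, ...] = ("BC", "ABC")
) -> dict[str, BreedComposition]:
    """Read and validate a composition table.

    When a genotype panel is supplied, composition rows must refer to known
    animals and every crossbred animal of the panel must have a row; unknown
    breed labels (outside the panel's purebred cohort labels plus the
    composition's own breeds) are fatal via BreedComposition validation.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    comps = compositions_from_frame(df)
    if gm is not None:
        known = set(gm.animal_ids)
        unknown = [a for a in comps if a not in known]
        if unknown:
            raise ValueError(f"composition refers to unknown animals: {unknown[:5]}")
        need = [
            a
            for a, c in zip(gm.animal_ids, gm.cohorts)
            if c in crossbred_labels and a not in comps
        ]
        if need:
            raise ValueError(f"crossbred animals without composition: {need[:5]}")
    return comps


def write_truth_origins(truth: TruthOrigins, snp_map: SnpMap, path: str) -> None:
    slices = snp_map.slices()
    with open(path, "w") as fh:
        fh.write("animal_id\tchrom\tsnp_index\tslot\tbreed\tallele\n")
        for i, aid in enumerate(truth.animal_ids):
            for chrom, sl in slices.items():
                o = truth.origins[i, sl]
                v = truth.hap_values[i, sl]
                for k in range(o.shape[0]):
                    for s, slot in enumerate(("pat", "mat")):
                        fh.write(
                            f"{aid}\t{chrom}\t{k}\t{slot}\t"
                            f"{truth.breeds[o[k, s]]}\t{v[k, s]}\n"
                        )


def read_truth_origins(path: str, snp_map: SnpMap, breeds=("A", "B", "C")) -> TruthOrigins:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    ids = list(dict.fromkeys(df["animal_id"]))
    idx = {a: i for i, a in enumerate(ids)}
    code = {b: k for k, b in enumerate(breeds)}
    slices = snp_map.slices()
    L = snp_map.n_snps
    origins = np.full((len(ids), L, 2), -1, dtype=np.int8)
    values = np.zeros((len(ids), L, 2), dtype=np.uint8)
    srow = df["slot"].map({"pat": 0, "mat": 1}).to_numpy()
    arow = df["animal_id"].map(idx).to_numpy()
    krow = df["snp_index"].to_numpy() + np.asarray(
        [slices[c].start for c in df["chrom"]]
    )
    origins[arow, krow, srow] = df["breed"].map(code).to_numpy()
    values[arow, krow, srow] = df["allele"].to_numpy()
    return TruthOrigins(ids, origins, values, tuple(breeds))


def write_origins(om: OriginMatrix, path: str) -> None:
    prov_names = ["none", "core_vote", "composition", "rule1", "rule2", "rule3"]
    slices = om.snp_map.slices()
    with open(path, "w") as fh:
        fh.write("animal_id\tchrom\tsnp_index\tslot\torigin\tallele\tprovenance\n")
        for i, aid in enumerate(om.animal_ids):
            for chrom, sl in slices.items():
                o = om.origins[i, sl]
                v = om.values[i, sl]
                p = om.provenance[i, sl]
                for k in range(o.shape[0]):
                    for s in (0, 1):
                        origin = "UNKNOWN" if o[k, s] < 0 else om.breeds[o[k, s]]
                        fh.write(
                            f"{aid}\t{chrom}\t{k}\t{s}\t{origin}\t{v[k, s]}\t"
                            f"{prov_names[p[k, s]]}\n"
                        )


def write_library(lib: BreedHaplotypeLibrary, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "analysis_id\tchrom\tcore_start\tcore_end\thaplotype\t"
            + "\t".join(f"count_{b}" for b in lib.breeds)
            + "\tassigned_origin\n"
        )
        for w in lib.windows:
            for h in range(w.haps.shape[0]):
                hap = "".join(str(int(x)) for x in w.haps[h])
                counts = "\t".join(str(int(c)) for c in w.counts[h])
                origin = "unassigned" if w.origin[h] < 0 else lib.breeds[w.origin[h]]
                fh.write(
                    f"{w.analysis_id}\t{w.chrom}\t{w.window.start}\t{w.window.end}\t"
                    f"{hap}\t{counts}\t{origin}\n"
                )


def read_genotypes(path: str, fmt: str, snp_map: SnpMap | None = None):
    """Dispatch reader: ``ped_map`` (path = prefix), ``tsv_matrix`` (needs a
    map) or ``vcf``.  Returns (GenotypeMatrix, SnpMap)."""
    if fmt == "ped_map":
        gm = read_ped_map(path)
        return gm, gm.snp_map
    if fmt == "tsv_matrix":
        if snp_map is None:
            raise ValueError("tsv_matrix requires a SNP map")
        gm = read_genotype_tsv(path, snp_map)
        return gm, snp_map
    if fmt == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")
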