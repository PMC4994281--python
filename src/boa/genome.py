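"""Genetic maps for the simulated and analysed genomes.

A :class:`SnpMap` holds, per chromosome, the genetic length in Morgan and the
ordered genetic positions of the SNPs.  SNPs are indexed 0-based within each
chromosome; most array-valued containers in this package concatenate
chromosomes in map order and use the global index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChromosomeMap", "SnpMap", "default_candidate_map", "scaled_candidate_map"]


@dataclass
class ChromosomeMap:
    """One chromosome: name, genetic length (Morgan) and sorted SNP positions."""

    name: str
    length_morgan: float
    positions: np.ndarray  # Morgan, strictly increasing, within [0, length]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 1:
            raise ValueError("positions must be 1-D")
        if self.positions.size and (
            self.positions[0] < 0 or self.positions[-1] > self.length_morgan
        ):
            raise ValueError(f"{self.name}: positions outside [0, {self.length_morgan}]")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"{self.name}: positions must be strictly increasing")

    @property
    def n_snps(self) -> int:
        return int(self.positions.size)


@dataclass
class SnpMap:
    """An ordered collection of chromosome maps."""

    chromosomes: list[ChromosomeMap] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return sum(c.n_snps for c in self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom(self, name: str) -> ChromosomeMap:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def slices(self) -> dict[str, slice]:
        """Global index slice of each chromosome in concatenation order."""
        out: dict[str, slice] = {}
        start = 0
        for c in self.chromosomes:
            out[c.name] = slice(start, start + c.n_snps)
            start += c.n_snps
        return out

    def subset(self, keep: np.ndarray) -> "SnpMap":
        """New map restricted to the global SNP indices/boolean mask ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype != bool:
            mask = np.zeros(self.n_snps, dtype=bool)
            mask[keep] = True
        else:
            mask = keep
        chroms = []
        for name, sl in self.slices().items():
            c = self.chrom(name)
            chroms.append(
                ChromosomeMap(c.name, c.length_morgan, c.positions[mask[sl]])
            )
        return SnpMap(chroms)

    def restrict_chromosomes(self, names: list[str]) -> tuple["SnpMap", np.ndarray]:
        """Map with only ``names``, plus the global indices retained."""
        sl = self.slices()
        idx = np.concatenate(
            [np.arange(s.start, s.stop) for n, s in sl.items() if n in names]
        )
        return SnpMap([self.chrom(n) for n in self.names if n in names]), idx


def default_candidate_map(rng: np.random.Generator) -> SnpMap:
    """Candidate SNP map of the simulation study's default genome.

    Two chromosomes sized like pig chromosomes SSC1 and SSC18: 3.20 Morgan
    carrying 6700 candidate loci and 0.61 Morgan carrying 1353, positions
    uniform on the genetic map (~60k-chip density after the MAF filter).
    """
    return scaled_candidate_map(rng, scale=1.0)


def scaled_candidate_map(rng: np.random.Generator, scale: float = 1.0) -> SnpMap:
    """Default genome with lengths and locus counts multiplied by ``scale``."""
    chroms = []
    for name, length, n in [("chr1", 3.20, 6700), ("chr2", 0.61, 1353)]:
        length = length * scale
        n = max(2, int(round(n * scale)))
        pos = np.sort(rng.uniform(0.0, length, size=n))
        # enforce strict monotonicity in the (measure-zero) event of ties
        pos = np.maximum.accumulate(pos + np.arange(n) * 1e-12)
        chroms.append(ChromosomeMap(name, length, pos))
    return SnpMap(chroms)
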