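"""Per-analysis, per-core libraries of purebred haplotypes with breed origin.

Every fully phased core haplotype copy observed in a purebred animal is
counted towards its breed.  A haplotype is then assigned to the breed holding
the majority of its copies if the fraction of copies seen in the *other*
breeds is below the relaxation factor ``f_r`` (strict exclusivity when
``f_r = 0``); otherwise it stays unassigned.  Libraries from all analyses are
retained jointly and are the lookup tables for crossbred allele voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phasing import CoreWindow, PhasedAnalysis

__all__ = [
    "LibraryConfig",
    "WindowLibrary",
    "BreedHaplotypeLibrary",
    "collect_haplotypes",
    "assign_haplotype_origins",
]


@dataclass(frozen=True)
class LibraryConfig:
    """Relaxation factor (percent) and the purebred cohort labels."""

    f_r: float = 0.0
    purebred_labels: tuple[str, ...] = ("A", "B", "C")

    def __post_init__(self) -> None:
        if not 0 <= self.f_r < 50:
            raise ValueError("f_r must lie in [0, 50) percent")


@dataclass
class WindowLibrary:
    """Distinct core haplotypes of one (analysis, chromosome, core) with
    per-breed copy counts and an assigned origin (-1 = unassigned)."""

    analysis_id: str
    chrom: str
    window: CoreWindow
    haps: np.ndarray  # (H, core) uint8
    counts: np.ndarray  # (H, n_breeds) int64
    origin: np.ndarray  # (H,) int8

    def lookup(self) -> dict[bytes, int]:
        """bytes(core haplotype) -> assigned breed code, assigned rows only."""
        return {
            self.haps[h].tobytes(): int(self.origin[h])
            for h in range(self.haps.shape[0])
            if self.origin[h] >= 0
        }


@dataclass
class BreedHaplotypeLibrary:
    """All window libraries of a phasing suite, keyed for exact lookup."""

    breeds: tuple[str, ...]
    f_r: float = 0.0
    windows: list[WindowLibrary] = field(default_factory=list)

    def key(self, analysis_id: str, chrom: str, window: CoreWindow) -> tuple:
        return (analysis_id, chrom, window.start, window.end)

    def __post_init__(self) -> None:
        self._index = {self.key(w.analysis_id, w.chrom, w.window): w for w in self.windows}

    def add(self, w: WindowLibrary) -> None:
        self.windows.append(w)
        self._index[self.key(w.analysis_id, w.chrom, w.window)] = w

    def get(self, analysis_id: str, chrom: str, window: CoreWindow) -> WindowLibrary:
        return self._index[(analysis_id, chrom, window.start, window.end)]

    def assigned_keys(self) -> set[tuple]:
        """(analysis, chrom, start, end, haplotype bytes) of every assigned
        haplotype — the monotonicity witness across relaxation factors."""
        out = set()
        for w in self.windows:
            for h in range(w.haps.shape[0]):
                if w.origin[h] >= 0:
                    out.add(
                        (w.analysis_id, w.chrom, w.window.start, w.window.end,
                         w.haps[h].tobytes())
                    )
        return out


def collect_haplotypes(
    phased: dict[str, PhasedAnalysis],
    cohorts: np.ndarray,
    breeds: tuple[str, ...] = ("A", "B", "C"),
) -> BreedHaplotypeLibrary:
    """Count every fully phased core haplotype copy of every purebred animal.

    Each animal contributes its two core haplotypes per window (copies are
    counted, not deduplicated per animal); haplotypes with any unresolved
    entry are skipped.  Returns a library with counts only (origins all
    unassigned until :func:`assign_haplotype_origins`).
    """
    lib = BreedHaplotypeLibrary(breeds=tuple(breeds))
    breed_of = {b: k for k, b in enumerate(breeds)}
    pure_rows = np.asarray(
        [breed_of.get(c, -1) for c in cohorts], dtype=np.int64
    )
    pure_idx = np.nonzero(pure_rows >= 0)[0]
    pure_breed = pure_rows[pure_idx]
    for aid, analysis in phased.items():
        for chrom, windows in analysis.cores.items():
            h = analysis.haps[chrom]
            for win in windows:
                hw = h[pure_idx, :, win.start : win.end]  # (np, 2, c)
                flat = hw.reshape(-1, hw.shape[2])
                labels = np.repeat(pure_breed, 2)
                full = ~(flat < 0).any(axis=1)
                flat = flat[full].astype(np.uint8)
                labels = labels[full]
                if flat.shape[0]:
                    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
                    counts = np.zeros((uniq.shape[0], len(breeds)), dtype=np.int64)
                    np.add.at(counts, (inverse, labels), 1)
                else:
                    uniq = np.empty((0, hw.shape[2]), dtype=np.uint8)
                    counts = np.zeros((0, len(breeds)), dtype=np.int64)
                lib.add(
                    WindowLibrary(
                        analysis_id=aid,
                        chrom=chrom,
                        window=win,
                        haps=uniq,
                        counts=counts,
                        origin=np.full(uniq.shape[0], -1, dtype=np.int8),
                    )
                )
    return lib


def assign_haplotype_origins(
    lib: BreedHaplotypeLibrary, cfg: LibraryConfig
) -> BreedHaplotypeLibrary:
    """Assign each library haplotype a breed origin under relaxation ``f_r``.

    With copy counts ``c_b`` and total ``C``, the haplotype goes to the unique
    majority breed ``b*`` iff the other-breed fraction ``(C - c_b*)/C`` is
    strictly below ``f_r/100`` (for ``f_r > 0``), or iff no copy at all was
    seen in another breed (``f_r = 0``).  Ties for the majority leave the
    haplotype unassigned.  Returns a new library sharing count arrays.
    """
    out = BreedHaplotypeLibrary(breeds=lib.breeds, f_r=cfg.f_r)
    for w in lib.windows:
        counts = w.counts
        total = counts.sum(axis=1)
        top = counts.max(axis=1, initial=0)
        unique_max = (counts == top[:, None]).sum(axis=1) == 1
        other = total - top
        with np.errstate(invalid="ignore", divide="ignore"):
            if cfg.f_r == 0:
                ok = other == 0
            else:
                ok = other * 100.0 < cfg.f_r * total
        ok &= unique_max & (total > 0)
        origin = np.where(ok, np.argmax(counts, axis=1), -1).astype(np.int8)
        out.add(
            WindowLibrary(w.analysis_id, w.chrom, w.window, w.haps, counts, origin)
        )
    return out
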