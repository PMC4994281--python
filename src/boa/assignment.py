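"""Breed-origin assignment for the alleles of crossbred animals.

Every phasing analysis contributes at most one *vote* per allele: a crossbred
animal's fully phased core haplotype is looked up in the breed haplotype
library and, when that haplotype carries an assigned origin, every allele on
it receives one vote for that breed.  Votes inconsistent with the zygosity of
the input genotype are discarded, the paternal allele of a three-way crossbred
is resolved first, and each allele then takes the plurality breed among the
composition-admissible votes; plurality ties and conflicting evidence resolve
to UNKNOWN rather than to a guess.

Three optional post-processing rules deduce further assignments: (1) the
paternal allele when the maternal one is known, (2) the second allele of a
two-way crossbred when the first is known, and (3) alleles bracketed by
same-breed assignments that co-occur in a single assigned library haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breedlib import BreedHaplotypeLibrary
from .genome import SnpMap
from .phasing import PhasedAnalysis
from .simdata import GenotypeMatrix

__all__ = [
    "BreedComposition",
    "VoteTable",
    "OriginMatrix",
    "compositions_from_frame",
    "vote_allele_origins",
    "resolve_origins",
    "apply_post_rules",
    "assign_breed_origin",
    "UNKNOWN",
]

UNKNOWN = np.int8(-1)

#: provenance codes
PROV_NONE, PROV_VOTE, PROV_COMPOSITION, PROV_RULE1, PROV_RULE2, PROV_RULE3 = range(6)


@dataclass(frozen=True)
class BreedComposition:
    """Breed composition of one crossbred animal.

    ``two_way`` animals carry exactly two parental breeds (slot order carries
    no paternal meaning when the paternal breed is unrecorded); ``three_way``
    animals have a paternal breed plus two maternal breeds.
    """

    animal_id: str
    cross_type: str
    breeds: tuple[str, ...]
    paternal_breed: str | None = None

    def __post_init__(self) -> None:
        if self.cross_type not in ("two_way", "three_way"):
            raise ValueError(f"unknown cross type {self.cross_type!r}")
        if self.cross_type == "two_way" and len(self.breeds) != 2:
            raise ValueError(f"{self.animal_id}: two_way requires exactly 2 breeds")
        if self.cross_type == "three_way":
            if len(self.breeds) != 2:
                raise ValueError(
                    f"{self.animal_id}: three_way requires 2 maternal breeds"
                )
            if not self.paternal_breed:
                raise ValueError(f"{self.animal_id}: three_way requires paternal breed")

    @property
    def parental_set(self) -> frozenset[str]:
        s = set(self.breeds)
        if self.paternal_breed:
            s.add(self.paternal_breed)
        return frozenset(s)


def compositions_from_frame(df: pd.DataFrame) -> dict[str, BreedComposition]:
    """Parse a composition table (animal_id, cross_type, breeds, paternal_breed)."""
    out = {}
    for row in df.itertuples(index=False):
        breeds = tuple(b for b in str(row.breeds).split(",") if b)
        pat = getattr(row, "paternal_breed", "") or None
        if isinstance(pat, float) and np.isnan(pat):  # pandas NA
            pat = None
        out[row.animal_id] = BreedComposition(
            row.animal_id, row.cross_type, breeds, pat
        )
    return out


@dataclass
class VoteTable:
    """Per-analysis phased values and origin votes for crossbred animals.

    ``values[a, i, k, s]`` is the phased allele of animal ``i``'s haplotype
    slot ``s`` at SNP ``k`` in analysis ``a`` (-1 unresolved);
    ``origins[a, i, k, s]`` the breed vote carried by that slot (-1 none).
    Each allele can collect at most one vote per analysis.
    """

    analysis_ids: list[str]
    animal_ids: list[str]
    values: np.ndarray  # (A, n, L, 2) int8
    origins: np.ndarray  # (A, n, L, 2) int8


def vote_allele_origins(
    phased: dict[str, PhasedAnalysis],
    library: BreedHaplotypeLibrary,
    gm: GenotypeMatrix,
    crossbred_index: np.ndarray,
) -> VoteTable:
    """Trace crossbred core haplotypes through the library and collect votes.

    A fully phased core haplotype found in the library with an assigned origin
    votes that breed for every SNP of the core on its slot; unresolved or
    unassigned haplotypes contribute nothing.
    """
    lib_ids = {w.analysis_id for w in library.windows}
    if set(phased) - lib_ids:
        raise ValueError(
            f"phasing analyses {sorted(set(phased) - lib_ids)} missing from library"
        )
    aids = sorted(phased)
    n = crossbred_index.size
    L = gm.n_snps
    values = np.full((len(aids), n, L, 2), UNKNOWN, dtype=np.int8)
    origins = np.full_like(values, UNKNOWN)
    slices = gm.snp_map.slices()
    for ai, aid in enumerate(aids):
        analysis = phased[aid]
        for chrom, windows in analysis.cores.items():
            off = slices[chrom].start
            h = analysis.haps[chrom][crossbred_index]  # (n, 2, Lc)
            values[ai, :, off : off + h.shape[2], :] = h.transpose(0, 2, 1)
            for win in windows:
                table = library.get(aid, chrom, win).lookup()
                if not table:
                    continue
                hw = h[:, :, win.start : win.end]
                full = ~(hw < 0).any(axis=2)  # (n, 2)
                gsl = slice(off + win.start, off + win.end)
                for i in range(n):
                    for s in (0, 1):
                        if full[i, s]:
                            code = table.get(
                                hw[i, s].astype(np.uint8).tobytes(), -1
                            )
                            if code >= 0:
                                origins[ai, i, gsl, s] = code
    return VoteTable(aids, [gm.animal_ids[i] for i in crossbred_index], values, origins)


@dataclass
class OriginMatrix:
    """Assigned breed origin per crossbred allele.

    ``origins[i, k, s]`` is the breed code (-1 UNKNOWN); ``values[i, k, s]``
    the allele value the slot refers to (at heterozygous SNPs slot 0 holds the
    '0' allele and slot 1 the '1' allele; at homozygous SNPs both equal the
    genotype's allele and, for three-way animals, slot 0 is the
    paternal-forced slot).  ``provenance`` records how each assignment arose.
    """

    animal_ids: list[str]
    breeds: tuple[str, ...]
    snp_map: SnpMap
    origins: np.ndarray  # (n, L, 2) int8
    values: np.ndarray  # (n, L, 2) int8
    provenance: np.ndarray  # (n, L, 2) uint8

    def copy(self) -> "OriginMatrix":
        return OriginMatrix(
            list(self.animal_ids),
            self.breeds,
            self.snp_map,
            self.origins.copy(),
            self.values.copy(),
            self.provenance.copy(),
        )


def _strict_plurality(stacks: list[np.ndarray], codes: list[int]):
    """Strict plurality among candidate breeds.

    ``stacks[j]`` holds the vote counts of breed ``codes[j]``; returns
    (winner code array, winner count array) with -1 where the maximum is not
    unique or zero.
    """
    counts = np.stack(stacks, axis=-1)
    top = counts.max(axis=-1)
    n_top = (counts == top[..., None]).sum(axis=-1)
    win = np.take(np.asarray(codes, dtype=np.int8), np.argmax(counts, axis=-1))
    ok = (top > 0) & (n_top == 1)
    return np.where(ok, win, UNKNOWN).astype(np.int8), top


def _count_votes(
    vt: VoteTable, grp: np.ndarray, g: np.ndarray, n_breeds: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zygosity-filtered vote counts for a group of animals.

    Returns ``V0``/``V1`` (votes for the allele with value 0/1 at heterozygous
    SNPs) and ``Vp`` (pooled votes at homozygous SNPs), each (m, L, n_breeds).
    """
    m, L = g.shape
    V0 = np.zeros((m, L, n_breeds), dtype=np.int16)
    V1 = np.zeros_like(V0)
    Vp = np.zeros_like(V0)
    het = g == 1
    hom = (g == 0) | (g == 2)
    aval = (g // 2).astype(np.int8)  # allele value at homozygous SNPs
    for a in range(len(vt.analysis_ids)):
        v = vt.values[a][grp]
        o = vt.origins[a][grp]
        both = (v[..., 0] >= 0) & (v[..., 1] >= 0)
        het_ok = ~both | (v[..., 0] + v[..., 1] == 1)
        for s in (0, 1):
            val = v[..., s]
            org = o[..., s]
            has = (val >= 0) & (org >= 0)
            het_votes = has & het & het_ok
            hom_votes = has & hom & (val == aval)
            for b in range(n_breeds):
                is_b = org == b
                V0[..., b] += het_votes & (val == 0) & is_b
                V1[..., b] += het_votes & (val == 1) & is_b
                Vp[..., b] += hom_votes & is_b
    return V0, V1, Vp


def _resolve_two_way(
    g: np.ndarray, V0: np.ndarray, V1: np.ndarray, Vp: np.ndarray, b1: int, b2: int
):
    """Per-SNP resolution for a two-way crossbred group.

    The true origin pair is one allele of each breed at every SNP, so an
    assigned pair may never repeat a breed; when both alleles' plurality is
    the same breed the better-supported allele keeps it.
    """
    m, L = g.shape
    het = g == 1
    hom = (g == 0) | (g == 2)
    a0, s0 = _strict_plurality([V0[..., b1], V0[..., b2]], [b1, b2])
    a1, s1 = _strict_plurality([V1[..., b1], V1[..., b2]], [b1, b2])
    conflict = (a0 >= 0) & (a0 == a1)
    a0 = np.where(conflict & ~(s0 > s1), UNKNOWN, a0)
    a1 = np.where(conflict & ~(s1 > s0), UNKNOWN, a1)
    h0 = np.where(Vp[..., b1] > 0, np.int8(b1), UNKNOWN)
    h1 = np.where(Vp[..., b2] > 0, np.int8(b2), UNKNOWN)
    origins = np.stack(
        [np.where(het, a0, np.where(hom, h0, UNKNOWN)),
         np.where(het, a1, np.where(hom, h1, UNKNOWN))],
        axis=-1,
    ).astype(np.int8)
    values = _slot_values(g)
    prov = np.where(origins >= 0, PROV_VOTE, PROV_NONE).astype(np.uint8)
    return origins, values, prov


def _resolve_three_way(
    g: np.ndarray,
    V0: np.ndarray,
    V1: np.ndarray,
    Vp: np.ndarray,
    p: int,
    m1: int,
    m2: int,
):
    """Per-SNP resolution for a three-way crossbred group (paternal breed
    ``p``, maternal breeds ``m1``/``m2``).

    The paternal allele is resolved first; at homozygous SNPs with any votes
    present the breed composition forces one slot to the paternal breed even
    when the haplotype votes conflict.
    """
    het = g == 1
    hom = (g == 0) | (g == 2)
    adm = [p, m1, m2]
    plur0, _ = _strict_plurality([V0[..., b] for b in adm], adm)
    plur1, _ = _strict_plurality([V1[..., b] for b in adm], adm)
    p0, p1 = plur0 == p, plur1 == p
    vp0, vp1 = V0[..., p], V1[..., p]
    pat_slot = np.where(
        p0 & ~p1, 0,
        np.where(
            p1 & ~p0, 1,
            np.where(p0 & p1 & (vp0 > vp1), 0,
                     np.where(p0 & p1 & (vp1 > vp0), 1, -1)),
        ),
    )
    mat0, q0 = _strict_plurality([V0[..., m1], V0[..., m2]], [m1, m2])
    mat1, q1 = _strict_plurality([V1[..., m1], V1[..., m2]], [m1, m2])
    a0 = np.where(pat_slot == 0, np.int8(p), np.where(pat_slot == 1, mat0, UNKNOWN))
    a1 = np.where(pat_slot == 1, np.int8(p), np.where(pat_slot == 0, mat1, UNKNOWN))
    # no slot claimed the paternal breed: alleles may take their maternal
    # plurality, but the pair must still admit one paternal allele
    free = pat_slot < 0
    c0 = np.where(free & (plur0 == mat0), mat0, UNKNOWN)
    c1 = np.where(free & (plur1 == mat1), mat1, UNKNOWN)
    both_mat = free & (c0 >= 0) & (c1 >= 0)
    c0 = np.where(both_mat & ~(q0 > q1), UNKNOWN, c0)
    c1 = np.where(both_mat & ~(q1 > q0), UNKNOWN, c1)
    a0 = np.where(free, c0, a0)
    a1 = np.where(free, c1, a1)

    # homozygous SNPs: pooled votes; composition forces the paternal slot
    pooled = Vp[..., p] + Vp[..., m1] + Vp[..., m2]
    h0 = np.where(pooled > 0, np.int8(p), UNKNOWN)
    hm, _ = _strict_plurality([Vp[..., m1], Vp[..., m2]], [m1, m2])
    origins = np.stack(
        [np.where(het, a0, np.where(hom, h0, UNKNOWN)),
         np.where(het, a1, np.where(hom, hm, UNKNOWN))],
        axis=-1,
    ).astype(np.int8)
    values = _slot_values(g)
    prov = np.where(origins >= 0, PROV_VOTE, PROV_NONE).astype(np.uint8)
    hom_forced = hom & (h0 >= 0)
    prov[..., 0] = np.where(hom_forced, PROV_COMPOSITION, prov[..., 0])
    return origins, values, prov


def _slot_values(g: np.ndarray) -> np.ndarray:
    """Slot allele values: (0, 1) at heterozygous SNPs, (a, a) at homozygous
    ones, (-1, -1) where the genotype is missing."""
    het = g == 1
    hom = (g == 0) | (g == 2)
    a = (g // 2).astype(np.int8)
    v0 = np.where(het, np.int8(0), np.where(hom, a, UNKNOWN))
    v1 = np.where(het, np.int8(1), np.where(hom, a, UNKNOWN))
    return np.stack([v0, v1], axis=-1).astype(np.int8)


def resolve_origins(
    votes: VoteTable,
    compositions: dict[str, BreedComposition],
    gm: GenotypeMatrix,
    crossbred_index: np.ndarray,
    breeds: tuple[str, ...],
) -> OriginMatrix:
    """Resolve the vote table into per-allele breed origins.

    Animals are processed in groups sharing a breed composition; assigned
    labels always lie inside the animal's parental breed set, and UNKNOWN is
    the fallback for absent votes, plurality ties and conflicting evidence.
    """
    code = {b: k for k, b in enumerate(breeds)}
    n = crossbred_index.size
    L = gm.n_snps
    origins = np.full((n, L, 2), UNKNOWN, dtype=np.int8)
    values = np.full((n, L, 2), UNKNOWN, dtype=np.int8)
    prov = np.zeros((n, L, 2), dtype=np.uint8)
    g_all = gm.genotypes[crossbred_index]
    comp_keys = []
    for i, aid in enumerate(votes.animal_ids):
        if aid not in compositions:
            raise ValueError(f"crossbred animal {aid} missing from composition table")
        c = compositions[aid]
        comp_keys.append((c.cross_type, tuple(sorted(c.breeds)), c.paternal_breed or ""))
    comp_keys = np.asarray(comp_keys, dtype=object)
    for key in sorted({tuple(k) for k in comp_keys}):
        grp = np.nonzero([tuple(k) == key for k in comp_keys])[0]
        cross_type, bset, pat = key
        g = g_all[grp]
        V0, V1, Vp = _count_votes(votes, grp, g, len(breeds))
        if cross_type == "two_way":
            b1, b2 = sorted(code[b] for b in bset)
            o, v, pr = _resolve_two_way(g, V0, V1, Vp, b1, b2)
        else:
            m1, m2 = sorted(code[b] for b in bset)
            o, v, pr = _resolve_three_way(g, V0, V1, Vp, code[pat], m1, m2)
        origins[grp], values[grp], prov[grp] = o, v, pr
    return OriginMatrix(
        list(votes.animal_ids), tuple(breeds), gm.snp_map, origins, values, prov
    )


# ---------------------------------------------------------------------------
# post-processing rules
# ---------------------------------------------------------------------------


def _rule3_fill(
    om: OriginMatrix,
    i: int,
    comp: BreedComposition,
    library: BreedHaplotypeLibrary,
    code: dict[str, int],
) -> None:
    """Bridge UNKNOWN alleles between same-breed assignments (rule 3).

    The two flanking assigned alleles must co-occur, with their observed
    values, in a single assigned library haplotype of that breed taken from
    the analysis with the smallest core length whose core spans both flanks.
    Intervals containing an assignment whose pairing with the bridged breed is
    inadmissible for the composition are left untouched.
    """
    pset = {code[b] for b in comp.parental_set}
    pat = code[comp.paternal_breed] if comp.paternal_breed else None
    # windows by (chrom) sorted by core length then offset flag
    by_chrom: dict[str, list] = {}
    for w in sorted(
        library.windows,
        key=lambda w: (w.window.end - w.window.start, w.analysis_id.endswith("o")),
    ):
        by_chrom.setdefault(w.chrom, []).append(w)
    slices = om.snp_map.slices()
    orig = om.origins[i]
    vals = om.values[i]
    for chrom, sl in slices.items():
        o = orig[sl]
        v = vals[sl]
        for b in sorted(pset):
            on_b = (o == b).any(axis=1)
            pos = np.nonzero(on_b)[0]
            if pos.size < 2:
                continue
            for idx in range(pos.size - 1):
                left, right = int(pos[idx]), int(pos[idx + 1])
                if right <= left + 1:
                    continue
                interior = np.arange(left + 1, right)
                if not (o[interior] < 0).any():
                    continue
                # admissibility of bridging breed b across the interior
                blocked = False
                for k in interior:
                    ks = o[k]
                    if (ks >= 0).all():
                        continue  # fully assigned, nothing to fill
                    ass = ks[ks >= 0]
                    for c in ass:
                        if c == b:
                            continue
                        if comp.cross_type == "two_way":
                            continue  # the two breeds always pair
                        if b != pat and c != pat:
                            blocked = True  # two maternal breeds cannot pair
                if blocked:
                    continue
                # flank values on the b-assigned slots
                sL = int(np.nonzero(o[left] == b)[0][0])
                sR = int(np.nonzero(o[right] == b)[0][0])
                vL, vR = int(v[left, sL]), int(v[right, sR])
                if vL < 0 or vR < 0:
                    continue
                hap = _find_spanning_hap(
                    by_chrom.get(chrom, []), left, right, b, vL, vR
                )
                if hap is None:
                    continue
                win_start, row = hap
                for k in interior:
                    ks = o[k]
                    if (ks >= 0).all() or (ks == b).any():
                        continue
                    open_slots = np.nonzero(ks < 0)[0]
                    if open_slots.size == 2:
                        hv = int(row[k - win_start])
                        match = np.nonzero(v[k] == hv)[0]
                        s = int(match[0]) if match.size else int(open_slots[0])
                    else:
                        s = int(open_slots[0])
                    o[k, s] = b
                    om.provenance[i, sl][k, s] = PROV_RULE3


def _find_spanning_hap(windows, left, right, b, vL, vR):
    """Smallest-core assigned library haplotype of breed ``b`` spanning both
    flanks with matching allele values; returns (core start, haplotype row)."""
    for w in windows:
        if w.window.start <= left and right < w.window.end:
            sel = (
                (w.origin == b)
                & (w.haps[:, left - w.window.start] == vL)
                & (w.haps[:, right - w.window.start] == vR)
            )
            hit = np.nonzero(sel)[0]
            if hit.size:
                return w.window.start, w.haps[hit[0]]
            return None  # smallest spanning core lacks such a haplotype
    return None


def apply_post_rules(
    om: OriginMatrix,
    compositions: dict[str, BreedComposition],
    library: BreedHaplotypeLibrary,
    gm: GenotypeMatrix | None = None,
) -> OriginMatrix:
    """Apply the three deduction rules in order (1, 2, 3), one pass.

    Rule 1: a lone maternal-breed assignment fixes the other allele to the
    paternal breed (three-way).  Rule 2: for two-way animals a lone assignment
    of either breed fixes the other allele to the remaining breed.  Rule 3:
    UNKNOWN alleles bracketed by same-breed assignments supported by a single
    spanning library haplotype take that breed.
    """
    om = om.copy()
    code = {b: k for k, b in enumerate(om.breeds)}
    for i, aid in enumerate(om.animal_ids):
        comp = compositions[aid]
        o = om.origins[i]
        assigned = o >= 0
        n_ass = assigned.sum(axis=1)
        lone = n_ass == 1
        lone_breed = np.where(assigned[:, 0], o[:, 0], o[:, 1])
        open_slot = np.where(assigned[:, 0], 1, 0)
        if comp.cross_type == "three_way":
            pat = code[comp.paternal_breed]
            mats = {code[b] for b in comp.breeds}
            fix = lone & np.isin(lone_breed, list(mats))
            rule = PROV_RULE1
            fill = np.full(o.shape[0], pat, dtype=np.int8)
        else:
            b1, b2 = (code[b] for b in comp.breeds)
            fix = lone
            rule = PROV_RULE2
            fill = (b1 + b2 - lone_breed).astype(np.int8)
        rows = np.nonzero(fix)[0]
        o[rows, open_slot[rows]] = fill[rows]
        om.provenance[i][rows, open_slot[rows]] = rule
        _rule3_fill(om, i, comp, library, code)
    return om


def assign_breed_origin(
    phased: dict[str, PhasedAnalysis],
    library: BreedHaplotypeLibrary,
    gm: GenotypeMatrix,
    composition: pd.DataFrame | dict[str, BreedComposition],
    crossbred_index: np.ndarray | None = None,
    post_rules: bool = False,
) -> OriginMatrix:
    """Vote, resolve and (optionally) post-process in one call."""
    comps = (
        composition
        if isinstance(composition, dict)
        else compositions_from_frame(composition)
    )
    if crossbred_index is None:
        crossbred_index = np.nonzero(
            np.isin(np.asarray(gm.animal_ids, dtype=object), list(comps))
        )[0]
    votes = vote_allele_origins(phased, library, gm, crossbred_index)
    om = resolve_origins(votes, comps, gm, crossbred_index, library.breeds)
    if post_rules:
        om = apply_post_rules(om, comps, library, gm)
    return om
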