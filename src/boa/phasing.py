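"""Long-range phasing with surrogate parents and haplotype-library imputation.

Genotypes are phased per *core* (a tile of consecutive SNPs) using *surrogate
parents*: animals with (almost) no opposing homozygous genotypes with the
focal animal over the core plus flanking *tails*.  Surrogates are partitioned
into the two haplotype sides of the focal animal through their mutual opposing
homozygotes, and an allele is declared for a side once enough informative
surrogates agree.  Partially phased cores are then completed against a library
of fully phased core haplotypes when the completion is unambiguous.

Each analysis is defined by a (core length, tail length) pair and an offset
flag; offset analyses shift all cores by half a core length so that core
boundaries interleave between the two runs.  A suite of such analyses phases
every SNP many times, which downstream consensus voting exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simdata import GenotypeMatrix

__all__ = [
    "AnalysisSettings",
    "CoreWindow",
    "PhasedAnalysis",
    "DEFAULT_CORE_TAILS",
    "default_suite",
    "build_cores",
    "find_surrogates",
    "phase_core",
    "impute_from_library",
    "run_phasing_suite",
]

#: (core length, tail length) pairs of the default phasing suite
DEFAULT_CORE_TAILS: list[tuple[int, int]] = [
    (150, 200),
    (200, 200),
    (250, 100),
    (250, 200),
    (300, 100),
    (300, 200),
    (350, 50),
    (350, 100),
    (350, 200),
]

UNRESOLVED = np.int8(-1)


@dataclass(frozen=True)
class AnalysisSettings:
    """Parameters of one phasing analysis.

    ``genotype_error_tol`` is the fraction of opposing homozygotes tolerated
    when qualifying surrogates (the allowance is ``floor(tol * window size)``,
    compared inclusively).  ``min_surrogates`` informative surrogates must
    agree on a phase before it is declared, with at most
    ``max_surrogate_disagreement_pct`` percent of them disagreeing.
    ``max_partition_surrogates`` caps how many surrogates (those with the
    fewest opposing homozygotes) enter the side-partitioning step; surrogate
    evidence saturates well below the cap in dense panels.
    """

    core_length: int
    tail_length: int
    offset: bool = False
    genotype_error_tol: float = 0.01
    hap_disagreement_tol: float = 0.01
    min_surrogates: int = 10
    max_surrogate_disagreement_pct: float = 10.0
    max_partition_surrogates: int = 300

    def __post_init__(self) -> None:
        if self.core_length < 1 or self.tail_length < 0:
            raise ValueError("core_length >= 1 and tail_length >= 0 required")
        for tol in (self.genotype_error_tol, self.hap_disagreement_tol):
            if not 0 <= tol <= 1:
                raise ValueError("tolerances must lie in [0, 1]")

    @property
    def analysis_id(self) -> str:
        return f"c{self.core_length}t{self.tail_length}{'o' if self.offset else 'n'}"


def default_suite(
    core_tails: list[tuple[int, int]] | None = None, **kwargs
) -> list[AnalysisSettings]:
    """The default suite: each (core, tail) pair run non-offset and offset."""
    pairs = DEFAULT_CORE_TAILS if core_tails is None else core_tails
    out = []
    for core, tail in pairs:
        for off in (False, True):
            out.append(AnalysisSettings(core, tail, offset=off, **kwargs))
    return out


@dataclass(frozen=True)
class CoreWindow:
    """A core interval and its tail-extended window, in SNP indices of one
    chromosome; intervals are half-open."""

    start: int
    end: int
    tail_start: int
    tail_end: int


def build_cores(n_snps: int, settings: AnalysisSettings) -> list[CoreWindow]:
    """Tile a chromosome of ``n_snps`` SNPs into cores.

    Non-offset analyses start cores at 0, core_length, 2*core_length, ...; a
    final partial core is retained.  Offset analyses prepend a half-length
    first core so cores of the two runs overlap by 50 %.  Tails extend each
    core by ``tail_length`` SNPs on both sides, clipped at chromosome ends.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    c, t = settings.core_length, settings.tail_length
    starts = [0]
    first_end = min(c // 2, n_snps) if settings.offset else min(c, n_snps)
    bounds = [(0, first_end)]
    pos = first_end
    while pos < n_snps:
        bounds.append((pos, min(pos + c, n_snps)))
        pos += c
    return [
        CoreWindow(s, e, max(0, s - t), min(n_snps, e + t)) for s, e in bounds
    ]


# ---------------------------------------------------------------------------
# surrogate parents
# ---------------------------------------------------------------------------


def _opposing_matrix(gw: np.ndarray) -> np.ndarray:
    """Pairwise counts of opposing homozygotes over the window (n x n)."""
    a0 = (gw == 0).astype(np.float32)
    a2 = (gw == 2).astype(np.float32)
    p = a0 @ a2.T
    return np.rint(p + p.T).astype(np.int32)


def find_surrogates(
    genotypes: np.ndarray,
    window: np.ndarray | slice,
    focal: int,
    genotype_error_tol: float = 0.01,
) -> np.ndarray:
    """Animals qualifying as surrogate parents of ``focal`` over ``window``.

    Animal ``j`` qualifies iff its count of opposing homozygotes with the
    focal animal over the window is at most ``floor(tol * window size)``.
    Missing genotypes never count as opposing.
    """
    gw = genotypes[:, window]
    gf = gw[focal]
    opp = (((gf == 0) & (gw == 2)) | ((gf == 2) & (gw == 0))).sum(axis=1)
    allowance = int(np.floor(genotype_error_tol * gw.shape[1]))
    ok = np.nonzero(opp <= allowance)[0]
    return ok[ok != focal]


def _two_color(adj: np.ndarray) -> np.ndarray:
    """Greedy BFS 2-colouring of a conflict graph.

    The seed (highest-degree node, lowest index on ties) gets colour 0 and the
    colouring propagates along conflict edges; nodes unreachable from the seed
    stay -1 (side unknown) unless the graph has no edges at all, in which case
    every node joins side 0 (all surrogates mutually compatible).
    """
    m = adj.shape[0]
    color = np.full(m, -1, dtype=np.int8)
    if m == 0:
        return color
    deg = adj.sum(axis=1)
    if deg.max() == 0:
        color[:] = 0
        return color
    seed = int(np.argmax(deg))
    color[seed] = 0
    frontier = np.zeros(m, dtype=bool)
    frontier[seed] = True
    cur = 0
    while frontier.any():
        reached = adj[frontier].any(axis=0)
        new = reached & (color < 0)
        cur = 1 - cur
        color[new] = cur
        frontier = new
    # local refinement: move surrogates to the side they conflict with less
    # (repairs odd-cycle propagation errors in noisy conflict graphs)
    for _ in range(2):
        in0 = color == 0
        in1 = color == 1
        if not (in0.any() and in1.any()):
            break
        c0 = adj[:, in0].sum(axis=1)
        c1 = adj[:, in1].sum(axis=1)
        colored = color >= 0
        new_color = np.where(
            colored & (c0 > c1), 1, np.where(colored & (c1 > c0), 0, color)
        ).astype(np.int8)
        if np.array_equal(new_color, color):
            break
        color = new_color
    return color


def _declare_sides(
    g_core: np.ndarray,
    het_idx: np.ndarray,
    side_counts0: np.ndarray,
    side_counts2: np.ndarray,
    settings: AnalysisSettings,
) -> np.ndarray:
    """Declared allele per heterozygous SNP for one side (-1 undeclared)."""
    n0 = side_counts0[het_idx]
    n2 = side_counts2[het_idx]
    total = n0 + n2
    minority = np.minimum(n0, n2)
    with np.errstate(invalid="ignore"):
        ok = (total >= settings.min_surrogates) & (
            minority * 100.0 <= settings.max_surrogate_disagreement_pct * total
        )
    out = np.where(n2 > n0, np.int8(1), np.int8(0))
    return np.where(ok, out, UNRESOLVED).astype(np.int8)


def _refine_sides(
    color: np.ndarray,
    win0: np.ndarray,
    win2: np.ndarray,
    n_iter: int = 5,
) -> np.ndarray:
    """Polish the side partition with a signed consensus iteration.

    ``win0``/``win2`` are surrogate x window-heterozygous-SNP homozygosity
    indicators.  A surrogate sharing the focal's first haplotype agrees with
    the focal's (unknown) phase vector wherever it is homozygous, a sharer of
    the second haplotype anti-agrees; side labels and phase vector are
    therefore the signs of the leading rank-one factorisation of the signed
    evidence matrix, found by alternating updates from the conflict-graph
    colouring."""
    e = win2.astype(np.float32) - win0.astype(np.float32)
    sigma = np.where(color == 0, 1.0, np.where(color == 1, -1.0, 0.0)).astype(
        np.float32
    )
    for _ in range(n_iter):
        h = np.sign(e.T @ sigma)
        new = np.sign(e @ h)
        if np.array_equal(new, sigma):
            break
        sigma = new
    out = np.full(color.size, -1, dtype=np.int8)
    out[sigma > 0] = 0
    out[sigma < 0] = 1
    return out


def _phase_focal(
    g_core: np.ndarray,
    surr: np.ndarray,
    opp_row: np.ndarray,
    opp_mat: np.ndarray,
    allowance: int,
    core0_counts: np.ndarray,
    core2_counts: np.ndarray,
    win0_counts: np.ndarray,
    win2_counts: np.ndarray,
    het_win: np.ndarray,
    settings: AnalysisSettings,
) -> np.ndarray:
    """Phase one animal's core given its surrogate set.

    ``opp_row`` holds the focal animal's opposing-homozygote counts against
    everybody; ``opp_mat`` the pairwise counts (only surrogate x surrogate
    entries are read).  ``core0_counts``/``core2_counts`` are
    (n_animals, core) boolean matrices of homozygous genotypes, used to
    accumulate per-side evidence; ``win0_counts``/``win2_counts`` the same
    over the tail-extended window, used to partition surrogates into the two
    haplotype sides (``het_win``: the focal's heterozygous window SNPs).
    """
    c = g_core.size
    hap = np.full((2, c), UNRESOLVED, dtype=np.int8)
    hom0 = g_core == 0
    hom2 = g_core == 2
    hap[:, hom0] = 0
    hap[:, hom2] = 1
    het_idx = np.nonzero(g_core == 1)[0]
    if het_idx.size == 0 or surr.size == 0:
        return hap

    if surr.size > settings.max_partition_surrogates:
        order = np.argsort(opp_row[surr], kind="stable")
        surr = np.sort(surr[order[: settings.max_partition_surrogates]])

    adj = opp_mat[np.ix_(surr, surr)] > allowance
    color = _two_color(adj)
    if het_win.any():
        color = _refine_sides(
            color, win0_counts[surr][:, het_win], win2_counts[surr][:, het_win]
        )
    d = []
    for side in (0, 1):
        rows = surr[color == side]
        if rows.size:
            s0 = core0_counts[rows].sum(axis=0)
            s2 = core2_counts[rows].sum(axis=0)
            d.append(_declare_sides(g_core, het_idx, s0, s2, settings))
        else:
            d.append(np.full(het_idx.size, UNRESOLVED, dtype=np.int8))
    d0, d1 = d
    both = (d0 >= 0) & (d1 >= 0)
    conflict = both & (d0 + d1 != 1)
    d0 = np.where(conflict, UNRESOLVED, d0)
    d1 = np.where(conflict, UNRESOLVED, d1)
    # genotype complement: a heterozygous SNP declared on one side fixes the other
    only0 = (d0 >= 0) & (d1 < 0)
    only1 = (d1 >= 0) & (d0 < 0)
    d1 = np.where(only0, 1 - d0, d1).astype(np.int8)
    d0 = np.where(only1, 1 - d1, d0).astype(np.int8)
    hap[0, het_idx] = d0
    hap[1, het_idx] = d1
    return hap


def phase_core(
    genotypes: np.ndarray,
    core: np.ndarray | slice,
    window: np.ndarray | slice,
    focal: int,
    settings: AnalysisSettings,
    surrogates: np.ndarray | None = None,
) -> np.ndarray:
    """Phase the core of one animal; standalone counterpart of the suite path.

    Returns a (2, core length) array over {0, 1, -1}; unresolved entries are
    the fallback, never an error.
    """
    gw = genotypes[:, window]
    allowance = int(np.floor(settings.genotype_error_tol * gw.shape[1]))
    if surrogates is None:
        surrogates = find_surrogates(
            genotypes, window, focal, settings.genotype_error_tol
        )
    gf = gw[focal]
    opp = (((gf == 0) & (gw == 2)) | ((gf == 2) & (gw == 0))).sum(axis=1)
    # pairwise counts among surrogates only (small matrix)
    gs = gw[surrogates]
    a0 = (gs == 0).astype(np.float32)
    a2 = (gs == 2).astype(np.float32)
    opp_full = np.zeros((genotypes.shape[0], genotypes.shape[0]), dtype=np.int32)
    sub = np.rint(a0 @ a2.T)
    opp_full[np.ix_(surrogates, surrogates)] = (sub + sub.T).astype(np.int32)
    gc = genotypes[:, core]
    return _phase_focal(
        gc[focal],
        np.asarray(surrogates),
        opp,
        opp_full,
        allowance,
        (gc == 0),
        (gc == 2),
        (gw == 0),
        (gw == 2),
        gf == 1,
        settings,
    )


# ---------------------------------------------------------------------------
# haplotype-library imputation
# ---------------------------------------------------------------------------


def impute_from_library(
    haps: np.ndarray,
    g_core: np.ndarray,
    hap_disagreement_tol: float = 0.01,
    max_iter: int = 5,
) -> np.ndarray:
    """Complete partially phased core haplotypes from the library of fully
    phased ones.

    ``haps`` is (n_animals, 2, core) over {0, 1, -1}; ``g_core`` the matching
    genotypes.  A partial haplotype is completed when exactly one library
    haplotype matches all its resolved positions and violates at most
    ``floor(tol * core)`` genotype constraints (a constraint exists wherever
    the complementary haplotype is resolved and the genotype is non-missing).
    When several library haplotypes match, the ambiguity is pruned by
    requiring the genotype complement of the candidate to be a library
    haplotype itself; if exactly one candidate pair explains the genotype,
    both haplotypes are completed.  Remaining ambiguity leaves entries
    unresolved.  The library is rebuilt and matching repeated until a fixed
    point (at most ``max_iter`` rounds).
    """
    haps = haps.copy()
    n, _, c = haps.shape
    allowance = int(np.floor(hap_disagreement_tol * c))
    for _ in range(max_iter):
        rows = haps.reshape(2 * n, c)
        full = ~(rows < 0).any(axis=1)
        if not full.any():
            break
        # dedup by row bytes (insertion order); order never affects results
        # because every downstream decision is order-invariant
        full_rows = rows[full].astype(np.uint8)
        seen: dict[bytes, int] = {}
        for h in range(full_rows.shape[0]):
            seen.setdefault(full_rows[h].tobytes(), h)
        lib = full_rows[np.fromiter(seen.values(), dtype=np.int64)].astype(np.int8)
        lib_set = set(seen.keys())
        partial_idx = np.nonzero(~full)[0]
        if partial_idx.size == 0:
            break
        pr = rows[partial_idx]
        res = pr >= 0
        # mismatches at resolved positions, via two rank-1 products
        libf = lib.astype(np.float32)
        r1 = (res & (pr == 1)).astype(np.float32)
        r0 = (res & (pr == 0)).astype(np.float32)
        mism = r1 @ (1.0 - libf).T + r0 @ libf.T  # (n_partial, H)
        exact = mism < 0.5

        # genotype-constraint violations for candidate completions
        animal = partial_idx // 2
        other = haps[animal, 1 - (partial_idx % 2)]
        g = g_core[animal]
        constrained = (other >= 0) & (g >= 0) & ~res
        target = np.where(constrained, g - other, np.int8(0)).astype(np.float32)
        # candidate value must equal target where constrained
        c1 = (constrained & (target == 1)).astype(np.float32)
        c0 = (constrained & (target == 0)).astype(np.float32)
        viol = c1 @ (1.0 - libf).T + c0 @ libf.T
        ok = exact & (viol <= allowance + 0.5)

        n_match = ok.sum(axis=1)
        changed = False

        def consistent_now(row_i: int, h: np.ndarray, gr: np.ndarray) -> bool:
            # adoption-time check against the paired haplotype's current state
            # (it may have been completed earlier in this same pass)
            other_now = rows[row_i ^ 1]
            m = (other_now >= 0) & (gr >= 0)
            return int(((h + other_now != gr) & m).sum()) <= allowance

        for r in np.nonzero(n_match == 1)[0]:
            row_i = int(partial_idx[r])
            new = lib[int(np.argmax(ok[r]))]
            if np.array_equal(rows[row_i], new):
                continue
            if consistent_now(row_i, new, g[r]):
                rows[row_i] = new
                changed = True
        # pair pruning for ambiguous rows with a complete genotype
        for r in np.nonzero(n_match > 1)[0]:
            row_i = int(partial_idx[r])
            gr = g[r]
            if (gr < 0).any():
                continue
            viable = []
            for k in np.nonzero(ok[r])[0]:
                comp = gr - lib[k]
                if comp.min() < 0 or comp.max() > 1:
                    continue
                if comp.astype(np.uint8).tobytes() in lib_set:
                    viable.append(int(k))
                    if len(viable) > 1:
                        break
            if len(viable) == 1:
                h = lib[viable[0]]
                if not np.array_equal(rows[row_i], h) and consistent_now(row_i, h, gr):
                    rows[row_i] = h
                    paired = row_i ^ 1
                    fill = rows[paired] < 0
                    rows[paired][fill] = (gr - h)[fill]
                    changed = True
                    continue
            # consensus fill: entries every matching candidate agrees on
            cand = np.nonzero(ok[r])[0]
            if 1 < cand.size <= 500:
                sub = lib[cand]
                agree = (sub == sub[0]).all(axis=0)
                other_now = rows[row_i ^ 1]
                safe = (other_now < 0) | (gr < 0) | (sub[0] + other_now == gr)
                fill = agree & safe & (rows[row_i] < 0)
                if fill.any():
                    rows[row_i][fill] = sub[0][fill]
                    changed = True
        haps = rows.reshape(n, 2, c)
        # complement heterozygous positions on the paired haplotype
        het = g_core == 1
        for s in (0, 1):
            m = het & (haps[:, s] >= 0) & (haps[:, 1 - s] < 0)
            if m.any():
                haps[:, 1 - s][m] = 1 - haps[:, s][m]
        if not changed:
            break
    return haps


# ---------------------------------------------------------------------------
# full analyses
# ---------------------------------------------------------------------------


@dataclass
class PhasedAnalysis:
    """Phased haplotypes of one analysis: per chromosome an
    (n_animals, 2, n_snps) array over {0, 1, -1} plus the core tiling."""

    settings: AnalysisSettings
    cores: dict[str, list[CoreWindow]] = field(default_factory=dict)
    haps: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def analysis_id(self) -> str:
        return self.settings.analysis_id


def _half_products(g: np.ndarray, start: int, stop: int) -> np.ndarray:
    """Unsymmetrized opposing-homozygote products over columns [start, stop)."""
    sub = g[:, start:stop]
    a0 = (sub == 0).astype(np.float32)
    a2 = (sub == 2).astype(np.float32)
    return a0 @ a2.T


def _phase_chromosome(
    g: np.ndarray, settings: AnalysisSettings, use_kernel: bool = True
) -> tuple[list[CoreWindow], np.ndarray]:
    n, L = g.shape
    cores = build_cores(L, settings)
    haps = np.full((n, 2, L), UNRESOLVED, dtype=np.int8)
    # The opposing-homozygote matrix of consecutive windows is maintained by
    # a sliding update (windows overlap by the tails): entries are exact
    # small-integer sums in float32, so the result is identical to computing
    # each window from scratch.
    acc: np.ndarray | None = None
    prev: CoreWindow | None = None
    for win in cores:
        wsl = slice(win.tail_start, win.tail_end)
        csl = slice(win.start, win.end)
        if acc is None:
            acc = _half_products(g, win.tail_start, win.tail_end)
        else:
            assert prev is not None
            if win.tail_start > prev.tail_start:
                acc -= _half_products(g, prev.tail_start, win.tail_start)
            if win.tail_end > prev.tail_end:
                acc += _half_products(g, prev.tail_end, win.tail_end)
        prev = win
        opp = np.rint(acc + acc.T).astype(np.int32)
        allowance = int(np.floor(settings.genotype_error_tol * (win.tail_end - win.tail_start)))
        np.fill_diagonal(opp, allowance + 1)  # exclude self
        gc = np.ascontiguousarray(g[:, csl])
        gw = np.ascontiguousarray(g[:, wsl])
        hw = np.empty((n, 2, win.end - win.start), dtype=np.int8)
        if use_kernel:
            from ._kernels import phase_window

            phase_window(
                gc, gw, opp, allowance, settings.min_surrogates,
                float(settings.max_surrogate_disagreement_pct),
                settings.max_partition_surrogates, hw,
            )
        else:
            c0 = gc == 0
            c2 = gc == 2
            w0 = gw == 0
            w2 = gw == 2
            for i in range(n):
                surr = np.nonzero(opp[i] <= allowance)[0]
                hw[i] = _phase_focal(
                    gc[i], surr, opp[i], opp, allowance, c0, c2, w0, w2,
                    gw[i] == 1, settings
                )
        hw = impute_from_library(hw, gc, settings.hap_disagreement_tol)
        haps[:, :, csl] = hw
    return cores, haps


def phase_analysis(gm: GenotypeMatrix, settings: AnalysisSettings) -> PhasedAnalysis:
    """Run one phasing analysis over all chromosomes of a genotype panel."""
    out = PhasedAnalysis(settings)
    for name, sl in gm.snp_map.slices().items():
        cores, haps = _phase_chromosome(gm.genotypes[:, sl], settings)
        out.cores[name] = cores
        out.haps[name] = haps
    return out


def run_phasing_suite(
    gm: GenotypeMatrix,
    suite: list[AnalysisSettings] | None = None,
    progress: bool = False,
) -> dict[str, PhasedAnalysis]:
    """Run a suite of analyses; results keyed by analysis id.

    Deterministic given the inputs: analyses run in suite order, animals in
    panel order and cores left to right.
    """
    if suite is None:
        suite = default_suite()
    if not suite:
        raise ValueError("empty phasing suite")
    out: dict[str, PhasedAnalysis] = {}
    for settings in suite:
        if settings.analysis_id in out:
            raise ValueError(f"duplicate analysis id {settings.analysis_id}")
        out[settings.analysis_id] = phase_analysis(gm, settings)
        if progress:  # pragma: no cover - cosmetic
            print(f"phased {settings.analysis_id}")
    return out
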