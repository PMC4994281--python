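"""Accuracy statistics, genetic differentiation and setting-selection tools.

Covers: per-animal %correct / %incorrect / %unknown against the simulator's
truth; the global multi-locus Weir–Cockerham (1984) fixation index F_ST among
the purebred populations (ratio of summed variance components across loci);
the closed-form expected %correct for heterozygous genotypes of a two-way
crossbred based on within-breed minor allele frequencies; greedy forward
selection of phasing analyses; and the Spearman comparison of the selected
order with a predefined core/tail-length ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .assignment import OriginMatrix
from .phasing import AnalysisSettings
from .simdata import GenotypeMatrix, TruthOrigins

__all__ = [
    "AssignmentStats",
    "FstEstimate",
    "SelectionTrace",
    "score_alleles",
    "assignment_stats",
    "global_fst",
    "expected_correct_het",
    "observed_het_correct",
    "forward_select_analyses",
    "predefined_order",
    "spearman_vs_predefined",
]


# ---------------------------------------------------------------------------
# accuracy against truth
# ---------------------------------------------------------------------------


@dataclass
class AssignmentStats:
    """Per-animal percentages and their aggregates for one chromosome."""

    per_animal: pd.DataFrame  # animal_id, cohort, pct_correct/incorrect/unknown

    def aggregate(self, by: str = "cohort") -> pd.DataFrame:
        """Mean/min/max of the three percentages plus the share of animals
        with at least 80 % of alleles assigned."""
        df = self.per_animal.copy()
        df["pct_assigned"] = 100.0 - df["pct_unknown"]
        g = df.groupby(by)
        out = g.agg(
            mean_correct=("pct_correct", "mean"),
            min_correct=("pct_correct", "min"),
            max_correct=("pct_correct", "max"),
            mean_incorrect=("pct_incorrect", "mean"),
            max_incorrect=("pct_incorrect", "max"),
            mean_unknown=("pct_unknown", "mean"),
            max_unknown=("pct_unknown", "max"),
            pct_animals_ge80_assigned=("pct_assigned", lambda s: 100.0 * (s >= 80).mean()),
        )
        return out


def score_alleles(
    om: OriginMatrix, truth: TruthOrigins, genotypes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-allele correctness: (correct, incorrect) boolean (n, L, 2) arrays.

    At heterozygous SNPs the assigned slots are matched to the truth slots by
    allele value; at homozygous SNPs the two truth labels are matched to the
    assigned pair by maximum agreement (the only convention that never
    penalises a correct unordered assignment).
    """
    if om.origins.shape != truth.origins.shape:
        raise ValueError("assignment and truth matrices have mismatching shapes")
    if list(om.animal_ids) != list(truth.animal_ids):
        raise ValueError("assignment and truth animal ids differ")
    o = om.origins
    assigned = o >= 0
    het = genotypes == 1
    # truth origin of the allele with value v, defined at heterozygous SNPs
    t_pat, t_mat = truth.origins[..., 0], truth.origins[..., 1]
    v_pat = truth.hap_values[..., 0]
    truth_of_value0 = np.where(v_pat == 0, t_pat, t_mat)
    truth_of_value1 = np.where(v_pat == 1, t_pat, t_mat)

    correct = np.zeros_like(assigned)
    # heterozygous: slot s of the origin matrix refers to allele value om.values[..,s]
    for s in (0, 1):
        val = om.values[..., s]
        t = np.where(val == 0, truth_of_value0, truth_of_value1)
        correct[..., s] = het & assigned[..., s] & (o[..., s] == t)
    # homozygous (or missing-genotype) SNPs: maximum-agreement pairing
    hom = ~het
    m_id = (o[..., 0] == t_pat) & assigned[..., 0]
    m_id = m_id.astype(np.int8) + ((o[..., 1] == t_mat) & assigned[..., 1])
    m_sw = ((o[..., 0] == t_mat) & assigned[..., 0]).astype(np.int8) + (
        (o[..., 1] == t_pat) & assigned[..., 1]
    )
    use_id = m_id >= m_sw
    c0 = np.where(use_id, o[..., 0] == t_pat, o[..., 0] == t_mat)
    c1 = np.where(use_id, o[..., 1] == t_mat, o[..., 1] == t_pat)
    correct[..., 0] |= hom & assigned[..., 0] & c0
    correct[..., 1] |= hom & assigned[..., 1] & c1
    incorrect = assigned & ~correct
    return correct, incorrect


def assignment_stats(
    om: OriginMatrix,
    truth: TruthOrigins,
    genotypes: np.ndarray,
    cohorts: Sequence[str] | None = None,
    chromosome: str | None = None,
) -> AssignmentStats:
    """Per-animal %correct / %incorrect / %unknown over all alleles of one
    chromosome (or the whole genome); the three percentages sum to 100."""
    correct, incorrect = score_alleles(om, truth, genotypes)
    if chromosome is not None:
        sl = om.snp_map.slices()[chromosome]
        correct = correct[:, sl]
        incorrect = incorrect[:, sl]
    n_alleles = correct.shape[1] * 2
    pc = 100.0 * correct.sum(axis=(1, 2)) / n_alleles
    pi = 100.0 * incorrect.sum(axis=(1, 2)) / n_alleles
    df = pd.DataFrame(
        {
            "animal_id": om.animal_ids,
            "cohort": list(cohorts) if cohorts is not None else ["all"] * len(om.animal_ids),
            "pct_correct": pc,
            "pct_incorrect": pi,
            "pct_unknown": 100.0 - pc - pi,
        }
    )
    return AssignmentStats(df)


# ---------------------------------------------------------------------------
# Weir–Cockerham global F_ST
# ---------------------------------------------------------------------------


@dataclass
class FstEstimate:
    """Global multi-locus F_ST with per-locus variance components.

    ``a`` is the among-population component, ``b`` among individuals within
    populations, ``c`` within individuals; the global estimate is
    sum(a) / sum(a + b + c) over loci (the ratio-of-sums convention)."""

    fst: float
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray


def global_fst(genotypes: np.ndarray, labels: Sequence[str]) -> FstEstimate:
    """Weir–Cockerham (1984) F_ST from biallelic dosages (0/1/2, -1 missing).

    Requires at least two populations; loci where fewer than two populations
    have data, or that are monomorphic overall, contribute zero to both sums.
    Returns NaN when no locus is informative.
    """
    labels = np.asarray(labels)
    pops = np.unique(labels)
    if pops.size < 2:
        raise ValueError("global F_ST needs at least two populations")
    g = np.asarray(genotypes, dtype=np.float64)
    valid = g >= 0
    L = g.shape[1]
    r = pops.size
    n_i = np.zeros((r, L))
    p_i = np.zeros((r, L))
    h_i = np.zeros((r, L))
    for k, pop in enumerate(pops):
        rows = labels == pop
        v = valid[rows]
        n = v.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(v, g[rows], 0.0).sum(axis=0) / (2.0 * n)
            h = np.where(v & (g[rows] == 1), 1.0, 0.0).sum(axis=0) / n
        n_i[k] = n
        p_i[k] = np.where(n > 0, p, 0.0)
        h_i[k] = np.where(n > 0, h, 0.0)
    has = n_i > 0
    r_l = has.sum(axis=0).astype(float)  # populations with data per locus
    ok = r_l >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.sum(axis=0) / r_l
        nc = (n_i.sum(axis=0) - (n_i**2).sum(axis=0) / n_i.sum(axis=0)) / (r_l - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r_l * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r_l - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r_l * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r_l - 1) / r_l * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r_l - 1) / r_l * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    mono = (pbar <= 0) | (pbar >= 1)
    keep = ok & ~mono & (nbar > 1) & (nc > 0)
    a = np.where(keep, a, 0.0)
    b = np.where(keep, b, 0.0)
    c = np.where(keep, c, 0.0)
    denom = (a + b + c).sum()
    fst = float(a.sum() / denom) if denom != 0 else float("nan")
    return FstEstimate(fst, a, b, c)


# ---------------------------------------------------------------------------
# MAF-based expectation for heterozygous genotypes
# ---------------------------------------------------------------------------


def expected_correct_het(q_b, q_c):
    """Expected %correct for heterozygous genotypes of a two-way crossbred
    when assignment uses only within-breed minor allele frequencies.

    With the minor allele coded 0 and within-breed MAFs ``q_b`` and ``q_c``,
    assigning every heterozygote the origin pattern of the most frequent
    heterozygous configuration is correct with probability::

        max((1-q_b) q_c, (1-q_c) q_b) / ((1-q_b) q_c + (1-q_c) q_b)

    expressed in percent.  Undefined (NaN) when both products vanish.
    Accepts scalars or arrays; symmetric in its arguments.
    """
    qb = np.asarray(q_b, dtype=float)
    qc = np.asarray(q_c, dtype=float)
    if np.any((qb < 0) | (qb > 1) | (qc < 0) | (qc > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    x = (1.0 - qb) * qc
    y = (1.0 - qc) * qb
    denom = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        # ratio first: q_B = q_C then yields exactly 1/2, a fixed allele
        # exactly 1, so the printed special cases are exact in floating point
        out = 100.0 * (np.maximum(x, y) / denom)
    out = np.where(denom > 0, out, np.nan)
    return out.item() if out.ndim == 0 else out


def observed_het_correct(
    om: OriginMatrix,
    truth: TruthOrigins,
    genotypes: np.ndarray,
    animal_mask: np.ndarray | None = None,
    chromosome: str | None = None,
    breed_freqs: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-SNP %correct among assigned alleles at heterozygous genotypes.

    Intended for two-way crossbreds.  Returns a frame with one row per SNP
    that shows at least one heterozygous crossbred genotype; when within-breed
    allele frequencies of the '0' allele complement are supplied as
    ``breed_freqs`` (minor-allele frequencies q_B, q_C per SNP), the expected
    %correct and the observed-minus-expected difference are included.
    """
    correct, incorrect = score_alleles(om, truth, genotypes)
    if animal_mask is not None:
        correct = correct[animal_mask]
        incorrect = incorrect[animal_mask]
        genotypes = genotypes[animal_mask]
    sl = slice(None) if chromosome is None else om.snp_map.slices()[chromosome]
    het = (genotypes == 1)[:, sl, None]
    n_corr = (correct[:, sl] & het).sum(axis=(0, 2))
    n_inc = (incorrect[:, sl] & het).sum(axis=(0, 2))
    assigned = n_corr + n_inc
    rows = np.nonzero(het.any(axis=(0, 2)))[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * n_corr / assigned
    df = pd.DataFrame(
        {
            "snp": rows,
            "n_assigned": assigned[rows],
            "pct_correct": pct[rows],
        }
    )
    if breed_freqs is not None:
        qb, qc = breed_freqs
        exp = expected_correct_het(qb, qc)
        df["expected"] = np.asarray(exp)[rows]
        df["diff"] = df["pct_correct"] - df["expected"]
    return df


# ---------------------------------------------------------------------------
# forward selection of phasing analyses
# ---------------------------------------------------------------------------


@dataclass
class SelectionTrace:
    """Greedy forward-selection order with the criterion after each step."""

    order: list[str] = field(default_factory=list)
    criterion: list[float] = field(default_factory=list)


def forward_select_analyses(
    analysis_ids: Sequence[str],
    criterion: Callable[[list[str]], float],
) -> SelectionTrace:
    """Greedy forward selection over phasing analyses.

    Starting from the empty set, at each step the analysis whose addition
    maximises ``criterion(subset)`` joins the set (ties broken by analysis id)
    until all analyses are included.
    """
    remaining = sorted(analysis_ids)
    trace = SelectionTrace()
    chosen: list[str] = []
    while remaining:
        best_id, best_val = None, -np.inf
        for aid in remaining:
            val = criterion(chosen + [aid])
            if val > best_val:
                best_id, best_val = aid, val
        chosen.append(best_id)
        remaining.remove(best_id)
        trace.order.append(best_id)
        trace.criterion.append(float(best_val))
    return trace


def predefined_order(suite: Sequence[AnalysisSettings]) -> list[str]:
    """The reference ranking: decreasing total (core+tail) length, ties by
    decreasing core length; the offset run follows its non-offset partner."""
    pairs = sorted(
        {(s.core_length, s.tail_length) for s in suite},
        key=lambda ct: (-(ct[0] + ct[1]), -ct[0]),
    )
    ids = []
    by_key = {(s.core_length, s.tail_length, s.offset): s.analysis_id for s in suite}
    for c, t in pairs:
        for off in (False, True):
            if (c, t, off) in by_key:
                ids.append(by_key[(c, t, off)])
    return ids


def spearman_vs_predefined(
    selection_order: Sequence[str], suite: Sequence[AnalysisSettings]
) -> float:
    """Spearman rank correlation between the forward-selection order and the
    predefined core/tail ranking (midranks on ties)."""
    ref = predefined_order(suite)
    if set(ref) != set(selection_order):
        raise ValueError("selection order and suite analyses differ")
    ranks_sel = {aid: k for k, aid in enumerate(selection_order)}
    x = [ranks_sel[aid] for aid in ref]
    y = list(range(len(ref)))
    return float(sstats.spearmanr(x, y).statistic)
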