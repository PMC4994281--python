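"""Evaluation tests: accuracy scoring, Weir–Cockerham F_ST against an
independent per-locus oracle, the MAF-based expectation, forward selection
and the Spearman comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boa.assignment import OriginMatrix
from boa.evaluation import (
    assignment_stats,
    expected_correct_het,
    forward_select_analyses,
    global_fst,
    observed_het_correct,
    predefined_order,
    spearman_vs_predefined,
)
from boa.genome import ChromosomeMap, SnpMap
from boa.phasing import default_suite
from boa.simdata import TruthOrigins


def om_from(origins, values, snp_map, ids=None):
    o = np.asarray(origins, dtype=np.int8)
    return OriginMatrix(
        ids or [f"x{i}" for i in range(o.shape[0])],
        ("A", "B", "C"),
        snp_map,
        o,
        np.asarray(values, dtype=np.int8),
        np.zeros_like(o, dtype=np.uint8),
    )


def map_of(n):
    return SnpMap([ChromosomeMap("chr1", 1.0, np.linspace(0.01, 0.99, n))])


class TestAssignmentStats:
    def _truth(self, n_snp, origins, values):
        return TruthOrigins(
            ["x0"], np.asarray([origins], dtype=np.int8),
            np.asarray([values], dtype=np.uint8),
        )

    def test_perfect_assignment_scores_100(self):
        m = map_of(3)
        t_orig = [[0, 1]] * 3
        t_val = [[0, 1]] * 3  # heterozygous everywhere
        g = np.array([[1, 1, 1]], dtype=np.int8)
        om = om_from([[[0, 1]] * 3], [[[0, 1]] * 3], m)
        st_ = assignment_stats(om, self._truth(3, t_orig, t_val), g)
        row = st_.per_animal.iloc[0]
        assert (row.pct_correct, row.pct_incorrect, row.pct_unknown) == (100, 0, 0)

    def test_hand_counted_mixture(self):
        # 10 SNPs / 20 alleles: 15 correct, 1 incorrect, 4 unknown -> 75/5/20
        m = map_of(10)
        rng = np.random.Generator(np.random.PCG64(0))
        t_orig = np.column_stack([np.zeros(10, int), np.ones(10, int)])
        t_val = np.column_stack([np.zeros(10, int), np.ones(10, int)])
        g = np.full((1, 10), 1, dtype=np.int8)
        o = t_orig.copy()
        o[0, 0] = 1  # incorrect: true A claimed B
        o[1, 0] = -1
        o[2, 1] = -1
        o[3, 0] = -1
        o[4, 1] = -1  # four unknowns
        om = om_from([o], [t_val], m)
        row = assignment_stats(om, self._truth(10, t_orig, t_val), g).per_animal.iloc[0]
        assert (row.pct_correct, row.pct_incorrect, row.pct_unknown) == (75, 5, 20)

    def test_all_unknown(self):
        m = map_of(4)
        t_orig = [[0, 1]] * 4
        t_val = [[0, 1]] * 4
        g = np.ones((1, 4), dtype=np.int8)
        om = om_from([[[-1, -1]] * 4], [[[0, 1]] * 4], m)
        row = assignment_stats(om, self._truth(4, t_orig, t_val), g).per_animal.iloc[0]
        assert (row.pct_correct, row.pct_incorrect, row.pct_unknown) == (0, 0, 100)

    def test_homozygous_unordered_matching_never_penalises(self):
        # truth (pat=B, mat=C) at a homozygous SNP; assignment (C, B) is right
        m = map_of(1)
        g = np.array([[2]], dtype=np.int8)
        om = om_from([[[2, 1]]], [[[1, 1]]], m)
        truth = self._truth(1, [[1, 2]], [[1, 1]])
        row = assignment_stats(om, truth, g).per_animal.iloc[0]
        assert row.pct_correct == 100

    def test_percentages_sum_to_100_exactly(self, rng):
        m = map_of(17)
        n = 6
        g = rng.integers(0, 3, size=(n, 17)).astype(np.int8)
        t_orig = rng.integers(0, 3, size=(n, 17, 2)).astype(np.int8)
        t_val = rng.integers(0, 2, size=(n, 17, 2)).astype(np.uint8)
        o = rng.integers(-1, 3, size=(n, 17, 2)).astype(np.int8)
        v = rng.integers(0, 2, size=(n, 17, 2)).astype(np.int8)
        om = om_from(o, v, m)
        truth = TruthOrigins([f"x{i}" for i in range(n)], t_orig, t_val)
        df = assignment_stats(om, truth, g).per_animal
        assert np.allclose(df.pct_correct + df.pct_incorrect + df.pct_unknown, 100)


def _wc_oracle(genos, labels):
    """Independent scalar Weir–Cockerham implementation (per-locus loops)."""
    import math

    pops = sorted(set(labels))
    A = B = C = 0.0
    for k in range(genos.shape[1]):
        ns, ps, hs = [], [], []
        for p in pops:
            rows = [g for g, l in zip(genos[:, k], labels) if l == p and g >= 0]
            if not rows:
                continue
            ns.append(len(rows))
            ps.append(sum(rows) / (2.0 * len(rows)))
            hs.append(sum(1 for g in rows if g == 1) / len(rows))
        r = len(ns)
        if r < 2:
            continue
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (sum(ns) - sum(x * x for x in ns) / sum(ns)) / (r - 1)
        if nc <= 0:
            continue
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        if pbar <= 0 or pbar >= 1:
            continue
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    return A / (A + B + C)


class TestGlobalFst:
    def test_fixed_alternate_alleles_give_one(self):
        g = np.vstack([np.zeros((10, 5)), np.full((10, 5), 2)]).astype(np.int8)
        labels = ["p1"] * 10 + ["p2"] * 10
        assert global_fst(g, labels).fst == pytest.approx(1.0)

    def test_duplicated_population_near_zero(self, rng):
        g = rng.integers(0, 3, size=(200, 50)).astype(np.int8)
        labels = ["p1"] * 100 + ["p2"] * 100
        assert abs(global_fst(g, labels).fst) < 0.01

    def test_matches_independent_scalar_oracle(self, rng):
        g = rng.integers(0, 3, size=(20, 12)).astype(np.int8)
        g[rng.random(g.shape) < 0.05] = -1
        labels = ["p1"] * 10 + ["p2"] * 10
        assert global_fst(g, labels).fst == pytest.approx(_wc_oracle(g, labels))

    def test_three_population_oracle_agreement(self, rng):
        g = rng.integers(0, 3, size=(30, 25)).astype(np.int8)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        assert global_fst(g, labels).fst == pytest.approx(_wc_oracle(g, labels))

    def test_monomorphic_matrix_is_nan(self):
        g = np.ones((10, 4), dtype=np.int8) * 2
        assert np.isnan(global_fst(g, ["p1"] * 5 + ["p2"] * 5).fst)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            global_fst(np.zeros((4, 2), dtype=np.int8), ["p"] * 4)


class TestExpectedCorrectHet:
    def test_equal_frequencies_give_exactly_50(self):
        for q in (0.05, 0.1, 0.25, 0.5):
            assert expected_correct_het(q, q) == 50.0

    def test_fixed_allele_gives_exactly_100(self):
        assert expected_correct_het(0.0, 0.3) == 100.0
        assert expected_correct_het(0.2, 0.0) == 100.0

    def test_printed_formula_value(self):
        assert expected_correct_het(0.1, 0.4) == pytest.approx(100 * 0.36 / 0.42)

    def test_undefined_when_both_products_vanish(self):
        assert np.isnan(expected_correct_het(0.0, 0.0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.floats(0.001, 0.5), st.floats(0.001, 0.5)
    )
    def test_symmetry_and_bounds(self, qb, qc):
        f = expected_correct_het(qb, qc)
        assert f == pytest.approx(expected_correct_het(qc, qb))
        assert 50.0 <= f <= 100.0

    def test_grid_bounds_hold_everywhere(self):
        q = np.linspace(0.005, 0.5, 100)
        qb, qc = np.meshgrid(q, q)
        f = expected_correct_het(qb, qc)
        assert np.all(f >= 50.0 - 1e-9) and np.all(f <= 100.0 + 1e-9)
        assert np.allclose(f, f.T)


class TestForwardSelection:
    def test_single_analysis_trace(self):
        trace = forward_select_analyses(["a1"], lambda s: 42.0)
        assert trace.order == ["a1"] and trace.criterion == [42.0]

    def test_duplicate_analyses_leave_criterion_unchanged(self):
        crit = lambda s: float(len(set(s)))
        trace = forward_select_analyses(["a1", "a1_copy"], lambda s: float(len({x.rstrip("_copy") for x in s})))
        assert trace.criterion[0] == trace.criterion[1]

    def test_matches_exhaustive_stepwise_maxima(self):
        vals = {
            frozenset(): 0, frozenset("a"): 5, frozenset("b"): 3, frozenset("c"): 4,
            frozenset("ab"): 6, frozenset("ac"): 9, frozenset("bc"): 7,
            frozenset("abc"): 8,
        }
        crit = lambda s: vals[frozenset(s)]
        trace = forward_select_analyses(list("abc"), crit)
        # exhaustive greedy: best single 'a' (5); best pair containing a: 'ac' (9);
        # then all three (8)
        assert trace.order == ["a", "c", "b"]
        assert trace.criterion == [5, 9, 8]


class TestSpearman:
    def test_identity_and_reversal(self):
        suite = default_suite()
        ref = predefined_order(suite)
        assert spearman_vs_predefined(ref, suite) == pytest.approx(1.0)
        assert spearman_vs_predefined(ref[::-1], suite) == pytest.approx(-1.0)

    def test_predefined_ranking_of_default_nine(self):
        suite = default_suite()
        ref = predefined_order(suite)
        pairs = [tuple(map(int, aid[1:-1].split("t"))) for aid in ref[::2]]
        # decreasing total length, ties by decreasing core length
        assert pairs == [
            (350, 200), (300, 200), (350, 100), (250, 200),
            (350, 50), (300, 100), (200, 200), (250, 100), (150, 200),
        ]
        # offset runs adjacent to their non-offset partners
        assert all(ref[i][-1] == "n" and ref[i + 1][-1] == "o" for i in range(0, 18, 2))

    def test_mismatching_sets_rejected(self):
        suite = default_suite()
        with pytest.raises(ValueError):
            spearman_vs_predefined(["nope"], suite)
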