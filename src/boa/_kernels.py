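"""Compiled inner loop of the long-range phasing stage.

`phase_window` replicates the per-animal partition/declare logic of
`boa.phasing._phase_focal` (surrogate capping, conflict-graph 2-colouring
with local refinement, signed rank-one side polish, per-side declaration,
conflict pruning and genotype complement) as one numba-compiled pass over
all animals of a window.  Every operation is exact integer arithmetic, so
the compiled path is bit-identical to the pure-numpy reference; the
equivalence is asserted by the test-suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["phase_window", "crossover_fill"]


@njit(cache=True)
def crossover_fill(
    pos: np.ndarray,  # (L,) global SNP positions, sorted ascending
    starts: np.ndarray,  # (n_chrom,) chromosome start coordinates
    lengths: np.ndarray,  # (n_chrom,) chromosome lengths in Morgan
    counts: np.ndarray,  # (n_gametes, n_chrom) crossover counts
    start_flip: np.ndarray,  # (n_gametes, n_chrom) bool start-haplotype flips
    u: np.ndarray,  # flat uniform draws, consumed in gamete-then-chromosome order
    masks: np.ndarray,  # (n_gametes, L) bool output
) -> None:
    """Fill crossover masks; replicates
    `(np.searchsorted(sorted_events, pos, side="right") % 2) == 0`
    per gamete with a two-pointer sweep (positions are globally sorted)."""
    n_g, n_c = counts.shape
    L = pos.size
    off = 0
    for i in range(n_g):
        ncap = n_c
        for c in range(n_c):
            ncap += counts[i, c]
        ev = np.empty(ncap, np.float64)
        ne = 0
        for c in range(n_c):
            if start_flip[i, c]:
                ev[ne] = starts[c]
                ne += 1
            k = counts[i, c]
            for t in range(k):
                ev[ne] = starts[c] + u[off + t] * lengths[c]
                ne += 1
            off += k
        if ne == 0:
            for p in range(L):
                masks[i, p] = True
            continue
        evs = np.sort(ev[:ne])
        j = 0
        for p in range(L):
            while j < ne and evs[j] <= pos[p]:
                j += 1
            masks[i, p] = (j % 2) == 0


@njit(cache=True, fastmath=True)
def _sign_matvec(m: np.ndarray, v: np.ndarray, out: np.ndarray) -> None:
    """out[a] = sign(m[a] . v); entries of m and v are -1/0/+1, so every
    accumulation is an exact small integer in float32 regardless of the
    summation order fastmath may choose."""
    r, k = m.shape
    for a in range(r):
        acc = np.float32(0.0)
        row = m[a]
        for b in range(k):
            acc += row[b] * v[b]
        out[a] = 1.0 if acc > 0.0 else (-1.0 if acc < 0.0 else 0.0)


@njit(cache=True)
def phase_window(  # noqa: C901 - one flat kernel keeps the hot loop allocation-free
    gc: np.ndarray,  # (n, core) int8 genotypes of the core
    gw: np.ndarray,  # (n, window) int8 genotypes of the tail-extended window
    opp: np.ndarray,  # (n, n) int32 opposing-homozygote counts, diag > allowance
    allowance: int,
    min_surrogates: int,
    max_disagreement_pct: float,
    max_partition: int,
    haps: np.ndarray,  # (n, 2, core) int8 output, written in place
) -> None:
    n, c = gc.shape
    w = gw.shape[1]
    sel = np.zeros(n, np.uint8)
    surr = np.empty(n, np.int64)
    het = np.empty(c, np.int64)
    for i in range(n):
        # homozygous sites resolve immediately; the rest starts unresolved
        nhet = 0
        for p in range(c):
            gv = gc[i, p]
            if gv == 0:
                haps[i, 0, p] = 0
                haps[i, 1, p] = 0
            elif gv == 2:
                haps[i, 0, p] = 1
                haps[i, 1, p] = 1
            else:
                haps[i, 0, p] = -1
                haps[i, 1, p] = -1
                if gv == 1:
                    het[nhet] = p
                    nhet += 1
        if nhet == 0:
            continue

        # surrogate set, capped to the max_partition closest animals
        # (fewest opposing homozygotes first, ties by index)
        s = 0
        for j in range(n):
            if opp[i, j] <= allowance:
                s += 1
        if s == 0:
            continue
        if s > max_partition:
            for j in range(n):
                sel[j] = 0
            cnt = 0
            v = 0
            while cnt < max_partition and v <= allowance:
                for j in range(n):
                    if opp[i, j] == v:
                        sel[j] = 1
                        cnt += 1
                        if cnt == max_partition:
                            break
                v += 1
            s = 0
            for j in range(n):
                if sel[j]:
                    surr[s] = j
                    s += 1
        else:
            s = 0
            for j in range(n):
                if opp[i, j] <= allowance:
                    surr[s] = j
                    s += 1

        # conflict graph among surrogates and its BFS 2-colouring
        adj = np.zeros((s, s), np.uint8)
        deg = np.zeros(s, np.int64)
        for u in range(s):
            su = surr[u]
            # the diagonal is a self-loop by construction (the caller sets
            # opp[j, j] = allowance + 1); kept to mirror the reference path,
            # where it only biases the refinement counts by each node's own
            # side membership
            adj[u, u] = 1
            for t in range(u + 1, s):
                if opp[su, surr[t]] > allowance:
                    adj[u, t] = 1
                    adj[t, u] = 1
        maxdeg = 0
        seed = 0
        for u in range(s):
            d = 0
            for t in range(s):
                d += adj[u, t]
            deg[u] = d
            if d > maxdeg:
                maxdeg = d
                seed = u
        color = np.full(s, -1, np.int8)
        if maxdeg == 0:
            for u in range(s):
                color[u] = 0
        else:
            color[seed] = 0
            frontier = np.zeros(s, np.uint8)
            newf = np.zeros(s, np.uint8)
            frontier[seed] = 1
            nf = 1
            cur = 0
            while nf > 0:
                nf = 0
                cur = 1 - cur
                for t in range(s):
                    newf[t] = 0
                    if color[t] < 0:
                        acc = 0
                        row = adj[t]  # adj is symmetric
                        for u in range(s):
                            acc += row[u] * frontier[u]
                        if acc > 0:
                            newf[t] = 1
                            nf += 1
                for t in range(s):
                    if newf[t] == 1:
                        color[t] = cur
                tmp = frontier
                frontier = newf
                newf = tmp
            # local refinement: move to the side conflicted with less
            newc = np.empty(s, np.int8)
            is0 = np.empty(s, np.uint8)
            is1 = np.empty(s, np.uint8)
            for _it in range(2):
                n0 = 0
                n1 = 0
                for u in range(s):
                    is0[u] = 1 if color[u] == 0 else 0
                    is1[u] = 1 if color[u] == 1 else 0
                    n0 += is0[u]
                    n1 += is1[u]
                if n0 == 0 or n1 == 0:
                    break
                for u in range(s):
                    if color[u] >= 0:
                        c0n = 0
                        c1n = 0
                        row = adj[u]
                        for t in range(s):
                            c0n += row[t] * is0[t]
                            c1n += row[t] * is1[t]
                        if c0n > c1n:
                            newc[u] = 1
                        elif c1n > c0n:
                            newc[u] = 0
                        else:
                            newc[u] = color[u]
                    else:
                        newc[u] = color[u]
                same = True
                for u in range(s):
                    if newc[u] != color[u]:
                        same = False
                    color[u] = newc[u]
                if same:
                    break

        # signed rank-one polish over the focal's heterozygous window SNPs
        nh = 0
        for q in range(w):
            if gw[i, q] == 1:
                nh += 1
        if nh > 0:
            e = np.empty((s, nh), np.float32)
            et = np.empty((nh, s), np.float32)
            hcols = np.empty(nh, np.int64)
            col = 0
            for q in range(w):
                if gw[i, q] == 1:
                    hcols[col] = q
                    col += 1
            for u in range(s):
                row = gw[surr[u]]
                for t in range(nh):
                    gv = row[hcols[t]]
                    val = np.float32(0.0)
                    if gv == 2:
                        val = np.float32(1.0)
                    elif gv == 0:
                        val = np.float32(-1.0)
                    e[u, t] = val
                    et[t, u] = val
            sigma = np.empty(s, np.float32)
            news = np.empty(s, np.float32)
            h = np.empty(nh, np.float32)
            for u in range(s):
                if color[u] == 0:
                    sigma[u] = 1.0
                elif color[u] == 1:
                    sigma[u] = -1.0
                else:
                    sigma[u] = 0.0
            for _it in range(5):
                _sign_matvec(et, sigma, h)
                _sign_matvec(e, h, news)
                same = True
                for u in range(s):
                    if news[u] != sigma[u]:
                        same = False
                        break
                if same:
                    break
                for u in range(s):
                    sigma[u] = news[u]
            for u in range(s):
                if sigma[u] > 0.0:
                    color[u] = 0
                elif sigma[u] < 0.0:
                    color[u] = 1
                else:
                    color[u] = -1

        # per-side declaration at the heterozygous core SNPs
        cnt0 = np.zeros((2, nhet), np.int32)
        cnt2 = np.zeros((2, nhet), np.int32)
        for u in range(s):
            cu = color[u]
            if cu < 0:
                continue
            row = gc[surr[u]]
            for p in range(nhet):
                gv = row[het[p]]
                if gv == 0:
                    cnt0[cu, p] += 1
                elif gv == 2:
                    cnt2[cu, p] += 1
        for p in range(nhet):
            pos = het[p]
            d0 = np.int8(-1)
            d1 = np.int8(-1)
            for side in range(2):
                n0 = cnt0[side, p]
                n2 = cnt2[side, p]
                total = n0 + n2
                minority = n0 if n0 < n2 else n2
                if total >= min_surrogates and (
                    minority * 100.0 <= max_disagreement_pct * total
                ):
                    d = np.int8(1) if n2 > n0 else np.int8(0)
                else:
                    d = np.int8(-1)
                if side == 0:
                    d0 = d
                else:
                    d1 = d
            if d0 >= 0 and d1 >= 0 and d0 + d1 != 1:
                d0 = np.int8(-1)
                d1 = np.int8(-1)
            if d0 >= 0 and d1 < 0:
                d1 = np.int8(1 - d0)
            elif d1 >= 0 and d0 < 0:
                d0 = np.int8(1 - d1)
            haps[i, 0, pos] = d0
            haps[i, 1, pos] = d1
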