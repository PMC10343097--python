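"""Independent brute-force oracles used across the test suite.

Everything here recomputes quantities by exhaustive enumeration or
naive quadratic dynamic programming, deliberately sharing no code with
the implementations under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import rankdata

GAP = "-"


# ---------------------------------------------------------------------------
# global pairwise alignments

def enumerate_alignments(s1: str, s2: str):
    """Yield every global alignment of two strings as (row1, row2)."""
    n, m = len(s1), len(s2)

    def rec(i, j, r1, r2):
        if i == n and j == m:
            yield r1, r2
            return
        if i < n and j < m:
            yield from rec(i + 1, j + 1, r1 + s1[i], r2 + s2[j])
        if i < n:
            yield from rec(i + 1, j, r1 + s1[i], r2 + GAP)
        if j < m:
            yield from rec(i, j + 1, r1 + GAP, r2 + s2[j])

    yield from rec(0, 0, "", "")


def affine_alignment_score(row1, row2, score_fn, gap_open, gap_extend):
    """Score one alignment: Σ substitution − Σ gap runs (open + len·extend)."""
    total = 0.0
    for x, y in zip(row1, row2):
        if x != GAP and y != GAP:
            total += score_fn(x, y)
    for row in (row1, row2):
        in_gap = False
        for ch in row:
            if ch == GAP:
                if not in_gap:
                    total -= gap_open
                    in_gap = True
                total -= gap_extend
            else:
                in_gap = False
    return total


def best_global_score(s1, s2, score_fn, gap_open, gap_extend):
    """Max affine-gap score over all global alignments (enumeration)."""
    return max(
        affine_alignment_score(r1, r2, score_fn, gap_open, gap_extend)
        for r1, r2 in enumerate_alignments(s1, s2)
    )


# ---------------------------------------------------------------------------
# LCS

def lcs_quadratic(s1: str, s2: str) -> int:
    n, m = len(s1), len(s2)
    L = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if s1[i - 1] == s2[j - 1]:
                L[i, j] = L[i - 1, j - 1] + 1
            else:
                L[i, j] = max(L[i - 1, j], L[i, j - 1])
    return int(L[n, m])


# ---------------------------------------------------------------------------
# pair-HMM path enumeration

def hmm_path_quantities(s1: str, s2: str, params):
    """(total probability, posterior match-mass matrix) by path enumeration.

    Paths run over states M (emit a pair), Ix (emit from s1), Iy (emit
    from s2), starting from the model's start distribution, with Ix↔Iy
    transitions disallowed, ending after both sequences are consumed.
    """
    from msaforge.seq_core import encode_residues

    a = encode_residues(s1)
    b = encode_residues(s2)
    n, m = len(a), len(b)
    t = params.transitions
    pi = params.start
    end = np.full(3, params.tau) if params.model_end else np.ones(3)
    em_m = params.match_emit
    em_i = params.insert_emit

    total = 0.0
    post = np.zeros((n, m))

    def rec(i, j, state, prob, matched):
        nonlocal total
        if i == n and j == m:
            p = prob * end[state]
            total += p
            for (ii, jj) in matched:
                post[ii, jj] += p
            return
        for nxt in range(3):
            tp = pi[nxt] if state is None else t[state, nxt]
            if tp == 0:
                continue
            if nxt == 0 and i < n and j < m:
                rec(i + 1, j + 1, 0, prob * tp * em_m[a[i], b[j]],
                    matched + [(i, j)])
            elif nxt == 1 and i < n:
                rec(i + 1, j, 1, prob * tp * em_i[a[i]], matched)
            elif nxt == 2 and j < m:
                rec(i, j + 1, 2, prob * tp * em_i[b[j]], matched)

    rec(0, 0, None, 1.0, [])
    return total, post / total if total > 0 else post


def best_mea_value(posterior: np.ndarray) -> float:
    """Max summed posterior over all monotone alignments (enumeration)."""
    n, m = posterior.shape
    s1 = "A" * n
    s2 = "A" * m
    best = 0.0
    for r1, r2 in enumerate_alignments(s1, s2):
        i = j = 0
        val = 0.0
        for x, y in zip(r1, r2):
            if x != GAP and y != GAP:
                val += posterior[i, j]
            if x != GAP:
                i += 1
            if y != GAP:
                j += 1
        best = max(best, val)
    return best


# ---------------------------------------------------------------------------
# profile--profile alignment

def profile_match_score(p1, p2, c1: int, c2: int, matrix) -> float:
    """Weighted mean substitution score of two profile columns."""
    total = 0.0
    for i, row1 in zip(p1.ids, p1.rows):
        for j, row2 in zip(p2.ids, p2.rows):
            x, y = row1[c1], row2[c2]
            if x != GAP and y != GAP:
                total += p1.weights[i] * p2.weights[j] * matrix.score(x, y)
    wsum1 = sum(p1.weights.values())
    wsum2 = sum(p2.weights.values())
    return total / (wsum1 * wsum2)


def enumerate_column_paths(L1: int, L2: int):
    """All monotone column-pairings of two profiles (None = gap column)."""
    def rec(i, j, path):
        if i == L1 and j == L2:
            yield path
            return
        if i < L1 and j < L2:
            yield from rec(i + 1, j + 1, path + [(i, j)])
        if i < L1:
            yield from rec(i + 1, j, path + [(i, None)])
        if j < L2:
            yield from rec(i, j + 1, path + [(None, j)])

    yield from rec(0, 0, [])


def best_profile_merge_score(p1, p2, matrix, gap_open, gap_extend) -> float:
    """Max profile-merge score over all column pairings (flat gap costs)."""
    best = None
    for path in enumerate_column_paths(p1.length, p2.length):
        total = 0.0
        for which in (0, 1):
            in_gap = False
            for pair in path:
                if pair[which] is None:
                    if not in_gap:
                        total -= gap_open
                        in_gap = True
                    total -= gap_extend
                else:
                    in_gap = False
        for c1, c2 in path:
            if c1 is not None and c2 is not None:
                total += profile_match_score(p1, p2, c1, c2, matrix)
        best = total if best is None else max(best, total)
    return best


def score_merged_profiles(merged, p1, p2, matrix, gap_open, gap_extend) -> float:
    """Score the implementation's merged profile under the oracle's model.

    The column path is reconstructed from the gap structure, which is
    unambiguous as long as neither input profile has an all-gap column.
    """
    path = []
    c1 = c2 = 0
    for c in range(merged.length):
        take1 = any(
            merged.rows[merged.ids.index(i)][c] != GAP for i in p1.ids
        )
        take2 = any(
            merged.rows[merged.ids.index(j)][c] != GAP for j in p2.ids
        )
        path.append((c1 if take1 else None, c2 if take2 else None))
        if take1:
            c1 += 1
        if take2:
            c2 += 1
    total = 0.0
    for which in (0, 1):
        in_gap = False
        for pair in path:
            if pair[which] is None:
                if not in_gap:
                    total -= gap_open
                    in_gap = True
                total -= gap_extend
            else:
                in_gap = False
    for a, b in path:
        if a is not None and b is not None:
            total += profile_match_score(p1, p2, a, b, matrix)
    return total


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank by sign enumeration

def wilcoxon_exact_enumeration(a, b) -> float:
    """P(W+ ≥ observed) over all 2^n sign assignments (zeros dropped)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for mask in range(2 ** n):
        w = sum(ranks[k] for k in range(n) if mask >> k & 1)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2 ** n


# ---------------------------------------------------------------------------
# best-class frequencies by direct recomputation

def best_class_freqs_brute(records, classes=("P", "C", "I", "CI")):
    """records: iterable of (instance, cls, score) for one benchmark band."""
    by_inst: dict[str, list[tuple[str, float]]] = {}
    for inst, cls, score in records:
        by_inst.setdefault(inst, []).append((cls, score))
    tied = {c: 0 for c in classes}
    unique = {c: 0 for c in classes}
    for inst, entries in by_inst.items():
        best = max(s for _, s in entries)
        winners = {c for c, s in entries if s == best}
        for c in winners:
            tied[c] += 1
            if len(winners) == 1:
                unique[c] += 1
    n = len(by_inst)
    return (
        {c: 100.0 * tied[c] / n for c in classes},
        {c: 100.0 * unique[c] / n for c in classes},
    )
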