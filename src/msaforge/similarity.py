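"""Stage 1 — pairwise similarity scoring.

Five interchangeable techniques fill the triangular similarity matrix that
drives guide-tree construction:

``F`` (FULL)
    Identity percentage of the optimal global affine-gap (Gotoh)
    alignment.  Identity is counted over columns where neither sequence
    has a gap.
``Q`` (QUICK)
    Fraction of distinct k-tuples shared by the two sequences (k = 1 by
    default, the classic fast protein heuristic).
``L`` (LCS)
    Length of the longest common subsequence divided by the shorter
    sequence length; computed in linear space (two rolling DP rows).
``K`` (KMERS)
    Shared k-mer count — the sum over distinct k-mers of the smaller of
    the two occurrence counts — divided by the shorter sequence length
    (k = 3 by default).
``P`` (PROBA)
    Maximum-expected-accuracy score from pair-HMM posterior residue-match
    probabilities, normalised by the shorter sequence length.

All five return values on a common 0–100 scale and are symmetric in their
two arguments, so Stage 2 is method-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio.Align import substitution_matrices

from .seq_core import (
    AA_ORDER,
    GAP,
    Sequence,
    SubstitutionMatrix,
    encode_residues,
)

METHODS = ("F", "K", "L", "P", "Q")

_NEG = -1e30  # effectively -inf for DP cells


# ---------------------------------------------------------------------------
# FULL: global affine-gap alignment (Gotoh)

def global_affine_align(
    s1: str,
    s2: str,
    matrix: SubstitutionMatrix,
    gap_open: float,
    gap_extend: float,
) -> tuple[float, str, str]:
    """Optimal global alignment with affine gap cost ``open + g * extend``.

    Returns ``(score, aligned1, aligned2)``.  Traceback ties prefer the
    diagonal, then the vertical (gap in ``s2``), then the horizontal
    move, so the result is deterministic.
    """
    if not s1 or not s2:
        raise ValueError("cannot align an empty sequence")
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be non-negative")
    a = encode_residues(s1)
    b = encode_residues(s2)
    n, m = len(a), len(b)
    S = matrix.scores[np.ix_(a, b)]  # (n, m) residue pair scores

    go = gap_open + gap_extend  # cost of opening a fresh 1-long gap
    ge = gap_extend

    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in s2 (consume s1)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in s1 (consume s2)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + i * ge)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + j * ge)

    for i in range(1, n + 1):
        Mprev, Ixprev, Iyprev = M[i - 1], Ix[i - 1], Iy[i - 1]
        M[i, 1:] = S[i - 1] + np.maximum.reduce(
            [Mprev[:-1], Ixprev[:-1], Iyprev[:-1]]
        )
        Ix[i, 1:] = np.maximum.reduce(
            [Mprev[1:] - go, Iyprev[1:] - go, Ixprev[1:] - ge]
        )
        # horizontal state: sequential along j
        Mi, Ixi, Iyi = M[i], Ix[i], Iy[i]
        for j in range(1, m + 1):
            Iyi[j] = max(Mi[j - 1] - go, Ixi[j - 1] - go, Iyi[j - 1] - ge)

    end_scores = (M[n, m], Ix[n, m], Iy[n, m])
    best = max(end_scores)

    # traceback (deterministic: M before Ix before Iy)
    state = int(np.argmax(end_scores))
    i, j = n, m
    out1: list[str] = []
    out2: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0:
            out1.append(s1[i - 1])
            out2.append(s2[j - 1])
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for st, val in ((0, M[i, j]), (1, Ix[i, j]), (2, Iy[i, j])):
                if abs(val - target) < tol:
                    state = st
                    break
        elif state == 1:
            out1.append(s1[i - 1])
            out2.append(GAP)
            cur = Ix[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - go - cur) < tol:
                state = 0
            elif abs(Ix[i, j] - ge - cur) < tol:
                state = 1
            else:
                state = 2
        else:
            out1.append(GAP)
            out2.append(s2[j - 1])
            cur = Iy[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - go - cur) < tol:
                state = 0
            elif abs(Ix[i, j] - go - cur) < tol:
                state = 1
            else:
                state = 2
    return float(best), "".join(reversed(out1)), "".join(reversed(out2))


def alignment_identity_percent(row1: str, row2: str) -> float:
    """Identity over gap-free columns of a pairwise alignment, in percent."""
    pairs = [(x, y) for x, y in zip(row1, row2) if x != GAP and y != GAP]
    if not pairs:
        return 0.0
    matches = sum(1 for x, y in pairs if x == y)
    return 100.0 * matches / len(pairs)


def score_full(
    s1: str,
    s2: str,
    matrix: SubstitutionMatrix,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """FULL similarity: identity percentage of the optimal global alignment."""
    _, r1, r2 = global_affine_align(s1, s2, matrix, gap_open, gap_extend)
    return alignment_identity_percent(r1, r2)


# ---------------------------------------------------------------------------
# QUICK and KMERS: tuple-counting heuristics

def _check_k(s1: str, s2: str, k: int) -> None:
    if not (1 <= k <= min(len(s1), len(s2))):
        raise ValueError(f"k={k} out of range for lengths {len(s1)}, {len(s2)}")


def score_quick(s1: str, s2: str, k: int = 1) -> float:
    """QUICK similarity: distinct shared k-tuples / (min(len) − k + 1) × 100."""
    _check_k(s1, s2, k)
    t1 = {s1[i : i + k] for i in range(len(s1) - k + 1)}
    t2 = {s2[i : i + k] for i in range(len(s2) - k + 1)}
    denom = min(len(s1), len(s2)) - k + 1
    return 100.0 * min(len(t1 & t2), denom) / denom


def score_kmers(s1: str, s2: str, k: int = 3) -> float:
    """KMERS similarity: Σ_kmer min(count1, count2) / min(len) × 100."""
    _check_k(s1, s2, k)
    c1: dict[str, int] = {}
    c2: dict[str, int] = {}
    for i in range(len(s1) - k + 1):
        w = s1[i : i + k]
        c1[w] = c1.get(w, 0) + 1
    for i in range(len(s2) - k + 1):
        w = s2[i : i + k]
        c2[w] = c2.get(w, 0) + 1
    shared = sum(min(c, c2.get(w, 0)) for w, c in c1.items())
    denom = min(len(s1), len(s2))
    return 100.0 * min(shared, denom) / denom


# ---------------------------------------------------------------------------
# LCS

def lcs_length(s1: str, s2: str) -> int:
    """Longest-common-subsequence length in linear space (two DP rows)."""
    if not s1 or not s2:
        raise ValueError("LCS of an empty sequence is undefined here")
    if len(s2) > len(s1):
        s1, s2 = s2, s1
    prev = np.zeros(len(s2) + 1, dtype=np.int32)
    cur = np.zeros(len(s2) + 1, dtype=np.int32)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    for ch in s1:
        code = ord(ch)
        np.maximum(prev[1:], cur[:-1], out=cur[1:])
        hit = b == code
        np.maximum(cur[1:], np.where(hit, prev[:-1] + 1, 0), out=cur[1:])
        # running max to keep monotonicity along the row
        np.maximum.accumulate(cur, out=cur)
        prev, cur = cur, prev
        cur[:] = 0
    return int(prev[-1])


def score_lcs(s1: str, s2: str) -> float:
    """LCS similarity: 100 × |LCS| / min(len)."""
    return 100.0 * lcs_length(s1, s2) / min(len(s1), len(s2))


# ---------------------------------------------------------------------------
# PROBA: pair-HMM posteriors and maximum expected accuracy

@dataclass
class PairHMMParams:
    """Three-state pair hidden Markov model (match + two insert states).

    ``match_emit`` is the joint residue-pair probability table for the
    match state; ``insert_emit`` the background emission for both insert
    states.  ``delta`` is the match → insert transition probability (gap
    open), ``epsilon`` the insert self-loop (gap extend).  Transitions
    between the two insert states are disallowed.  With ``model_end``
    False the model has no explicit end state: every path that consumes
    both sequences terminates with probability one.
    """

    match_emit: np.ndarray
    insert_emit: np.ndarray
    delta: float = 0.02
    epsilon: float = 0.4
    model_end: bool = False
    tau: float = 0.01

    def __post_init__(self) -> None:
        self.match_emit = np.asarray(self.match_emit, dtype=float)
        self.insert_emit = np.asarray(self.insert_emit, dtype=float)
        na = len(AA_ORDER)
        if self.match_emit.shape != (na, na):
            raise ValueError("match_emit must be 21x21 over AA_ORDER")
        if self.insert_emit.shape != (na,):
            raise ValueError("insert_emit must have 21 entries")
        if abs(self.match_emit.sum() - 1.0) > 1e-9:
            raise ValueError("match emissions must sum to 1")
        if abs(self.insert_emit.sum() - 1.0) > 1e-9:
            raise ValueError("insert emissions must sum to 1")
        for row in self.transitions:
            if abs(row.sum() + (self.tau if self.model_end else 0.0) - 1.0) > 1e-9:
                raise ValueError("each state's outgoing transitions must sum to 1")

    @property
    def transitions(self) -> np.ndarray:
        """(3, 3) transition matrix over states (M, Ix, Iy)."""
        d, e = self.delta, self.epsilon
        leave = self.tau if self.model_end else 0.0
        return np.array(
            [
                [1.0 - 2 * d - leave, d, d],
                [1.0 - e - leave, e, 0.0],
                [1.0 - e - leave, 0.0, e],
            ]
        )

    @property
    def start(self) -> np.ndarray:
        d = self.delta
        return np.array([1.0 - 2 * d, d, d])


# classic BLOSUM62 amino-acid background frequencies, in AA_ORDER
_BLOSUM62_BACKGROUND = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}


def default_hmm_params(delta: float = 0.02, epsilon: float = 0.4) -> PairHMMParams:
    """Pair-HMM parameters derived from BLOSUM62.

    The joint match emissions invert the half-bit log-odds scores against
    the published BLOSUM62 background frequencies, p_ij ∝ q_i q_j
    2^(s_ij / 2), renormalised to a proper distribution.  'X' is treated
    as an average residue via the background marginal.
    """
    arr = substitution_matrices.load("BLOSUM62")
    aas = AA_ORDER[:-1]  # 20 standard residues
    S = np.array([[arr[a, b] for b in aas] for a in aas], dtype=float)
    q = np.array([_BLOSUM62_BACKGROUND[a] for a in aas])
    q = q / q.sum()
    p = np.outer(q, q) * np.exp2(S / 2.0)
    p /= p.sum()
    q = p.sum(axis=1)  # marginal background implied by the joint
    na = len(AA_ORDER)
    match = np.zeros((na, na))
    match[:20, :20] = p
    # X behaves as an unobserved average residue
    match[20, :20] = q * q.sum() / 20
    match[:20, 20] = match[20, :20]
    match[20, 20] = (q @ q) / 20
    match /= match.sum()
    insert = match.sum(axis=1)
    insert /= insert.sum()
    return PairHMMParams(match, insert, delta=delta, epsilon=epsilon)


def _hmm_tables(s1: str, s2: str, params: PairHMMParams):
    a = encode_residues(s1)
    b = encode_residues(s2)
    pm = params.match_emit[np.ix_(a, b)]  # (n, m)
    px = params.insert_emit[a]
    py = params.insert_emit[b]
    return a, b, pm, px, py


def pair_posterior(s1: str, s2: str, params: PairHMMParams) -> np.ndarray:
    """Posterior P(x_i ~ y_j) for every residue pair, via forward–backward.

    Row-rescaled probability-space recursions keep the computation exact
    to machine precision without underflow; the result is an
    ``(len(s1), len(s2))`` array with each row summing to at most 1.
    """
    a, b, pm, px, py = _hmm_tables(s1, s2, params)
    n, m = len(a), len(b)
    t = params.transitions
    pi = params.start
    end = np.full(3, params.tau) if params.model_end else np.ones(3)

    # ---- forward, scaled per row ----
    FM = np.zeros((n + 1, m + 1))
    FX = np.zeros((n + 1, m + 1))
    FY = np.zeros((n + 1, m + 1))
    logscale_f = np.zeros(n + 1)

    # row 0: only Iy chains are possible
    for j in range(1, m + 1):
        src = pi[2] if j == 1 else FY[0, j - 1] * t[2, 2]
        FY[0, j] = py[j - 1] * src
    c0 = max(FM[0].max(), FX[0].max(), FY[0].max(), 1.0)
    # keep the virtual start mass at (0,0): represent it explicitly
    start_mass = 1.0  # path yet to emit anything

    for i in range(1, n + 1):
        prevM, prevX, prevY = FM[i - 1], FX[i - 1], FY[i - 1]
        curM, curX, curY = FM[i], FX[i], FY[i]
        # match state (needs diagonal predecessor)
        diag = prevM[:-1] * t[0, 0] + prevX[:-1] * t[1, 0] + prevY[:-1] * t[2, 0]
        curM[1:] = pm[i - 1] * diag
        if i == 1:
            curM[1] += pm[0, 0] * pi[0] * _row_scale_product(logscale_f, 0)
        # Ix state (vertical)
        up = prevM[1:] * t[0, 1] + prevX[1:] * t[1, 1]
        curX[1:] = px[i - 1] * up
        if i == 1:
            curX[0] = px[0] * pi[1] * _row_scale_product(logscale_f, 0)
        else:
            curX[0] = px[i - 1] * prevX[0] * t[1, 1]
        # Iy state (horizontal, sequential)
        for j in range(1, m + 1):
            curY[j] = py[j - 1] * (
                curM[j - 1] * t[0, 2] + curY[j - 1] * t[2, 2]
            )
        c = max(curM.max(), curX.max(), curY.max())
        if c <= 0:
            c = 1.0
        curM /= c
        curX /= c
        curY /= c
        logscale_f[i] = logscale_f[i - 1] + np.log(c)

    log_total = (
        np.log(FM[n, m] * end[0] + FX[n, m] * end[1] + FY[n, m] * end[2])
        + logscale_f[n]
        if n > 0
        else np.log(FY[0, m] * end[2])
    )

    # ---- backward, scaled per row ----
    BM = np.zeros((n + 1, m + 1))
    BX = np.zeros((n + 1, m + 1))
    BY = np.zeros((n + 1, m + 1))
    logscale_b = np.zeros(n + 2)
    BM[n, m], BX[n, m], BY[n, m] = end
    for j in range(m - 1, -1, -1):
        BM[n, j] = t[0, 2] * py[j] * BY[n, j + 1]
        BX[n, j] = 0.0
        BY[n, j] = t[2, 2] * py[j] * BY[n, j + 1]
    for i in range(n - 1, -1, -1):
        nxtM, nxtX = BM[i + 1], BX[i + 1]
        curM, curX, curY = BM[i], BX[i], BY[i]
        # vectorisable pieces: transitions into M (diagonal) and Ix (down)
        diagM = pm[i][:] * nxtM[1:]  # em(i+1, j+1) * B_M[i+1][j+1]
        downX = px[i] * nxtX[:]  # em_x(i+1) * B_Ix[i+1][j]
        curX[:] = t[1, 0] * np.append(diagM, 0.0) + t[1, 1] * downX
        curX[m] = t[1, 1] * downX[m]
        for j in range(m - 1, -1, -1):
            right_y = py[j] * curY[j + 1]
            curM[j] = t[0, 0] * diagM[j] + t[0, 1] * downX[j] + t[0, 2] * right_y
            curY[j] = t[2, 0] * diagM[j] + t[2, 2] * right_y
        curM[m] = t[0, 1] * downX[m]
        c = max(curM.max(), curX.max(), curY.max())
        if c <= 0:
            c = 1.0
        curM /= c
        curX /= c
        curY /= c
        logscale_b[i] = logscale_b[i + 1] + np.log(c)

    post = np.zeros((n, m))
    with np.errstate(divide="ignore"):
        for i in range(1, n + 1):
            fm = FM[i, 1:]
            bm = BM[i, 1:]
            mask = (fm > 0) & (bm > 0)
            if not mask.any():
                continue
            logp = (
                np.log(np.where(mask, fm, 1.0))
                + np.log(np.where(mask, bm, 1.0))
                + logscale_f[i]
                + logscale_b[i]
                - log_total
            )
            post[i - 1] = np.where(mask, np.exp(logp), 0.0)
    return np.clip(post, 0.0, 1.0)


def _row_scale_product(logscale: np.ndarray, i: int) -> float:
    # forward rows are stored at scale exp(-logscale[i]); injecting fresh
    # start mass into row i must be divided by the accumulated scale
    return float(np.exp(-logscale[i]))


def mea_alignment_value(posterior: np.ndarray) -> float:
    """Maximum over monotone alignments of the summed posterior mass."""
    n, m = posterior.shape
    A = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        prev = A[i - 1]
        cur = A[i]
        p = posterior[i - 1]
        for j in range(1, m + 1):
            cur[j] = max(prev[j - 1] + p[j - 1], prev[j], cur[j - 1])
    return float(A[n, m])


def score_proba(
    s1: str, s2: str, params: PairHMMParams, posterior: np.ndarray | None = None
) -> float:
    """PROBA similarity: 100 × MEA(posterior) / min(len)."""
    if posterior is None:
        posterior = pair_posterior(s1, s2, params)
    val = mea_alignment_value(posterior)
    return float(np.clip(100.0 * val / min(len(s1), len(s2)), 0.0, 100.0))


# ---------------------------------------------------------------------------
# the triangular similarity matrix

class SimilarityMatrix:
    """Triangular pairwise similarity table on the 0–100 scale."""

    def __init__(self, ids: list[str], method: str, entries: Mapping[tuple[str, str], float]):
        if method not in METHODS:
            raise ValueError(f"unknown method tag {method!r}")
        self.ids = list(ids)
        self.method = method
        self._entries: dict[tuple[str, str], float] = {}
        for (i, j), v in entries.items():
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"similarity {v} for pair ({i},{j}) outside [0,100]")
            self._entries[self._key(i, j)] = float(v)
        expected = {self._key(i, j) for i in ids for j in ids if i < j}
        if set(self._entries) != expected:
            raise ValueError("entries do not cover exactly all unordered pairs")

    @staticmethod
    def _key(i: str, j: str) -> tuple[str, str]:
        if i == j:
            raise KeyError("diagonal similarity is not stored")
        return (i, j) if i < j else (j, i)

    @property
    def n(self) -> int:
        return len(self.ids)

    def get(self, i: str, j: str) -> float:
        return self._entries[self._key(i, j)]

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for (i, j), v in sorted(self._entries.items()):
            yield i, j, v

    def to_distance(self, i: str, j: str) -> float:
        """d = (100 − M) / 100, clamped to [0, 1]."""
        return float(np.clip((100.0 - self.get(i, j)) / 100.0, 0.0, 1.0))


def build_similarity_matrix(
    seqs: list[Sequence],
    method: str,
    *,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    k: int | None = None,
    hmm_params: PairHMMParams | None = None,
    posterior_cache: dict | None = None,
) -> SimilarityMatrix:
    """Score all n(n−1)/2 sequence pairs with the chosen technique.

    ``posterior_cache`` (a dict keyed by sorted id pairs) lets the PROBA
    method and the consistency stage share pair-HMM posteriors instead of
    recomputing them.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if method in ("F",) and matrix is None:
        matrix = SubstitutionMatrix.load("BLOSUM62")
    if method == "P" and hmm_params is None:
        hmm_params = default_hmm_params()
    if k is None:
        k = 1 if method == "Q" else 3

    entries: dict[tuple[str, str], float] = {}
    for idx1 in range(len(seqs)):
        for idx2 in range(idx1 + 1, len(seqs)):
            s1, s2 = seqs[idx1], seqs[idx2]
            try:
                if method == "F":
                    v = score_full(s1.residues, s2.residues, matrix, gap_open, gap_extend)
                elif method == "Q":
                    v = score_quick(s1.residues, s2.residues, k)
                elif method == "L":
                    v = score_lcs(s1.residues, s2.residues)
                elif method == "K":
                    v = score_kmers(s1.residues, s2.residues, k)
                else:
                    post = None
                    if posterior_cache is not None:
                        key = tuple(sorted((s1.id, s2.id)))
                        post = posterior_cache.get(key)
                        if post is not None and key != (s1.id, s2.id):
                            post = post.T
                    if post is None:
                        post = pair_posterior(s1.residues, s2.residues, hmm_params)
                        if posterior_cache is not None:
                            key = tuple(sorted((s1.id, s2.id)))
                            posterior_cache[key] = (
                                post if key == (s1.id, s2.id) else post.T
                            )
                    v = score_proba(s1.residues, s2.residues, hmm_params, post)
            except Exception as exc:
                raise RuntimeError(
                    f"similarity {method} failed for pair ({s1.id}, {s2.id}): {exc}"
                ) from exc
            entries[(s1.id, s2.id)] = v
    return SimilarityMatrix([s.id for s in seqs], method, entries)
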