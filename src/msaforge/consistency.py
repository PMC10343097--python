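"""Stage 3 — constraint libraries and the triplet consistency transformation.

The constraint library stores, for every unordered sequence pair, sparse
weighted evidence that residue x of one sequence should sit in the same
column as residue y of the other.  The primary library is filled either
from pair-HMM match posteriors (the default) or from the residue pairs
matched by pairwise global alignments, T-COFFEE style.  The consistency
transformation then reinforces each entry with indirect evidence routed
through every third sequence:

    W'(i_x, j_y) = W(i_x, j_y) + Σ_z Σ_k min(W(i_x, z_k), W(z_k, j_y))

Reinforced entries act as anchor points: Stage 4 adds their (rescaled)
weights to the profile match scores, steering the dynamic program toward
transitively consistent columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_core import GAP, Sequence, SubstitutionMatrix
from .similarity import PairHMMParams, default_hmm_params, global_affine_align, \
    alignment_identity_percent, pair_posterior

PairKey = tuple[str, str]


class ConstraintLibrary:
    """Sparse residue-pair weights per unordered sequence pair.

    Entries are stored once per pair under the lexicographically sorted
    id key; lookups with the ids swapped transparently transpose the
    position indices.  Positions are 0-based residue ordinals (gaps are
    never stored).
    """

    def __init__(self, seq_ids: list[str]):
        if len(set(seq_ids)) != len(seq_ids):
            raise ValueError("duplicate sequence ids")
        self.seq_ids = list(seq_ids)
        self._data: dict[PairKey, dict[tuple[int, int], float]] = {}
        self.extended = False

    @staticmethod
    def _key(i: str, j: str) -> tuple[PairKey, bool]:
        if i == j:
            raise KeyError("self-pairs are not stored")
        return ((i, j), False) if i < j else ((j, i), True)

    def set_weight(self, i: str, j: str, x: int, y: int, w: float) -> None:
        if w < 0:
            raise ValueError("constraint weights must be non-negative")
        key, swapped = self._key(i, j)
        if swapped:
            x, y = y, x
        self._data.setdefault(key, {})[(x, y)] = float(w)

    def get_weight(self, i: str, j: str, x: int, y: int) -> float:
        key, swapped = self._key(i, j)
        if swapped:
            x, y = y, x
        return self._data.get(key, {}).get((x, y), 0.0)

    def pair_entries(self, i: str, j: str) -> dict[tuple[int, int], float]:
        """Entries for the pair with positions oriented as (pos_in_i, pos_in_j)."""
        key, swapped = self._key(i, j)
        entries = self._data.get(key, {})
        if swapped:
            return {(y, x): w for (x, y), w in entries.items()}
        return dict(entries)

    @property
    def max_weight(self) -> float:
        vals = [w for d in self._data.values() for w in d.values()]
        return max(vals) if vals else 0.0

    def n_entries(self) -> int:
        return sum(len(d) for d in self._data.values())


def build_primary_library(
    seqs: list[Sequence],
    mode: str = "posterior",
    *,
    hmm_params: PairHMMParams | None = None,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    epsilon: float = 0.01,
    posterior_cache: dict | None = None,
) -> ConstraintLibrary:
    """Fill the primary library from pairwise information.

    ``posterior`` mode weights residue pairs by their pair-HMM match
    posterior, dropping entries below ``epsilon`` to keep the library
    sparse.  ``alignment`` mode assigns the pairwise alignment's identity
    percentage to every residue pair matched by the optimal global
    alignment (T-COFFEE's sequence-weighting scheme).
    """
    if mode not in ("posterior", "alignment"):
        raise ValueError(f"unknown library mode {mode!r}")
    lib = ConstraintLibrary([s.id for s in seqs])
    if mode == "posterior" and hmm_params is None:
        hmm_params = default_hmm_params()
    if mode == "alignment" and matrix is None:
        matrix = SubstitutionMatrix.load("BLOSUM62")

    for a in range(len(seqs)):
        for b in range(a + 1, len(seqs)):
            s1, s2 = seqs[a], seqs[b]
            if mode == "posterior":
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
                        posterior_cache[key] = post if key == (s1.id, s2.id) else post.T
                xs, ys = np.nonzero(post >= epsilon)
                for x, y in zip(xs.tolist(), ys.tolist()):
                    lib.set_weight(s1.id, s2.id, x, y, float(post[x, y]))
            else:
                _, r1, r2 = global_affine_align(
                    s1.residues, s2.residues, matrix, gap_open, gap_extend
                )
                ident = alignment_identity_percent(r1, r2)
                x = y = 0
                for c1, c2 in zip(r1, r2):
                    if c1 != GAP and c2 != GAP:
                        lib.set_weight(s1.id, s2.id, x, y, ident)
                    if c1 != GAP:
                        x += 1
                    if c2 != GAP:
                        y += 1
    return lib


def consistency_transform(lib: ConstraintLibrary) -> ConstraintLibrary:
    """One round of T-COFFEE triplet extension over all sequence pairs."""
    out = ConstraintLibrary(lib.seq_ids)
    ids = lib.seq_ids
    # pre-index each pair's entries by the position in each member
    by_pos: dict[tuple[str, str], dict[int, dict[int, float]]] = {}
    for a in range(len(ids)):
        for b in range(len(ids)):
            if a == b:
                continue
            entries = lib.pair_entries(ids[a], ids[b])
            idx: dict[int, dict[int, float]] = {}
            for (x, y), w in entries.items():
                idx.setdefault(x, {})[y] = w
            by_pos[(ids[a], ids[b])] = idx

    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            i, j = ids[a], ids[b]
            extended: dict[tuple[int, int], float] = dict(lib.pair_entries(i, j))
            for z in ids:
                if z in (i, j):
                    continue
                zi = by_pos[(z, i)]  # z position -> {i position: w}
                zj = by_pos[(z, j)]
                for k, xi_map in zi.items():
                    yj_map = zj.get(k)
                    if not yj_map:
                        continue
                    for x, w1 in xi_map.items():
                        for y, w2 in yj_map.items():
                            key = (x, y)
                            extended[key] = extended.get(key, 0.0) + min(w1, w2)
            for (x, y), w in extended.items():
                out.set_weight(i, j, x, y, w)
    out.extended = True
    return out


def library_bonus(
    lib: ConstraintLibrary,
    pair: tuple[str, str],
    positions: tuple[int, int],
    scale: float = 1.0,
) -> float:
    """Scaled library weight for one residue pair; 0 when absent."""
    i, j = pair
    x, y = positions
    return scale * lib.get_weight(i, j, x, y)


def bonus_scale(lib: ConstraintLibrary, matrix: SubstitutionMatrix) -> float:
    """Scale λ mapping the maximum library weight onto the maximum
    substitution score, so bonuses stay commensurate with gap penalties."""
    w = lib.max_weight
    if w <= 0:
        return 0.0
    return matrix.max_score / w


def dump_library(lib: ConstraintLibrary, path) -> None:
    """Write the library as TSV: seq_i, pos_i, seq_j, pos_j, weight (0-based)."""
    with open(path, "w") as fh:
        fh.write("seq_i\tpos_i\tseq_j\tpos_j\tweight\n")
        for a in range(len(lib.seq_ids)):
            for b in range(a + 1, len(lib.seq_ids)):
                i, j = lib.seq_ids[a], lib.seq_ids[b]
                for (x, y), w in sorted(lib.pair_entries(i, j).items()):
                    fh.write(f"{i}\t{x}\t{j}\t{y}\t{w:.10g}\n")


def load_library(path, seq_ids: list[str], extended: bool = False) -> ConstraintLibrary:
    lib = ConstraintLibrary(seq_ids)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("seq_i"):
            raise ValueError("missing library TSV header")
        for line in fh:
            i, x, j, y, w = line.rstrip("\n").split("\t")
            lib.set_weight(i, j, int(x), int(y), float(w))
    lib.extended = extended
    return lib
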