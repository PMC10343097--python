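"""Stage 4 — progressive profile–profile alignment along the guide tree.

A *profile* is a set of already-aligned rows treated as one alignable
object: per-column weighted residue frequencies, gap fractions, and the
member sequence weights derived from the guide tree (each leaf's weight
is the sum over its root path of branch length divided by the number of
leaves sharing that branch, normalised to mean one — the classic
tree-based weighting that down-weights redundant subfamilies).

Two profiles are aligned by a global affine-gap dynamic program over
column pairs.  The match score of columns (c1, c2) is the weighted
average substitution score over member residue pairs; when a constraint
library is supplied, its (rescaled) residue-pair weights are averaged
into the same cell, which is how consistency evidence steers the
alignment.  Gap-open penalties are position specific: they drop inside
and near existing gap columns so that new gaps coalesce with old ones,
and terminal gaps can be exempted from the opening charge.  Previously
aligned columns are never torn apart — gaps enter a profile only as
whole columns ("once a gap, always a gap").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .consistency import ConstraintLibrary, bonus_scale
from .guidetree import GuideTree, TreeNode
from .seq_core import (
    AA_ORDER,
    GAP,
    GAP_CODE,
    Alignment,
    Sequence,
    SubstitutionMatrix,
)
from .similarity import SimilarityMatrix

_NEG = -1e30


@dataclass
class GapModel:
    """Affine gap parameters with position-specific opening rules.

    A fresh gap of length g costs ``gap_open × m + g × gap_extend`` where
    m is the opening multiplier at the insertion point.  With
    ``position_specific`` on, m = ``gap_column_factor`` scaled by the
    residue fraction at columns that already contain gaps, relaxing back
    to 1 over ``proximity_window`` columns; with ``terminal_free`` on,
    leading and trailing gaps pay no opening charge.
    """

    gap_open: float = 10.0
    gap_extend: float = 0.2
    position_specific: bool = True
    terminal_free: bool = True
    gap_column_factor: float = 0.3
    proximity_window: int = 4

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if not (0 < self.gap_column_factor <= 1):
            raise ValueError("gap_column_factor must be in (0, 1]")


class Profile:
    """One or more aligned rows with member weights and column statistics."""

    def __init__(self, ids: list[str], rows: list[str], weights: Mapping[str, float]):
        if len(ids) != len(rows) or not ids:
            raise ValueError("ids/rows mismatch or empty profile")
        if len({len(r) for r in rows}) != 1:
            raise ValueError("profile rows must have equal length")
        self.ids = list(ids)
        self.rows = [str(r) for r in rows]
        self.weights = {}
        for i in ids:
            w = float(weights.get(i, 1.0))
            if not np.isfinite(w) or w <= 0:
                raise ValueError(f"weight for {i!r} must be finite and > 0")
            self.weights[i] = w
        table = {a: k for k, a in enumerate(AA_ORDER)}
        table[GAP] = GAP_CODE
        self.encoded = np.array(
            [[table[c] for c in r] for r in self.rows], dtype=np.int8
        )

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[i] for i in self.ids])

    def column_freq(self) -> np.ndarray:
        """(L, 22) weighted symbol counts per column (last slot = gap)."""
        L = self.length
        freq = np.zeros((L, GAP_CODE + 1))
        w = self.weight_vector
        for r in range(self.n):
            freq[np.arange(L), self.encoded[r]] += w[r]
        return freq

    def gap_fraction(self) -> np.ndarray:
        return (self.encoded == GAP_CODE).mean(axis=0)

    def residue_columns(self, seq_id: str) -> np.ndarray:
        """Column index of each residue ordinal for one member row."""
        row = self.rows[self.ids.index(seq_id)]
        return np.array([c for c, ch in enumerate(row) if ch != GAP], dtype=int)

    def to_alignment(self) -> Alignment:
        return Alignment(self.ids, self.rows)

    @classmethod
    def from_alignment(cls, aln: Alignment, weights: Mapping[str, float] | None = None) -> "Profile":
        return cls(aln.ids, aln.rows, weights or {})

    @classmethod
    def from_sequence(cls, seq: Sequence, weight: float = 1.0) -> "Profile":
        return cls([seq.id], [seq.residues], {seq.id: weight})


def compute_sequence_weights(tree: GuideTree) -> dict[str, float]:
    """Tree-based sequence weights, normalised to mean 1.

    Each leaf accumulates, along its path to the root, every branch
    length divided by the number of leaves below that branch, so shared
    branches are split among the sequences that share them.  Trees with
    all-zero branch lengths (e.g. identical sequences) yield unit
    weights.
    """
    leaves_below: dict[int, int] = {}
    for v in tree.root.postorder():
        leaves_below[id(v)] = (
            1 if v.is_leaf else sum(leaves_below[id(c)] for c in v.children)
        )
    raw: dict[str, float] = {}

    def walk(v: TreeNode, acc: float) -> None:
        here = acc + (v.length / leaves_below[id(v)] if v is not tree.root else 0.0)
        if v.is_leaf:
            raw[v.name] = here
        for c in v.children:
            walk(c, here)

    walk(tree.root, 0.0)
    total = sum(raw.values())
    if total <= 0:
        return {name: 1.0 for name in raw}
    mean = total / len(raw)
    return {name: w / mean for name, w in raw.items()}


def _open_multipliers(profile: Profile, gm: GapModel) -> np.ndarray:
    """Opening multiplier at each of the L+1 insertion points."""
    L = profile.length
    mult = np.ones(L + 1)
    if not gm.position_specific:
        return mult
    gfrac = profile.gap_fraction()
    gap_cols = np.nonzero(gfrac > 0)[0]
    if gap_cols.size == 0:
        return mult
    base = np.maximum(gm.gap_column_factor * (1.0 - gfrac[gap_cols]), 0.05)
    w = gm.proximity_window
    for j in range(L + 1):
        # distance from insertion point j to each gap column's near edge
        dist = np.where(gap_cols >= j, gap_cols - j, j - gap_cols - 1)
        near = dist <= w
        if near.any():
            relaxed = base[near] + (1.0 - base[near]) * dist[near] / (w + 1)
            mult[j] = relaxed.min()
    return mult


def _bonus_matrix(
    p1: Profile,
    p2: Profile,
    lib: ConstraintLibrary,
    scale: float,
) -> np.ndarray:
    """Average library bonus per column pair, over member sequence pairs."""
    B = np.zeros((p1.length, p2.length))
    if scale == 0.0:
        return B
    cols1 = {i: p1.residue_columns(i) for i in p1.ids}
    cols2 = {j: p2.residue_columns(j) for j in p2.ids}
    for i in p1.ids:
        ci = cols1[i]
        for j in p2.ids:
            cj = cols2[j]
            for (x, y), w in lib.pair_entries(i, j).items():
                if x < len(ci) and y < len(cj):
                    B[ci[x], cj[y]] += w
    return B * (scale / (p1.n * p2.n))


def align_profiles(
    p1: Profile,
    p2: Profile,
    matrix: SubstitutionMatrix,
    gap_model: GapModel | None = None,
    lib: ConstraintLibrary | None = None,
    lib_scale: float | str = "auto",
) -> Profile:
    """Globally align two profiles; returns the merged profile.

    ``lib_scale`` is the λ multiplier applied to library weights before
    they are added to match scores; "auto" rescales the maximum library
    weight to the maximum substitution score, 0 disables the bonus
    entirely (degenerating consistency strategies to plain progressive).
    """
    if set(p1.ids) & set(p2.ids):
        raise ValueError("profiles share member sequences")
    gm = gap_model or GapModel()
    L1, L2 = p1.length, p2.length

    S = matrix.padded()[: GAP_CODE + 1, : GAP_CODE + 1]
    F1 = p1.column_freq()
    F2 = p2.column_freq()
    denom = F1.sum(axis=1)[:, None] * F2.sum(axis=1)[None, :]
    match = (F1 @ S @ F2.T) / denom
    if lib is not None:
        scale = bonus_scale(lib, matrix) if lib_scale == "auto" else float(lib_scale)
        match = match + _bonus_matrix(p1, p2, lib, scale)

    m1 = _open_multipliers(p1, gm)
    m2 = _open_multipliers(p2, gm)
    go1 = gm.gap_open * m1  # opening a gap *in p1* at insertion point i
    go2 = gm.gap_open * m2
    if gm.terminal_free:
        go1 = go1.copy()
        go2 = go2.copy()
        go1[0] = go1[L1] = 0.0
        go2[0] = go2[L2] = 0.0
    ge = gm.gap_extend

    M = np.full((L1 + 1, L2 + 1), _NEG)
    Ix = np.full((L1 + 1, L2 + 1), _NEG)  # gap column in p2, consuming p1
    Iy = np.full((L1 + 1, L2 + 1), _NEG)
    # pointer codes: 0 = from M, 1 = from Ix, 2 = from Iy
    ptrM = np.zeros((L1 + 1, L2 + 1), dtype=np.uint8)
    ptrX = np.zeros((L1 + 1, L2 + 1), dtype=np.uint8)
    ptrY = np.zeros((L1 + 1, L2 + 1), dtype=np.uint8)

    M[0, 0] = 0.0
    for i in range(1, L1 + 1):
        Ix[i, 0] = -(go2[0] + i * ge)
        ptrX[i, 0] = 0 if i == 1 else 1
    for j in range(1, L2 + 1):
        Iy[0, j] = -(go1[0] + j * ge)
        ptrY[0, j] = 0 if j == 1 else 2

    for i in range(1, L1 + 1):
        Mp, Xp, Yp = M[i - 1], Ix[i - 1], Iy[i - 1]
        Mi, Xi, Yi = M[i], Ix[i], Iy[i]
        mrow = match[i - 1]
        for j in range(1, L2 + 1):
            # match state: consume column i of p1 and j of p2
            best, ptr = Mp[j - 1], 0
            if Xp[j - 1] > best:
                best, ptr = Xp[j - 1], 1
            if Yp[j - 1] > best:
                best, ptr = Yp[j - 1], 2
            Mi[j] = mrow[j - 1] + best
            ptrM[i, j] = ptr
            # gap in p2 (vertical): opening charged at p2 insertion point j
            open_cost = go2[j] + ge
            best, ptr = Mp[j] - open_cost, 0
            cand = Xp[j] - ge
            if cand > best + 1e-15:
                best, ptr = cand, 1
            cand = Yp[j] - open_cost
            if cand > best:
                best, ptr = cand, 2
            Xi[j] = best
            ptrX[i, j] = ptr
            # gap in p1 (horizontal)
            open_cost = go1[i] + ge
            best, ptr = Mi[j - 1] - open_cost, 0
            cand = Xi[j - 1] - open_cost
            if cand > best:
                best, ptr = cand, 1
            cand = Yi[j - 1] - ge
            if cand > best + 1e-15:
                best, ptr = cand, 2
            Yi[j] = best
            ptrY[i, j] = ptr

    ends = (M[L1, L2], Ix[L1, L2], Iy[L1, L2])
    state = int(np.argmax(ends))
    if ends[0] >= ends[state]:
        state = 0  # prefer ending in a match column on ties

    # traceback into a column path
    path: list[tuple[int | None, int | None]] = []
    i, j = L1, L2
    while i > 0 or j > 0:
        if state == 0:
            path.append((i - 1, j - 1))
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            path.append((i - 1, None))
            state = int(ptrX[i, j])
            i -= 1
        else:
            path.append((None, j - 1))
            state = int(ptrY[i, j])
            j -= 1
    path.reverse()

    rows1 = []
    for r in p1.rows:
        rows1.append("".join(r[c1] if c1 is not None else GAP for c1, _ in path))
    rows2 = []
    for r in p2.rows:
        rows2.append("".join(r[c2] if c2 is not None else GAP for _, c2 in path))
    merged = Profile(
        p1.ids + p2.ids, rows1 + rows2, {**p1.weights, **p2.weights}
    )
    return merged


class MatrixChooser:
    """Fixed or similarity-adaptive substitution matrix selection.

    Adaptive mode ladders through the BLOSUM series by the mean Stage-1
    similarity of the cross-profile sequence pairs: ≥60 → BLOSUM80,
    ≥40 → BLOSUM62, ≥20 → BLOSUM50, else BLOSUM45 (the most permissive
    matrix of the distributed series).
    """

    _LADDER = ((60.0, "BLOSUM80"), (40.0, "BLOSUM62"), (20.0, "BLOSUM50"), (-1.0, "BLOSUM45"))

    def __init__(self, fixed: SubstitutionMatrix | None = None,
                 sim: SimilarityMatrix | None = None):
        if fixed is None and sim is None:
            fixed = SubstitutionMatrix.load("BLOSUM62")
        self.fixed = fixed
        self.sim = sim
        self._cache: dict[str, SubstitutionMatrix] = {}

    def choose(self, p1: Profile, p2: Profile) -> SubstitutionMatrix:
        if self.fixed is not None:
            return self.fixed
        vals = [self.sim.get(i, j) for i in p1.ids for j in p2.ids]
        mean = float(np.mean(vals))
        for threshold, name in self._LADDER:
            if mean >= threshold:
                if name not in self._cache:
                    self._cache[name] = SubstitutionMatrix.load(name)
                return self._cache[name]
        raise AssertionError("unreachable")


def progressive_align(
    seqs: list[Sequence],
    tree: GuideTree,
    matrix: SubstitutionMatrix | MatrixChooser,
    gap_model: GapModel | None = None,
    lib: ConstraintLibrary | None = None,
    lib_scale: float | str = "auto",
) -> Alignment:
    """Bottom-up progressive alignment along the guide tree.

    The tree is traversed post-order; each internal node merges its two
    children's profiles.  The result contains all sequences, de-gaps to
    the inputs, and is returned in input sequence order.
    """
    by_id = {s.id: s for s in seqs}
    if sorted(by_id) != sorted(tree.leaf_names()):
        raise ValueError("tree leaves do not match sequence ids")
    chooser = matrix if isinstance(matrix, MatrixChooser) else MatrixChooser(fixed=matrix)
    weights = compute_sequence_weights(tree)

    def build(v: TreeNode) -> Profile:
        if v.is_leaf:
            return Profile.from_sequence(by_id[v.name], weights[v.name])
        left = build(v.children[0])
        right = build(v.children[1])
        return align_profiles(
            left, right, chooser.choose(left, right), gap_model, lib, lib_scale
        )

    final = build(tree.root)
    aln = final.to_alignment()
    return aln.reorder([s.id for s in seqs])
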