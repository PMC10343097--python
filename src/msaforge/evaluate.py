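"""Alignment-quality metrics: Developer Score, identity, identity bands.

The Developer Score (DS) measures how much of a trusted reference
alignment a test alignment recovers: every pair of residues that share a
column in the reference — restricted to reference columns whose gap
fraction is below 20% — is checked for sharing a column in the test
alignment, and DS is the matched fraction, in [0, 1].

Identity summarises how similar an alignment's sequences are: for each
sequence pair, matched-residue columns divided by the columns that are
not gap–gap for that pair, averaged over all pairs and expressed as a
percentage.  Benchmark instances are conventionally banded by this
value: <20%, [20, 40), and [40, 80); anything ≥80% falls outside the
customary comparison bands and is tagged "high".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .seq_core import Alignment, GAP


@dataclass
class ScoreReport:
    """Per-instance, per-strategy metric record."""

    instance: str
    strategy: str
    developer_score: float
    identity: float
    wsp: float
    group: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.developer_score <= 1.0):
            raise ValueError("developer_score must be in [0, 1]")
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be in [0, 100]")


def _residue_pair_columns(aln: Alignment) -> dict[tuple[str, int], int]:
    """(sequence id, residue ordinal) → column index."""
    out: dict[tuple[str, int], int] = {}
    for sid, row in zip(aln.ids, aln.rows):
        ordinal = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                out[(sid, ordinal)] = c
                ordinal += 1
    return out


def developer_score(test: Alignment, ref: Alignment, gap_frac: float = 0.2) -> float:
    """Fraction of qualifying reference residue pairs recovered by ``test``.

    Reference columns qualify when their per-column gap fraction is
    strictly below ``gap_frac``.  Residues are identified by (sequence
    id, residue ordinal), so the score is invariant under row reordering
    and under all-gap columns in either alignment.
    """
    if sorted(test.ids) != sorted(ref.ids):
        raise ValueError("test and reference cover different sequence sets")
    for sid in ref.ids:
        if test.row(sid).replace(GAP, "") != ref.row(sid).replace(GAP, ""):
            raise ValueError(f"sequence {sid!r} differs between test and reference")

    test_cols = _residue_pair_columns(test)
    n = ref.n
    total = 0
    matched = 0
    # residue ordinals per reference row, tracked while scanning columns
    ordinals = {sid: 0 for sid in ref.ids}
    for c in range(ref.length):
        column = [(sid, ref.row(sid)[c]) for sid in ref.ids]
        gaps = sum(1 for _, ch in column if ch == GAP)
        residues = [
            (sid, ordinals[sid]) for sid, ch in column if ch != GAP
        ]
        for sid, ch in column:
            if ch != GAP:
                ordinals[sid] += 1
        if gaps / n >= gap_frac:
            continue
        for (s1, o1), (s2, o2) in combinations(residues, 2):
            total += 1
            if test_cols[(s1, o1)] == test_cols[(s2, o2)]:
                matched += 1
    if total == 0:
        raise ValueError("no qualifying residue pairs in the reference")
    return matched / total


def identity(aln: Alignment) -> float:
    """Mean pairwise identity of an alignment, in percent.

    For each sequence pair: matched residue columns divided by the
    alignment length minus that pair's gap-only columns.  Invariant
    under row reordering.
    """
    if aln.n < 2:
        raise ValueError("identity needs at least two sequences")
    L = aln.length
    total = 0.0
    for r1, r2 in combinations(aln.rows, 2):
        matches = 0
        gap_only = 0
        for x, y in zip(r1, r2):
            if x == GAP and y == GAP:
                gap_only += 1
            elif x == y and x != GAP:
                matches += 1
        denom = L - gap_only
        if denom == 0:
            raise ValueError("a sequence pair has only gap-gap columns")
        total += matches / denom
    n_pairs = aln.n * (aln.n - 1) // 2
    return 100.0 * total / n_pairs


BAND_HIGH = "high"


def identity_group(id_value: float) -> str:
    """Band tag for an identity value: band1 <20, band2 [20,40), band3 [40,80).

    Values of 80 or more fall outside the customary benchmark bands and
    are tagged ``"high"``; callers typically exclude them from banded
    comparisons.
    """
    if not (0.0 <= id_value <= 100.0):
        raise ValueError("identity must be in [0, 100]")
    if id_value < 20.0:
        return "band1"
    if id_value < 40.0:
        return "band2"
    if id_value < 80.0:
        return "band3"
    return BAND_HIGH
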