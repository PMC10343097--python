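"""Sequence and alignment data model with file I/O.

The framework works on protein sequences over the 20 standard amino-acid
letters plus ``X`` for anything unknown or non-standard.  Alignments are
rectangular blocks of rows over the same alphabet extended with the gap
symbol ``-``; readers normalise the ``.``/``~`` gap dialects of MSF and
friends to ``-`` so every downstream dynamic program sees one canonical
form.

File parsing is delegated to Biopython (``Bio.SeqIO`` / ``Bio.AlignIO``);
this module adds the invariants the rest of the framework relies on:
unique ids, alphabet checking, equal-length rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence as TSequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: canonical residue order used by every encoder in the package
AA_ORDER = "ACDEFGHIKLMNPQRSTVWYX"
AA_SET = frozenset(AA_ORDER)
GAP = "-"
#: integer code for the gap symbol in encoded alignments
GAP_CODE = len(AA_ORDER)

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


class SeqFormatError(ValueError):
    """Malformed input file (FASTA/Clustal/MSF syntax or ragged rows)."""


class AlphabetError(ValueError):
    """Residue outside the protein alphabet in strict mode."""


@dataclass(frozen=True)
class Sequence:
    """An unaligned protein sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residues")
        bad = set(self.residues) - AA_SET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r}: illegal residues {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _clean_residues(seq_id: str, raw: str, on_illegal: str) -> str:
    """Uppercase and sanitise residues; ``on_illegal`` is 'map' or 'strict'."""
    s = raw.upper()
    if GAP in s:
        raise AlphabetError(f"sequence {seq_id!r}: unaligned input must be gap-free")
    bad = set(s) - AA_SET
    if bad:
        if on_illegal == "strict":
            raise AlphabetError(
                f"sequence {seq_id!r}: illegal residues {sorted(bad)!r}"
            )
        warnings.warn(
            f"sequence {seq_id!r}: mapping non-standard residues {sorted(bad)!r} to 'X'",
            stacklevel=3,
        )
        s = "".join(c if c in AA_SET else "X" for c in s)
    return s


class Alignment:
    """A rectangular multiple alignment: ordered (id, aligned-row) pairs."""

    def __init__(self, ids: TSequence[str], rows: TSequence[str]):
        ids = list(ids)
        rows = [str(r) for r in rows]
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        if len(ids) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            ragged = [i for i, r in zip(ids, rows) if len(r) != len(rows[0])]
            raise SeqFormatError(f"ragged alignment rows for ids {ragged!r}")
        L = lengths.pop()
        if L < 1:
            raise ValueError("alignment length must be >= 1")
        for i, r in zip(ids, rows):
            bad = set(r) - AA_SET - {GAP}
            if bad:
                raise AlphabetError(f"row {i!r}: illegal symbols {sorted(bad)!r}")
        self.ids = ids
        self.rows = rows

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def degapped(self) -> list[Sequence]:
        """The member sequences with gaps stripped, in row order."""
        return [Sequence(i, r.replace(GAP, "")) for i, r in zip(self.ids, self.rows)]

    def reorder(self, id_order: TSequence[str]) -> "Alignment":
        if sorted(id_order) != sorted(self.ids):
            raise ValueError("reorder ids do not match alignment members")
        return Alignment(list(id_order), [self.row(i) for i in id_order])

    def encoded(self) -> np.ndarray:
        """(n, L) int8 matrix; residues per AA_ORDER, gap = GAP_CODE."""
        table = {**_AA_INDEX, GAP: GAP_CODE}
        return np.array(
            [[table[c] for c in row] for row in self.rows], dtype=np.int8
        )

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Alignment)
            and self.ids == other.ids
            and self.rows == other.rows
        )

    def __repr__(self) -> str:
        return f"Alignment(n={self.n}, L={self.length})"


class SubstitutionMatrix:
    """Symmetric residue substitution scores over the extended alphabet.

    Backed by a dense (21, 21) float array in ``AA_ORDER`` order.  'X'
    scores default to the source matrix's 'X' row when present, else 0.
    """

    def __init__(self, name: str, scores: np.ndarray):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(AA_ORDER), len(AA_ORDER)):
            raise ValueError("scores must be 21x21 over AA_ORDER")
        if not np.allclose(scores, scores.T):
            raise ValueError(f"matrix {name!r} is not symmetric")
        self.name = name
        self.scores = scores

    def score(self, a: str, b: str) -> float:
        return float(self.scores[_AA_INDEX[a], _AA_INDEX[b]])

    @property
    def max_score(self) -> float:
        return float(self.scores.max())

    def padded(self) -> np.ndarray:
        """(22, 22) array with an all-zero gap row/column appended."""
        out = np.zeros((len(AA_ORDER) + 1, len(AA_ORDER) + 1))
        out[: len(AA_ORDER), : len(AA_ORDER)] = self.scores
        return out

    @classmethod
    def _from_biopython(cls, name: str, arr) -> "SubstitutionMatrix":
        alpha = arr.alphabet
        scores = np.zeros((len(AA_ORDER), len(AA_ORDER)))
        for i, a in enumerate(AA_ORDER):
            for j, b in enumerate(AA_ORDER):
                aa = a if a in alpha else "X" if "X" in alpha else "*"
                bb = b if b in alpha else "X" if "X" in alpha else "*"
                try:
                    scores[i, j] = arr[aa, bb]
                except (KeyError, IndexError):
                    scores[i, j] = 0.0
        scores = (scores + scores.T) / 2.0
        return cls(name, scores)

    @classmethod
    def load(cls, name: str) -> "SubstitutionMatrix":
        """Load a bundled matrix by name, e.g. ``BLOSUM62``."""
        arr = substitution_matrices.load(name.upper())
        return cls._from_biopython(name.upper(), arr)

    @classmethod
    def read(cls, path: str | Path) -> "SubstitutionMatrix":
        """Read an NCBI-style matrix text file."""
        arr = substitution_matrices.read(str(path))
        return cls._from_biopython(Path(path).stem, arr)


def read_fasta(path: str | Path, on_illegal: str = "map") -> list[Sequence]:
    """Read unaligned FASTA records, preserving order, rejecting duplicates.

    ``on_illegal`` = 'map' (non-standard residues become 'X', with a
    warning) or 'strict' (raise :class:`AlphabetError`).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqFormatError(f"{path}: no records")
    out: list[Sequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SeqFormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise SeqFormatError(f"{path}: empty record {rec.id!r}")
        out.append(
            Sequence(rec.id, _clean_residues(rec.id, str(rec.seq), on_illegal),
                     rec.description)
        )
    return out


_DIALECTS = {"fasta": "fasta", "clustal": "clustal", "msf": "msf"}


def read_alignment(path: str | Path, dialect: str = "fasta",
                   on_illegal: str = "map") -> Alignment:
    """Read an aligned file; '.'/'~' gap dialects are normalised to '-'."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), _DIALECTS[dialect])
    except ValueError as exc:
        raise SeqFormatError(f"{path}: {exc}") from exc
    ids, rows = [], []
    for rec in msa:
        row = str(rec.seq).upper().replace(".", GAP).replace("~", GAP)
        if on_illegal == "map":
            row = "".join(c if (c in AA_SET or c == GAP) else "X" for c in row)
        ids.append(rec.id)
        rows.append(row)
    return Alignment(ids, rows)


def write_alignment(aln: Alignment, path: str | Path, dialect: str = "fasta") -> None:
    """Write an alignment; round-trips through :func:`read_alignment`."""
    if dialect not in ("fasta", "clustal"):
        raise ValueError(f"unsupported output dialect {dialect!r}")
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(r), id=i, description="") for i, r in zip(aln.ids, aln.rows)]
    )
    AlignIO.write(msa, str(path), dialect)


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description=s.description)
               for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def remove_allgap_columns(aln: Alignment) -> Alignment:
    """Drop every column that is gaps-only; error if nothing remains."""
    keep = [j for j in range(aln.length)
            if any(r[j] != GAP for r in aln.rows)]
    if not keep:
        raise ValueError("alignment consists solely of gap columns")
    rows = ["".join(r[j] for j in keep) for r in aln.rows]
    return Alignment(aln.ids, rows)


def encode_residues(residues: str) -> np.ndarray:
    """Encode an ungapped residue string to AA_ORDER indices."""
    return np.array([_AA_INDEX[c] for c in residues], dtype=np.int8)
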