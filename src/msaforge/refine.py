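"""Stage 5 — tree-restricted iterative refinement of an alignment.

The refinement loop cuts one guide-tree edge at a time, splitting the
alignment rows into the leaves below the edge and the rest.  Each side
has its all-gap columns removed, the two resulting profiles are realigned
with the Stage-4 engine (including the constraint library when the
strategy uses one), and the candidate replaces the current best
alignment only when its weighted sum-of-pairs (WSP) objective is
strictly higher.  Edges are visited from the deepest upward; a full
sweep over all edges is one iteration, and the process stops when a
sweep accepts nothing or the iteration cap is reached.

WSP sums, over columns and sequence pairs, the substitution score of the
two residues; pairs involving a gap contribute zero (the objective
carries no affine gap term).  Pair weights default to the product of the
tree-derived sequence weights, normalised to mean one; setting all
weights to one recovers the plain sum-of-pairs (SP) score.  Improving
WSP is not the same as improving benchmark accuracy — the harness
records both and never assumes one implies the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np

from .consistency import ConstraintLibrary
from .guidetree import GuideTree, TreeNode
from .profile_align import GapModel, Profile, align_profiles, compute_sequence_weights
from .seq_core import Alignment, GAP_CODE, SubstitutionMatrix, remove_allgap_columns


@dataclass
class RefinementConfig:
    """Knobs of the refinement loop."""

    max_iterations: int = 100
    objective: str = "wsp"  # "wsp" (tree weights) or "sp" (unit weights)

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.objective not in ("wsp", "sp"):
            raise ValueError(f"unknown objective {self.objective!r}")


def pair_weights(
    weights: Mapping[str, float], ids: list[str], normalise: bool = True
) -> dict[tuple[str, str], float]:
    """w_ij = weight_i × weight_j for i < j, optionally mean-normalised."""
    out = {
        (i, j): weights[i] * weights[j] for i, j in combinations(sorted(ids), 2)
    }
    if normalise and out:
        mean = sum(out.values()) / len(out)
        if mean > 0:
            out = {k: v / mean for k, v in out.items()}
    return out


def wsp(
    aln: Alignment,
    matrix: SubstitutionMatrix,
    weights: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Weighted sum-of-pairs score; gap pairs contribute zero."""
    enc = aln.encoded()
    S = matrix.padded()  # zero row/col for the gap code
    total = 0.0
    for a, b in combinations(range(aln.n), 2):
        i, j = aln.ids[a], aln.ids[b]
        w = 1.0
        if weights is not None:
            w = weights.get((i, j), weights.get((j, i), 1.0))
        if w == 0.0:
            continue
        total += w * S[enc[a], enc[b]].sum()
    return float(total)


def partition_by_edge(tree: GuideTree, edge: TreeNode) -> tuple[set[str], set[str]]:
    """Leaves below the edge vs everything else; the root is not an edge."""
    if edge is tree.root:
        raise ValueError("the root does not define an edge")
    nodes = list(tree.root.postorder())
    if not any(v is edge for v in nodes):
        raise ValueError("edge does not belong to this tree")
    below = set(edge.leaf_names())
    rest = set(tree.leaf_names()) - below
    if not below or not rest:
        raise ValueError("edge partition must leave both sides non-empty")
    return below, rest


def _edges_deepest_first(tree: GuideTree) -> list[TreeNode]:
    depth: dict[int, int] = {id(tree.root): 0}
    order: list[tuple[int, int, TreeNode]] = []

    def walk(v: TreeNode, d: int) -> None:
        for c in v.children:
            depth[id(c)] = d + 1
            walk(c, d + 1)

    walk(tree.root, 0)
    post = {id(v): k for k, v in enumerate(tree.root.postorder())}
    edges = tree.edges()
    return sorted(edges, key=lambda v: (-depth[id(v)], post[id(v)]))


def _sub_profile(aln: Alignment, ids: set[str], weights: Mapping[str, float]) -> Profile:
    keep_ids = [i for i in aln.ids if i in ids]
    rows = [aln.row(i) for i in keep_ids]
    # drop columns that are all-gap within this side
    cols = [
        c for c in range(aln.length) if any(r[c] != "-" for r in rows)
    ]
    rows = ["".join(r[c] for c in cols) for r in rows]
    return Profile(keep_ids, rows, {i: weights[i] for i in keep_ids})


def refine(
    aln: Alignment,
    tree: GuideTree,
    matrix: SubstitutionMatrix,
    gap_model: GapModel | None = None,
    lib: ConstraintLibrary | None = None,
    lib_scale: float | str = "auto",
    cfg: RefinementConfig | None = None,
) -> Alignment:
    """Iteratively refine ``aln``; never returns a lower-WSP alignment."""
    cfg = cfg or RefinementConfig()
    if sorted(aln.ids) != sorted(tree.leaf_names()):
        raise ValueError("alignment rows do not match tree leaves")
    seq_weights = compute_sequence_weights(tree)
    if cfg.objective == "sp":
        wts = None
    else:
        wts = pair_weights(seq_weights, aln.ids)

    best = remove_allgap_columns(aln)
    best_score = wsp(best, matrix, wts)
    edges = _edges_deepest_first(tree)

    for _ in range(cfg.max_iterations):
        improved = False
        for edge in edges:
            below, rest = partition_by_edge(tree, edge)
            p1 = _sub_profile(best, below, seq_weights)
            p2 = _sub_profile(best, rest, seq_weights)
            merged = align_profiles(p1, p2, matrix, gap_model, lib, lib_scale)
            candidate = merged.to_alignment().reorder(best.ids)
            candidate = remove_allgap_columns(candidate)
            score = wsp(candidate, matrix, wts)
            if score > best_score:
                best, best_score = candidate, score
                improved = True
        if not improved:
            break
    return best
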