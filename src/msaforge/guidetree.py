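"""Stage 2 — guide-tree construction from the similarity matrix.

Four agglomerative builders are provided.  ``build_upgma`` follows the
average-linkage scheme in which the score between a freshly merged
cluster and any other cluster is the plain average of the two scores it
replaces (i.e. WPGMA; a size-weighted flag gives the textbook UPGMA).
``build_slink`` implements the two single-linkage variants SLMIN and
SLMAX.  Note the naming is as conventionally printed for this framework
and is inverted relative to similarity intuition: SLMAX propagates the
*minimum* of the two removed scores, SLMIN the *maximum*.  ``build_nj``
is classic Neighbor-Joining on distances d = (100 − M)/100, rooted at
the midpoint of the final join for progressive use.

All builders are deterministic: among equally good candidate pairs the
one whose (lexicographically smallest member id, other id) pair sorts
first is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .similarity import SimilarityMatrix


@dataclass
class TreeNode:
    """A node of a rooted binary guide tree.

    ``length`` is the branch length to the parent (0 for the root);
    ``join_index`` records the agglomeration order of internal nodes.
    """

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0
    join_index: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaf_names(self) -> list[str]:
        return [v.name for v in self.postorder() if v.is_leaf]

    def __repr__(self) -> str:
        return f"TreeNode({self.name or '*'})"


class GuideTree:
    """Rooted binary tree over sequence ids, driving progressive order."""

    def __init__(self, root: TreeNode):
        leaves = [v for v in root.postorder() if v.is_leaf]
        internal = [v for v in root.postorder() if not v.is_leaf]
        names = [v.name for v in leaves]
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels")
        if any(n is None for n in names):
            raise ValueError("unlabeled leaf")
        for v in internal:
            if len(v.children) != 2:
                raise ValueError("guide tree must be strictly binary")
        if len(internal) != len(leaves) - 1:
            raise ValueError("leaf/internal count mismatch for a binary tree")
        self.root = root

    @property
    def n_leaves(self) -> int:
        return sum(1 for v in self.root.postorder() if v.is_leaf)

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def edges(self) -> list[TreeNode]:
        """Every non-root node; each identifies the edge to its parent."""
        return [v for v in self.root.postorder() if v is not self.root]

    def __repr__(self) -> str:
        return f"GuideTree(n={self.n_leaves})"


# ---------------------------------------------------------------------------
# shared agglomeration machinery

def _cluster_label(node: TreeNode) -> str:
    return min(node.leaf_names())


def _pick_best_pair(
    scores: dict[frozenset, float], labels: dict[int, str], nodes: dict[int, TreeNode]
) -> tuple[int, int]:
    """Highest-score pair; ties broken by the sorted label pair."""
    best = None
    for key, s in scores.items():
        ia, ib = sorted(key, key=lambda k: labels[k])
        cand = (-s, labels[ia], labels[ib], ia, ib)
        if best is None or cand < best:
            best = cand
    return best[3], best[4]


def _height_from_score(score: float) -> float:
    # ultrametric height on the distance scale d = (100 - M)/100, halved
    return (100.0 - score) / 200.0


def _agglomerate(sim: SimilarityMatrix, update: str, weighted: bool = False) -> GuideTree:
    if sim.n < 2:
        raise ValueError("need at least 2 sequences to build a tree")
    nodes: dict[int, TreeNode] = {}
    labels: dict[int, str] = {}
    heights: dict[int, float] = {}
    sizes: dict[int, int] = {}
    for idx, name in enumerate(sim.ids):
        nodes[idx] = TreeNode(name=name)
        labels[idx] = name
        heights[idx] = 0.0
        sizes[idx] = 1
    scores: dict[frozenset, float] = {}
    index_of = {name: i for i, name in enumerate(sim.ids)}
    for i, j, v in sim.pairs():
        scores[frozenset((index_of[i], index_of[j]))] = v

    next_id = len(sim.ids)
    join_index = 0
    active = set(nodes)
    while len(active) > 1:
        ia, ib = _pick_best_pair(scores, labels, nodes)
        s = scores.pop(frozenset((ia, ib)))
        a, b = nodes[ia], nodes[ib]
        h = max(_height_from_score(s), heights[ia], heights[ib])
        a.length = h - heights[ia]
        b.length = h - heights[ib]
        parent = TreeNode(children=[a, b], join_index=join_index)
        join_index += 1
        nodes[next_id] = parent
        labels[next_id] = min(labels[ia], labels[ib])
        heights[next_id] = h
        sizes[next_id] = sizes[ia] + sizes[ib]
        active -= {ia, ib}
        for k in active:
            sa = scores.pop(frozenset((ia, k)))
            sb = scores.pop(frozenset((ib, k)))
            if update == "average":
                if weighted:
                    new = (sa * sizes[ia] + sb * sizes[ib]) / (sizes[ia] + sizes[ib])
                else:
                    new = (sa + sb) / 2.0
            elif update == "min":
                new = min(sa, sb)
            else:
                new = max(sa, sb)
            scores[frozenset((next_id, k))] = new
        active.add(next_id)
        next_id += 1
    return GuideTree(nodes[next_id - 1])


def build_upgma(sim: SimilarityMatrix, weighted: bool = False) -> GuideTree:
    """Average-linkage agglomeration on similarities (WPGMA by default)."""
    return _agglomerate(sim, "average", weighted=weighted)


def build_slink(sim: SimilarityMatrix, variant: str) -> GuideTree:
    """Single-linkage variants: SLMAX propagates min scores, SLMIN max."""
    if variant == "SLMAX":
        return _agglomerate(sim, "min")
    if variant == "SLMIN":
        return _agglomerate(sim, "max")
    raise ValueError(f"unknown single-linkage variant {variant!r}")


# ---------------------------------------------------------------------------
# Neighbor-Joining

def build_nj(sim: SimilarityMatrix) -> GuideTree:
    """Classic NJ (Q-criterion) on d = (100 − M)/100, midpoint-rooted.

    Negative limb lengths are clamped to zero.  For n = 2 the two leaves
    are joined directly.
    """
    ids = list(sim.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    nodes: dict[int, TreeNode] = {i: TreeNode(name=name) for i, name in enumerate(ids)}
    labels: dict[int, str] = {i: name for i, name in enumerate(ids)}
    dist: dict[frozenset, float] = {}
    for a in range(n):
        for b in range(a + 1, n):
            dist[frozenset((a, b))] = sim.to_distance(ids[a], ids[b])

    active = set(range(n))
    next_id = n
    join_index = 0
    while len(active) > 2:
        r = {
            i: sum(dist[frozenset((i, k))] for k in active if k != i)
            for i in active
        }
        m = len(active)
        best = None
        for key, d in dist.items():
            i, j = key
            if i not in active or j not in active:
                continue
            q = (m - 2) * d - r[i] - r[j]
            ia, ib = sorted((i, j), key=lambda k: labels[k])
            cand = (q, labels[ia], labels[ib], ia, ib)
            if best is None or cand < best:
                best = cand
        _, _, _, ia, ib = best
        d_ab = dist[frozenset((ia, ib))]
        la = 0.5 * d_ab + (r[ia] - r[ib]) / (2.0 * (m - 2))
        lb = d_ab - la
        a, b = nodes[ia], nodes[ib]
        a.length = max(la, 0.0)
        b.length = max(lb, 0.0)
        parent = TreeNode(children=[a, b], join_index=join_index)
        join_index += 1
        nodes[next_id] = parent
        labels[next_id] = min(labels[ia], labels[ib])
        active -= {ia, ib}
        for k in active:
            dk = 0.5 * (
                dist[frozenset((ia, k))] + dist[frozenset((ib, k))] - d_ab
            )
            dist[frozenset((next_id, k))] = max(dk, 0.0)
        active.add(next_id)
        next_id += 1

    ia, ib = sorted(active, key=lambda k: labels[k])
    d_final = dist.get(frozenset((ia, ib)), 0.0)
    a, b = nodes[ia], nodes[ib]
    a.length = d_final / 2.0
    b.length = d_final / 2.0
    root = TreeNode(children=[a, b], join_index=join_index)
    return GuideTree(root)


# ---------------------------------------------------------------------------
# Newick I/O

def to_newick(tree: GuideTree, lengths: bool = True) -> str:
    def render(v: TreeNode) -> str:
        if v.is_leaf:
            body = v.name
        else:
            body = "(" + ",".join(render(c) for c in v.children) + ")"
        if lengths and v.length:
            return f"{body}:{v.length:.10g}"
        return body

    return render(tree.root) + ";"


def from_newick(text: str) -> GuideTree:
    """Parse a Newick string into a guide tree (binary topologies only)."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick text must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise ValueError(f"unbalanced parentheses at offset {pos}")
            pos += 1
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos].strip()
        if label:
            node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in Newick at offset {pos}")
    for v in root.postorder():
        if v.children:
            v.name = None  # internal labels are not part of the model
    return GuideTree(root)
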