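import numpy as np
import pytest

from msaforge.guidetree import (
    GuideTree,
    build_nj,
    build_slink,
    build_upgma,
    from_newick,
    to_newick,
)
from msaforge.similarity import SimilarityMatrix


def sim_from(ids, entries):
    return SimilarityMatrix(list(ids), "F", entries)


def topology(tree):
    """Nested frozensets of leaf labels — topology up to child order."""

    def rec(v):
        if v.is_leaf:
            return v.name
        return frozenset(rec(c) for c in v.children)

    return rec(tree.root)


class TestUpgma:
    def test_hand_agglomeration(self):
        sim = sim_from("ABC", {("A", "B"): 90, ("A", "C"): 50, ("B", "C"): 50})
        tree = build_upgma(sim)
        assert topology(tree) == frozenset([frozenset(["A", "B"]), "C"])
        # merged score to C is the plain average (50 + 50) / 2 = 50,
        # hence the root height reflects similarity 50
        root_height = (100 - 50) / 200
        a = next(v for v in tree.root.postorder() if v.name == "A")
        assert a.length == pytest.approx((100 - 90) / 200)

    def test_two_sequences_single_join(self):
        sim = sim_from("AB", {("A", "B"): 75})
        tree = build_upgma(sim)
        assert tree.n_leaves == 2 and topology(tree) == frozenset(["A", "B"])

    def test_ultrametric_similarity_recovers_generating_topology(self, rng):
        """Join order reproduces the tree an ultrametric matrix encodes."""
        # generating topology ((A,B),(C,D)) with heights 10 and 30
        entries = {
            ("A", "B"): 90,
            ("C", "D"): 80,
            ("A", "C"): 40, ("A", "D"): 40,
            ("B", "C"): 40, ("B", "D"): 40,
        }
        tree = build_upgma(sim_from("ABCD", entries))
        assert topology(tree) == frozenset(
            [frozenset(["A", "B"]), frozenset(["C", "D"])]
        )

    def test_all_equal_similarities_caterpillar_by_id(self):
        entries = {(i, j): 50.0 for i, j in [("A", "B"), ("A", "C"), ("A", "D"),
                                             ("B", "C"), ("B", "D"), ("C", "D")]}
        tree = build_upgma(sim_from("ABCD", entries))
        assert topology(tree) == frozenset(
            [frozenset([frozenset(["A", "B"]), "C"]), "D"]
        )


class TestSlink:
    def test_slmin_propagates_max_slmax_propagates_min(self):
        entries = {("A", "B"): 90, ("A", "C"): 70, ("B", "C"): 30}
        # after joining (A,B): SLMIN keeps max(70, 30) = 70; SLMAX min = 30
        tmin = build_slink(sim_from("ABC", entries), "SLMIN")
        tmax = build_slink(sim_from("ABC", entries), "SLMAX")
        # the root height encodes the propagated score
        assert _root_height(tmin) == pytest.approx((100 - 70) / 200)
        assert _root_height(tmax) == pytest.approx((100 - 30) / 200)

    def test_equal_removed_scores_match_upgma_at_n3(self):
        entries = {("A", "B"): 90, ("A", "C"): 50, ("B", "C"): 50}
        trees = [
            build_upgma(sim_from("ABC", entries)),
            build_slink(sim_from("ABC", entries), "SLMIN"),
            build_slink(sim_from("ABC", entries), "SLMAX"),
        ]
        assert len({to_newick(t) for t in trees}) == 1

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            build_slink(sim_from("AB", {("A", "B"): 1}), "SLAVG")


def _leaf_path_lengths(tree):
    """Sum of branch lengths between every leaf pair."""
    from itertools import combinations

    dists = {}
    leaf_depth = {}
    parent = {}

    def assign(v, depth):
        for c in v.children:
            parent[id(c)] = v
            assign(c, depth + c.length)
        if v.is_leaf:
            leaf_depth[v.name] = depth

    assign(tree.root, 0.0)
    leaves = {v.name: v for v in tree.root.postorder() if v.is_leaf}

    def ancestors(v):
        out = [v]
        while id(v) in parent:
            v = parent[id(v)]
            out.append(v)
        return out

    for a, b in combinations(sorted(leaves), 2):
        anc_a = ancestors(leaves[a])
        anc_b = {id(x) for x in ancestors(leaves[b])}
        lca = next(x for x in anc_a if id(x) in anc_b)
        depth = {}

        def depth_of(node):
            d = 0.0
            v = node
            while v is not lca:
                d += v.length
                v = parent[id(v)]
            return d

        dists[frozenset((a, b))] = depth_of(leaves[a]) + depth_of(leaves[b])
    return dists


def _root_height(tree):
    child = tree.root.children[0]
    h = 0.0
    v = child
    while True:
        h += v.length
        if v.is_leaf:
            return h
        v = v.children[0]


class TestNeighborJoining:
    def test_additive_four_taxon_split_recovered(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:1)) are additive;
        # NJ must recover the AB|CD split
        d = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 3,
            ("B", "C"): 6, ("B", "D"): 4, ("C", "D"): 4,
        }
        entries = {k: 100 - 100 * v / 10 for k, v in d.items()}  # d = (100-M)/100 * 10
        sim = sim_from("ABCD", entries)
        tree = build_nj(sim)
        top = topology(tree)
        assert top == frozenset([frozenset(["A", "B"]), frozenset(["C", "D"])])

    def test_three_leaf_additive_path_lengths(self):
        """Rooted 3-leaf NJ tree reproduces every pairwise distance exactly."""
        d = {("A", "B"): 0.3, ("A", "C"): 0.5, ("B", "C"): 0.6}
        entries = {k: 100 * (1 - v) for k, v in d.items()}
        tree = build_nj(sim_from("ABC", entries))
        paths = _leaf_path_lengths(tree)
        for pair, expected in d.items():
            assert paths[frozenset(pair)] == pytest.approx(expected)

    def test_identical_sequences_zero_lengths(self):
        entries = {(i, j): 100.0 for i, j in [("A", "B"), ("A", "C"), ("B", "C")]}
        tree = build_nj(sim_from("ABC", entries))
        assert all(v.length == 0.0 for v in tree.edges())

    def test_matches_skbio_topology(self, rng):
        """NJ agrees with scikit-bio's implementation on random matrices."""
        import skbio

        for trial in range(10):
            n = 5
            ids = [f"t{k}" for k in range(n)]
            vals = rng.uniform(10, 90, size=(n, n))
            d = (vals + vals.T) / 2
            np.fill_diagonal(d, 0)
            entries = {
                (ids[i], ids[j]): 100 - d[i, j]
                for i in range(n)
                for j in range(i + 1, n)
            }
            tree = build_nj(SimilarityMatrix(ids, "F", entries))
            dm = skbio.DistanceMatrix(d / 100.0, ids)
            sk = skbio.tree.nj(dm)
            mine = {
                frozenset(v.leaf_names())
                for v in tree.root.postorder()
                if not v.is_leaf
            }
            theirs = {
                frozenset(t.name for t in v.tips())
                for v in sk.traverse()
                if not v.is_tip()
            }
            # every non-trivial split of ours must appear in skbio's tree
            nontrivial = {
                s for s in mine if 1 < len(s) < n - 1
            }
            theirs_all = theirs | {
                frozenset(ids) - s for s in theirs
            }
            assert nontrivial <= theirs_all


class TestNewick:
    def test_simple_round_trip(self):
        sim = sim_from("ABC", {("A", "B"): 90, ("A", "C"): 50, ("B", "C"): 50})
        tree = build_upgma(sim)
        again = from_newick(to_newick(tree))
        assert topology(again) == topology(tree)

    def test_underscore_labels_preserved(self):
        tree = from_newick("((seq_one:1,seq_two:2):1,seq_three:3);")
        assert sorted(tree.leaf_names()) == ["seq_one", "seq_three", "seq_two"]

    def test_random_trees_round_trip_postorder(self, rng):
        from msaforge.guidetree import build_upgma

        for trial in range(20):
            n = int(rng.integers(3, 17))
            ids = [f"x{k}" for k in range(n)]
            entries = {}
            for i in range(n):
                for j in range(i + 1, n):
                    entries[(ids[i], ids[j])] = float(rng.uniform(0, 100))
            tree = build_upgma(SimilarityMatrix(ids, "F", entries))
            again = from_newick(to_newick(tree))
            assert again.leaf_names() == tree.leaf_names()
            assert topology(again) == topology(tree)

    def test_round_trip_matches_dendropy(self):
        import dendropy

        sim = sim_from("ABCD", {
            ("A", "B"): 90, ("A", "C"): 30, ("A", "D"): 20,
            ("B", "C"): 35, ("B", "D"): 25, ("C", "D"): 70,
        })
        text = to_newick(build_upgma(sim))
        dt = dendropy.Tree.get(data=text, schema="newick")
        assert sorted(t.taxon.label for t in dt.leaf_node_iter()) == list("ABCD")

    def test_malformed_newick(self):
        with pytest.raises(ValueError):
            from_newick("((A,B,C);")


class TestInvariants:
    @pytest.mark.parametrize("builder", ["upgma", "slmin", "slmax", "nj"])
    def test_valid_binary_tree_counts(self, builder, rng):
        n = 7
        ids = [f"s{k}" for k in range(n)]
        entries = {}
        for i in range(n):
            for j in range(i + 1, n):
                entries[(ids[i], ids[j])] = float(rng.uniform(0, 100))
        sim = SimilarityMatrix(ids, "F", entries)
        tree = {
            "upgma": build_upgma,
            "slmin": lambda s: build_slink(s, "SLMIN"),
            "slmax": lambda s: build_slink(s, "SLMAX"),
            "nj": build_nj,
        }[builder](sim)
        leaves = [v for v in tree.root.postorder() if v.is_leaf]
        internal = [v for v in tree.root.postorder() if not v.is_leaf]
        assert len(leaves) == n and len(internal) == n - 1
        assert sorted(tree.leaf_names()) == ids
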