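import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msaforge.seq_core import Sequence
from msaforge.similarity import (
    PairHMMParams,
    build_similarity_matrix,
    global_affine_align,
    lcs_length,
    mea_alignment_value,
    pair_posterior,
    score_full,
    score_kmers,
    score_lcs,
    score_proba,
    score_quick,
)

from .conftest import AA20, random_protein
from . import oracles

protein_text = st.text(alphabet=AA20, min_size=1, max_size=20)


class TestFull:
    def test_identical_sequences_are_100(self, blosum62):
        assert score_full("ACDEFG", "ACDEFG", blosum62) == 100.0

    def test_no_possible_matches_is_0(self, blosum62):
        assert score_full("AAAA", "WWWW", blosum62, 10, 0.5) == 0.0

    def test_empty_sequence_errors(self, blosum62):
        with pytest.raises(ValueError):
            global_affine_align("", "ACD", blosum62, 10, 0.5)

    def test_score_matches_brute_force_enumeration(self, blosum62, rng):
        """Gotoh DP equals exhaustive search over all global alignments."""
        for _ in range(100):
            s1 = random_protein(rng, int(rng.integers(3, 7)))
            s2 = random_protein(rng, int(rng.integers(3, 7)))
            go, ge = float(rng.uniform(2, 12)), float(rng.uniform(0.1, 2))
            expected = oracles.best_global_score(s1, s2, blosum62.score, go, ge)
            got, r1, r2 = global_affine_align(s1, s2, blosum62, go, ge)
            assert got == pytest.approx(expected, abs=1e-9)
            # the traceback realises the optimal score
            assert oracles.affine_alignment_score(
                r1, r2, blosum62.score, go, ge
            ) == pytest.approx(got, abs=1e-9)

    def test_score_matches_independent_aligner(self, blosum62, rng):
        """Agreement with Biopython's PairwiseAligner on longer pairs."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        ref = Align.PairwiseAligner()
        ref.mode = "global"
        ref.substitution_matrix = substitution_matrices.load("BLOSUM62")
        for _ in range(200):
            s1 = random_protein(rng, int(rng.integers(5, 41)))
            s2 = random_protein(rng, int(rng.integers(5, 41)))
            go, ge = float(rng.uniform(3, 12)), float(rng.uniform(0.2, 1.5))
            ref.open_gap_score = -(go + ge)
            ref.extend_gap_score = -ge
            got, _, _ = global_affine_align(s1, s2, blosum62, go, ge)
            assert got == pytest.approx(ref.score(s1, s2), abs=1e-6)

    def test_symmetry(self, blosum62, rng):
        for _ in range(20):
            s1 = random_protein(rng, 12)
            s2 = random_protein(rng, 15)
            assert score_full(s1, s2, blosum62) == pytest.approx(
                score_full(s2, s1, blosum62)
            )


class TestQuick:
    def test_identical_k1_is_100(self):
        assert score_quick("ACDEF", "ACDEF", 1) == 100.0

    def test_disjoint_is_0(self):
        assert score_quick("AAAA", "CCCC", 1) == 0.0

    def test_distinct_shared_tuples_hand_case(self):
        # shared 2-tuples {AB, BA}; denominator 4 - 2 + 1 = 3
        assert score_quick("ABAB", "BABA", 2) == pytest.approx(100 * 2 / 3)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            score_quick("AC", "ACD", 5)


class TestKmers:
    def test_no_shared_kmers_is_0(self):
        assert score_kmers("AAAA", "CCCC", 2) == 0.0

    def test_min_count_hand_case(self):
        # k-mers of ABAB: AB x2, BA x1 -> shared count 3, min length 4
        assert score_kmers("ABAB", "ABAB", 2) == pytest.approx(75.0)

    @given(protein_text, protein_text, st.integers(1, 3))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_symmetric_and_bounded(self, s1, s2, k):
        if k > min(len(s1), len(s2)):
            return
        v = score_kmers(s1, s2, k)
        assert v == score_kmers(s2, s1, k)
        assert 0.0 <= v <= 100.0


class TestLcs:
    def test_classic_dp_hand_case(self):
        assert score_lcs("ACGT", "AGT") == 100.0

    def test_disjoint_alphabets(self):
        assert score_lcs("AAAA", "WWWW") == 0.0

    def test_linear_space_equals_quadratic_dp(self, rng):
        for _ in range(300):
            s1 = random_protein(rng, int(rng.integers(1, 30)))
            s2 = random_protein(rng, int(rng.integers(1, 30)))
            assert lcs_length(s1, s2) == oracles.lcs_quadratic(s1, s2)


class TestPairHMM:
    def test_params_validation(self, hmm_params):
        assert hmm_params.transitions.sum(axis=1) == pytest.approx(np.ones(3))
        bad = np.copy(hmm_params.match_emit)
        bad[0, 0] += 0.5
        with pytest.raises(ValueError):
            PairHMMParams(bad, hmm_params.insert_emit)

    def test_posterior_matches_path_enumeration(self, hmm_params, rng):
        """Forward-backward equals exhaustive path enumeration, len <= 4."""
        for _ in range(100):
            s1 = random_protein(rng, int(rng.integers(1, 5)))
            s2 = random_protein(rng, int(rng.integers(1, 5)))
            _, expected = oracles.hmm_path_quantities(s1, s2, hmm_params)
            got = pair_posterior(s1, s2, hmm_params)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_row_mass_bounded(self, hmm_params, rng):
        for _ in range(20):
            s1 = random_protein(rng, int(rng.integers(2, 40)))
            s2 = random_protein(rng, int(rng.integers(2, 40)))
            post = pair_posterior(s1, s2, hmm_params)
            assert (post >= 0).all() and (post <= 1).all()
            assert (post.sum(axis=1) <= 1 + 1e-9).all()
            assert (post.sum(axis=0) <= 1 + 1e-9).all()

    def test_identical_sequences_posterior_is_diagonal(self, hmm_params):
        post = pair_posterior("ACD", "ACD", hmm_params)
        assert (post.argmax(axis=1) == np.arange(3)).all()

    def test_mea_matches_enumeration(self, hmm_params, rng):
        for _ in range(100):
            s1 = random_protein(rng, int(rng.integers(1, 5)))
            s2 = random_protein(rng, int(rng.integers(1, 5)))
            post = pair_posterior(s1, s2, hmm_params)
            assert mea_alignment_value(post) == pytest.approx(
                oracles.best_mea_value(post), abs=1e-9
            )

    def test_score_proba_symmetric_and_bounded(self, hmm_params, rng):
        for _ in range(10):
            s1 = random_protein(rng, 10)
            s2 = random_protein(rng, 14)
            v12 = score_proba(s1, s2, hmm_params)
            v21 = score_proba(s2, s1, hmm_params)
            assert v12 == pytest.approx(v21, abs=1e-6)
            assert 0.0 <= v12 <= 100.0

    def test_zero_posterior_mass_scores_near_zero(self, hmm_params):
        post = np.zeros((3, 4))
        assert mea_alignment_value(post) == 0.0


class TestSimilarityMatrix:
    def test_identical_sequences_score_maximal(self, blosum62):
        seqs = [Sequence(i, "MKVLIT") for i in "abc"]
        for method in ("F", "Q", "L"):
            sim = build_similarity_matrix(seqs, method, matrix=blosum62)
            assert all(v == 100.0 for _, _, v in sim.pairs())
        # KMERS divides the shared count by the sequence length, so even
        # identical sequences top out at (L - k + 1) / L
        sim = build_similarity_matrix(seqs, "K", k=3)
        assert all(v == pytest.approx(100 * 4 / 6) for _, _, v in sim.pairs())

    def test_entry_count_combinatorics(self, blosum62):
        seqs = [Sequence(f"s{i}", "MKVLITAGHE") for i in range(4)]
        sim = build_similarity_matrix(seqs, "L")
        assert len(list(sim.pairs())) == 6

    def test_input_order_invariance(self, blosum62, rng):
        seqs = [Sequence(f"s{i}", random_protein(rng, 15)) for i in range(4)]
        sim1 = build_similarity_matrix(seqs, "F", matrix=blosum62)
        shuffled = [seqs[2], seqs[0], seqs[3], seqs[1]]
        sim2 = build_similarity_matrix(shuffled, "F", matrix=blosum62)
        for i, j, v in sim1.pairs():
            assert sim2.get(i, j) == pytest.approx(v)

    @given(protein_text, protein_text)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_every_method_bounded_and_symmetric(self, s1, s2):
        for fn in (score_quick, score_lcs):
            v = fn(s1, s2)
            assert 0.0 <= v <= 100.0
            assert v == pytest.approx(fn(s2, s1))
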