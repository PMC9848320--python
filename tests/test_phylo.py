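"""Alignment, distances, neighbor joining, bootstrap and tree utilities."""

import math

import numpy as np
import pytest

from astascan.io import SequenceRecord
from astascan.matrices import blosum62
from astascan.phylo import (
    Alignment,
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    UndefinedDistanceError,
    bootstrap_tree,
    distance_matrix,
    leaf_distance_matrix,
    neighbor_joining,
    pairwise_align,
    progressive_msa,
    robinson_foulds,
    summarize_clades,
)
from astascan.simulate import random_binary_tree

M = blosum62()
_ALPH = "ACDEFGHIKLMNPQRSTVWY"


def _rand_seq(rng, n):
    return "".join(rng.choice(list(_ALPH), size=n))


def enumerate_best_score(a, b, gap_open, gap_extend):
    """Exhaustive alignment-path enumeration; affine run cost open+(L-1)*ext."""
    best = [-math.inf]

    def rec(i, j, prev, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "D", score + M[(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, "U", score - (gap_extend if prev == "U" else gap_open))
        if j < len(b):
            rec(i, j + 1, "L", score - (gap_extend if prev == "L" else gap_open))

    rec(0, 0, None, 0.0)
    return best[0]


class TestPairwiseAlign:
    def test_identity_scores_diagonal_sum(self):
        s = "HEAGVWKLY"
        score, (ra, rb) = pairwise_align(s, s)
        assert score == sum(M[(c, c)] for c in s)
        assert ra == rb == s

    def test_empty_versus_n_closed_form(self):
        for n in (1, 2, 7):
            score, (ra, rb) = pairwise_align("", "A" * n)
            assert score == -(10.0 + (n - 1) * 0.5)
            assert ra == "-" * n and rb == "A" * n
        assert pairwise_align("", "")[0] == 0.0

    def test_alignment_preserves_sequences(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = _rand_seq(rng, 40), _rand_seq(rng, 55)
            _, (ra, rb) = pairwise_align(a, b)
            assert ra.replace("-", "") == a
            assert rb.replace("-", "") == b
            assert len(ra) == len(rb)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            a = _rand_seq(rng, int(rng.integers(0, 7)))
            b = _rand_seq(rng, int(rng.integers(1, 7)))
            score, _ = pairwise_align(a, b)
            assert score == pytest.approx(enumerate_best_score(a, b, 10.0, 0.5))

    def test_matches_biopython(self):
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        rng = np.random.default_rng(12)
        for _ in range(20):
            a, b = _rand_seq(rng, 35), _rand_seq(rng, 50)
            score, _ = pairwise_align(a, b)
            assert score == pytest.approx(aligner.score(a, b))


class TestProgressiveMSA:
    def test_identical_sequences_align_gap_free(self):
        recs = [SequenceRecord(f"s{i}", "MKWVTFISLLAC") for i in range(3)]
        aln = progressive_msa(recs)
        assert aln.rows == ("MKWVTFISLLAC",) * 3

    def test_two_sequences_equal_pairwise(self):
        rng = np.random.default_rng(13)
        a, b = _rand_seq(rng, 30), _rand_seq(rng, 34)
        _, (ra, rb) = pairwise_align(a, b)
        aln = progressive_msa([SequenceRecord("a", a), SequenceRecord("b", b)])
        assert aln.rows == (ra, rb)

    def test_degap_roundtrip_and_order(self):
        rng = np.random.default_rng(14)
        recs = [SequenceRecord(f"s{i}", _rand_seq(rng, int(rng.integers(40, 70))))
                for i in range(6)]
        aln = progressive_msa(recs)
        assert aln.ids == tuple(r.id for r in recs)
        for i, r in enumerate(recs):
            assert aln.degapped(i) == r.sequence
        assert len({len(row) for row in aln.rows}) == 1

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            progressive_msa([SequenceRecord("a", "MK")])

    def test_alignment_shape_validation(self):
        with pytest.raises(ValueError):
            Alignment(("a", "b"), ("AA", "AAA"))
        with pytest.raises(ValueError):
            Alignment(("a",), ("AA", "AA"))


class TestDistances:
    def test_p_and_kimura_values(self):
        rows = ("A" * 19 + "C", "A" * 19 + "D")
        aln = Alignment(("x", "y"), rows)
        dp = distance_matrix(aln, correction="p")
        assert dp.values[0, 1] == pytest.approx(0.05)
        dk = distance_matrix(aln, correction="kimura")
        assert dk.values[0, 1] == pytest.approx(-math.log(1 - 0.05 - 0.2 * 0.05**2))

    def test_gapped_columns_excluded(self):
        aln = Alignment(("x", "y"), ("AC-G", "AD-G"))
        d = distance_matrix(aln, correction="p")
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_saturation_cap(self):
        aln = Alignment(("x", "y"), ("ACDEFGHIKL", "LKIHGFEDCA"))
        d = distance_matrix(aln, correction="kimura")
        assert d.values[0, 1] == 10.0

    def test_no_comparable_columns_raises(self):
        aln = Alignment(("x", "y"), ("A-", "-A"))
        with pytest.raises(UndefinedDistanceError):
            distance_matrix(aln)

    def test_unknown_correction_rejected(self):
        aln = Alignment(("x", "y"), ("AA", "AA"))
        with pytest.raises(ValueError):
            distance_matrix(aln, correction="jc")

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(("a",), np.zeros((2, 2)))


class TestTrees:
    def test_newick_roundtrip(self):
        rng = np.random.default_rng(15)
        t = random_binary_tree([f"L{i}" for i in range(9)], rng,
                               branch_length=lambda: rng.uniform(0.1, 1.0))
        text = t.to_newick()
        again = PhyloTree.from_newick(text)
        assert again.to_newick() == text
        assert again.bipartitions() == t.bipartitions()

    def test_newick_parser_rejects_garbage(self):
        with pytest.raises(ValueError):
            PhyloTree.from_newick("(a,b)")  # missing ';'
        with pytest.raises(ValueError):
            PhyloTree.from_newick("(a,b;);junk;")

    def test_bipartitions_are_nontrivial(self):
        rng = np.random.default_rng(16)
        t = random_binary_tree([f"L{i}" for i in range(8)], rng)
        n = 8
        for bip in t.bipartitions():
            assert 2 <= len(bip) <= n - 2

    def test_leaf_distances_on_hand_tree(self):
        #  ((A:2,B:3):1,C:4,D:5) around a central node
        t = PhyloTree.from_newick("((A:2,B:3):1,C:4,D:5);")
        d = leaf_distance_matrix(t)
        idx = {n: i for i, n in enumerate(d.ids)}
        expect = {("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
                  ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9}
        for (x, y), v in expect.items():
            assert d.values[idx[x], idx[y]] == pytest.approx(v)


class TestNeighborJoining:
    def test_two_taxa(self):
        d = DistanceMatrix(("a", "b"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        t = neighbor_joining(d)
        assert all(leaf.branch_length == pytest.approx(0.2) for leaf in t.leaves())

    def test_hand_additive_four_taxa(self):
        true = PhyloTree.from_newick("((A:2,B:3):1,C:4,D:5);")
        t = neighbor_joining(leaf_distance_matrix(true))
        assert robinson_foulds(t, true) == 0
        rec = leaf_distance_matrix(t)
        ref = leaf_distance_matrix(true)
        assert rec.ids == ref.ids
        assert np.allclose(rec.values, ref.values)

    def test_recovers_random_additive_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n = int(rng.integers(4, 11))
            true = random_binary_tree(
                [f"L{i}" for i in range(n)], rng,
                branch_length=lambda: rng.uniform(0.05, 1.0),
            )
            t = neighbor_joining(leaf_distance_matrix(true))
            assert robinson_foulds(t, true) == 0

    def test_zero_matrix_star(self):
        d = DistanceMatrix(tuple("abcde"), np.zeros((5, 5)))
        t = neighbor_joining(d)
        assert t.leaf_names() == list("abcde")
        assert all(leaf.branch_length == 0.0 for leaf in t.leaves())

    def test_deterministic_under_ties(self):
        d = DistanceMatrix(tuple("abcd"), np.ones((4, 4)) - np.eye(4))
        assert neighbor_joining(d).to_newick() == neighbor_joining(d).to_newick()

    def test_rf_matches_dendropy(self):
        import dendropy

        rng = np.random.default_rng(18)
        taxa = [f"L{i}" for i in range(10)]
        ns = dendropy.TaxonNamespace()
        for _ in range(10):
            t1 = random_binary_tree(taxa, rng)
            t2 = random_binary_tree(taxa, rng)
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                                   taxon_namespace=ns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                                   taxon_namespace=ns)
            d1.is_rooted = d2.is_rooted = False
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert robinson_foulds(t1, t2) == expected


class TestBootstrap:
    def _two_group_alignment(self):
        a = "ACDEFGHIKLMNPQRSTVWY" * 3
        b = "".join("A" if c != "A" else "G" for c in a)  # every column differs
        return Alignment(("a1", "a2", "b1", "b2"), (a, a, b, b))

    def test_exact_replicate_count_and_support_range(self):
        aln = self._two_group_alignment()
        tree, reps = bootstrap_tree(aln, n_reps=25, seed=0, keep_replicates=True)
        assert len(reps) == 25
        for node in tree._bipartition_nodes().values():
            assert 0.0 <= node.support <= 100.0

    def test_unambiguous_split_gets_full_support(self):
        tree = bootstrap_tree(self._two_group_alignment(), n_reps=50, seed=1)
        (node,) = tree._bipartition_nodes().values()
        assert node.support == 100.0

    def test_seed_determinism(self):
        aln = self._two_group_alignment()
        t1 = bootstrap_tree(aln, n_reps=30, seed=7)
        t2 = bootstrap_tree(aln, n_reps=30, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_invalid_rep_count(self):
        with pytest.raises(ValueError):
            bootstrap_tree(self._two_group_alignment(), n_reps=0)


class TestSummarizeClades:
    def test_monophyly_and_unmapped(self):
        t = PhyloTree.from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1,c:1);")
        meta = {"a1": "A", "a2": "A", "b1": "B", "b2": "C"}
        df = summarize_clades(t, meta)
        by = {r.clade: r for r in df.itertuples()}
        assert by["A"].monophyletic and by["A"].n_leaves == 2
        assert by["B"].monophyletic and by["B"].n_leaves == 1  # singleton
        assert by["C"].monophyletic
        assert by["unmapped"].n_leaves == 1  # leaf c

    def test_paraphyletic_group_flagged(self):
        t = PhyloTree.from_newick("((a1:1,b1:1):1,(a2:1,b2:1):1,c:1);")
        df = summarize_clades(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c": "A"})
        by = {r.clade: r for r in df.itertuples()}
        assert not by["A"].monophyletic
        assert not by["B"].monophyletic
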