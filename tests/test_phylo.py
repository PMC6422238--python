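"""Pairwise alignment identities, NJ reconstruction and Newick round trips."""

import itertools
import random

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj
from Bio.Align import substitution_matrices

from lossscan.genemodels import ProtSequence
from lossscan.phylo import (
    PhyloTree,
    align_global,
    identity_distance_matrix,
    neighbor_joining,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = -10.0, -1.0


def brute_force_score(a: str, b: str) -> float:
    """Maximum global alignment score by exhaustive enumeration of all
    monotone alignments, scoring each gap run as open + (len-1) * extend."""
    best = [-np.inf]

    def score_alignment(cols):
        total, prev = 0.0, None
        for x, y in cols:
            if x == "-" or y == "-":
                gap_row = 0 if x == "-" else 1
                total += GAP_EXTEND if prev == gap_row else GAP_OPEN
                prev = gap_row
            else:
                total += BLOSUM62[x, y]
                prev = None
        return total

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score_alignment(cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


class TestAlign:
    def test_identical_sequences(self):
        res = align_global("ACDEFGHIKL", "ACDEFGHIKL")
        assert res.identity_pct == 100.0

    def test_single_substitution(self):
        res = align_global("ACDEFGHIKL", "ACDEFGHIKV")
        assert res.identity_pct == pytest.approx(90.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_global("", "ACD")

    def test_score_matches_enumeration_oracle(self):
        rng = random.Random(5)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(6):
            a = "".join(rng.choice(aa) for _ in range(rng.randint(3, 6)))
            b = "".join(rng.choice(aa) for _ in range(rng.randint(3, 6)))
            assert align_global(a, b).score == pytest.approx(brute_force_score(a, b))

    def test_symmetry(self):
        rng = random.Random(8)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(5):
            a = "".join(rng.choice(aa) for _ in range(12))
            b = "".join(rng.choice(aa) for _ in range(9))
            ab, ba = align_global(a, b), align_global(b, a)
            assert ab.score == pytest.approx(ba.score)
            assert ab.identity_pct == pytest.approx(ba.identity_pct)


class TestDistanceMatrix:
    def test_identical_pair_distance_zero(self):
        seqs = [ProtSequence("a", "ACDEFG"), ProtSequence("b", "ACDEFG")]
        dm = identity_distance_matrix(seqs)
        assert dm["a", "b"] == 0.0

    def test_identical_pair_strictly_minimal(self):
        seqs = [
            ProtSequence("a", "ACDEFGHIKL"),
            ProtSequence("b", "ACDEFGHIKL"),
            ProtSequence("c", "WWYYPPGGSS"),
        ]
        dm = identity_distance_matrix(seqs)
        assert dm["a", "b"] < dm["a", "c"]
        assert dm["a", "b"] < dm["b", "c"]

    def test_symmetry_on_random_inputs(self):
        rng = random.Random(3)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        seqs = [
            ProtSequence(f"s{i}", "".join(rng.choice(aa) for _ in range(15)))
            for i in range(4)
        ]
        dm = identity_distance_matrix(seqs)
        assert np.allclose(dm.data, dm.data.T)

    def test_duplicate_labels_rejected(self):
        seqs = [ProtSequence("a", "ACD"), ProtSequence("a", "ACE")]
        with pytest.raises(ValueError, match="duplicate"):
            identity_distance_matrix(seqs)


def additive_matrix():
    """Distances generated from a fixed 5-leaf tree:
    ((A:2,B:3):1,(C:4,D:5):2,E:6) with internal edge lengths 1 and 2."""
    dist = {
        ("A", "B"): 5, ("A", "C"): 9, ("A", "D"): 10, ("A", "E"): 9,
        ("B", "C"): 10, ("B", "D"): 11, ("B", "E"): 10,
        ("C", "D"): 9, ("C", "E"): 12, ("D", "E"): 13,
    }
    ids = list("ABCDE")
    m = np.zeros((5, 5))
    for (x, y), d in dist.items():
        i, j = ids.index(x), ids.index(y)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(m, ids=ids)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float),
                            ids=["x", "y", "z"])
        tree = neighbor_joining(dm)
        tt = tree.tip_distances()
        for a, b in itertools.combinations("xyz", 2):
            assert tt[a, b] == pytest.approx(dm[a, b])

    def test_additive_five_leaf_recovery(self):
        dm = additive_matrix()
        tree = neighbor_joining(dm)
        assert not tree.clamped
        tt = tree.tip_distances()
        for a, b in itertools.combinations("ABCDE", 2):
            assert abs(tt[a, b] - dm[a, b]) < 1e-9

    def test_agrees_with_skbio_oracle_on_additive_input(self):
        dm = additive_matrix()
        ours = neighbor_joining(dm).tip_distances()
        oracle = skbio_nj(dm).tip_tip_distances()
        for a, b in itertools.combinations("ABCDE", 2):
            assert ours[a, b] == pytest.approx(float(oracle[a, b]))

    def test_degenerate_equal_distances_yield_valid_tree(self):
        m = np.ones((4, 4)) - np.eye(4)
        tree = neighbor_joining(DistanceMatrix(m, ids=list("abcd")))
        assert tree.leaf_names() == set("abcd")
        for tip in tree.tree.tips():
            assert tip.length >= 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"]))

    def test_newick_round_trip(self):
        tree = neighbor_joining(additive_matrix())
        back = PhyloTree.from_newick(tree.to_newick())
        assert back.leaf_names() == tree.leaf_names()
        tt1, tt2 = tree.tip_distances(), back.tip_distances()
        for a, b in itertools.combinations("ABCDE", 2):
            assert tt2[a, b] == pytest.approx(tt1[a, b])
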