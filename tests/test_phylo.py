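import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from oracles import (bipartitions, brute_force_smallest_clade,
                     path_distances, random_binary_tree)

from mcoscreen import (ProteinRecord, criterion4, nj_tree, pairwise_distance,
                       read_newick, root_at_outgroup, smallest_clade,
                       write_newick)


def additive_case(seed, n_leaves):
    rng = np.random.default_rng(seed)
    true_tree = random_binary_tree(rng, n_leaves)
    labels, d = path_distances(true_tree)
    return true_tree, DistanceMatrix(d, ids=labels)


class TestPairwiseDistance:
    def test_identical_sequences(self, scheme):
        a = ProteinRecord(id="a", residues="MKWHCDEACFGILNPQ")
        assert pairwise_distance(a, a, scheme) == 0.0

    def test_half_mismatch_poisson_correction(self, scheme):
        """p = 0.5 maps to -ln(0.5).  Alternating identical (W/W) and
        positively scoring mismatched (K/R) columns force the ungapped
        diagonal alignment."""
        a = ProteinRecord(id="a", residues="WKWKWKWKWKWKWKWKWKWK")
        b = ProteinRecord(id="b", residues="WRWRWRWRWRWRWRWRWRWR")
        assert pairwise_distance(a, b, scheme) == pytest.approx(-math.log(0.5))

    def test_saturation_cap(self, scheme):
        a = ProteinRecord(id="a", residues="WWWW")
        b = ProteinRecord(id="b", residues="KKKK")
        assert pairwise_distance(a, b, scheme) == 10.0

    def test_symmetry_random_pairs(self, scheme):
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(25):
            a = ProteinRecord(id="a",
                              residues="".join(rng.choice(aas, size=30)))
            b = ProteinRecord(id="b",
                              residues="".join(rng.choice(aas, size=25)))
            assert pairwise_distance(a, b, scheme) == \
                pairwise_distance(b, a, scheme)


class TestNeighborJoining:
    def test_four_taxon_split_recovery(self):
        """NJ recovers ((A,B),(C,D)) from its additive matrix."""
        #      A   B   C   D      built from a tree with internal edge 1.0
        d = [[0.0, 0.3, 1.5, 1.6],
             [0.3, 0.0, 1.6, 1.7],
             [1.5, 1.6, 0.0, 0.3],
             [1.6, 1.7, 0.3, 0.0]]
        tree = nj_tree(DistanceMatrix(d, ids=list("ABCD")))
        assert frozenset("AB") in bipartitions(tree) \
            or frozenset("CD") in bipartitions(tree)

    def test_three_taxon_closed_form(self):
        d = [[0.0, 0.4, 0.6],
             [0.4, 0.0, 0.8],
             [0.6, 0.8, 0.0]]
        tree = nj_tree(DistanceMatrix(d, ids=list("ABC")))
        lengths = {t.name: t.length for t in tree.tips()}
        # three-point formulas: a = (dAB + dAC - dBC)/2, etc.
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.3)
        assert lengths["C"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_recovery_and_branch_lengths(self, seed):
        """On additive input NJ returns the generating topology with the
        generating branch lengths (checked via leaf-to-leaf distances)."""
        true_tree, dm = additive_case(100 + seed, 6)
        est = nj_tree(dm)
        assert bipartitions(est) == bipartitions(true_tree)
        _, d_true = path_distances(true_tree)
        _, d_est = path_distances(est)
        assert np.allclose(d_true, d_est, atol=1e-9)

    def test_agrees_with_skbio_topology(self):
        """Independent cross-check against scikit-bio's NJ on additive
        input (topologies must coincide; both are consistent)."""
        _, dm = additive_case(7, 8)
        ours = nj_tree(dm)
        theirs = skbio_nj(dm)
        assert bipartitions(ours) == bipartitions(theirs)

    def test_requires_three_labels(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix([[0.0, 1.0], [1.0, 0.0]], ids=["a", "b"]))


class TestRooting:
    def test_single_leaf_outgroup_roots_on_pendant_edge(self):
        tree = nj_tree(additive_case(5, 6)[1])
        rooted = root_at_outgroup(tree, ["L00"])
        sides = [frozenset(t.name for t in c.tips()) or frozenset([c.name])
                 for c in rooted.children]
        assert frozenset(["L00"]) in sides

    def test_complement_outgroup_equivalent(self):
        tree = nj_tree(additive_case(6, 6)[1])
        all_but_one = [f"L{k:02d}" for k in range(1, 6)]
        rooted = root_at_outgroup(tree, all_but_one)
        sides = [frozenset(t.name for t in c.tips()) or frozenset([c.name])
                 for c in rooted.children]
        assert frozenset(["L00"]) in sides

    def test_rooting_preserves_bipartitions(self):
        tree = nj_tree(additive_case(8, 7)[1])
        before = bipartitions(tree)
        rooted = root_at_outgroup(tree, ["L03"])
        assert bipartitions(rooted) == before

    def test_non_monophyletic_outgroup_errors_with_leaves(self):
        true_tree, dm = additive_case(9, 6)
        tree = nj_tree(dm)
        # two leaves that are not sisters in the estimated tree
        for pair in [("L00", "L01"), ("L00", "L02"), ("L00", "L03")]:
            try:
                root_at_outgroup(tree, pair)
            except ValueError as exc:
                assert "not monophyletic" in str(exc)
                return
        pytest.fail("every tested pair was monophyletic")


class TestClades:
    def test_single_and_full_leaf_sets(self):
        tree = root_at_outgroup(nj_tree(additive_case(3, 6)[1]), ["L05"])
        assert smallest_clade(tree, ["L01"]) == frozenset(["L01"])
        every = [f"L{k:02d}" for k in range(6)]
        assert smallest_clade(tree, every) == frozenset(every)

    def test_unknown_id_errors(self):
        tree = root_at_outgroup(nj_tree(additive_case(3, 6)[1]), ["L05"])
        with pytest.raises(ValueError, match="unknown"):
            smallest_clade(tree, ["nope"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(5, 13))
        tree = random_binary_tree(rng, n)
        labels = [f"L{k:02d}" for k in range(n)]
        for _ in range(5):
            k = int(rng.integers(2, min(5, n)))
            ids = set(rng.choice(labels, size=k, replace=False).tolist())
            assert smallest_clade(tree, ids) == \
                brute_force_smallest_clade(tree, ids)

    def test_criterion4_sister_passes_negative_inside_fails(self):
        tree = TreeNode.read(["((out:1,neg2:1):1,((cand:0.1,ref:0.1):0.5,"
                              "neg1:0.6):0.5);"])
        passed, clade = criterion4("cand", "ref", tree, {"neg1", "neg2"})
        assert passed and clade == frozenset({"cand", "ref"})
        # force neg1 into the connecting clade
        tree2 = TreeNode.read(["((out:1,x:1):1,((cand:0.1,neg1:0.1):0.5,"
                               "ref:0.6):0.5);"])
        passed2, clade2 = criterion4("cand", "ref", tree2, {"neg1"})
        assert not passed2 and "neg1" in clade2

    def test_criterion4_monotone_in_outside_negatives(self):
        tree = TreeNode.read(["((out:1,neg2:1):1,((cand:0.1,ref:0.1):0.5,"
                              "neg1:0.6):0.5);"])
        passed_small, _ = criterion4("cand", "ref", tree, {"neg1"})
        passed_big, _ = criterion4("cand", "ref", tree,
                                   {"neg1", "neg2", "out"})
        assert passed_small and passed_big


class TestNewick:
    def test_round_trip_six_decimals(self, tmp_path):
        tree = nj_tree(additive_case(4, 7)[1])
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert bipartitions(back) == bipartitions(tree)
        orig = {t.name: t.length for t in tree.tips()}
        new = {t.name: t.length for t in back.tips()}
        for name in orig:
            assert new[name] == pytest.approx(orig[name], abs=1e-6)
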