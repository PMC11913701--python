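import itertools

import numpy as np
import pytest

from oracles import rf_distance
from orthoquery.align import MultipleAlignment, percent_identity_matrix
from orthoquery.fixtures import random_tree
from orthoquery.phylo import (DistanceMatrix, NewickError, distance_from_pim,
                              from_newick, leaf_distance_matrix, midpoint_root,
                              neighbor_joining, to_newick, total_branch_length)


class TestDistanceFromPim:
    def test_endpoints(self):
        msa = MultipleAlignment(["a", "b"], ["AAAA", "AAAA"])
        dm = distance_from_pim(percent_identity_matrix(msa))
        assert dm["a", "b"] == 0.0

    def test_percent_to_p_distance(self):
        class Pim:
            labels = ["x", "y"]
            values = np.array([[100.0, 77.1], [77.1, 100.0]])
        dm = distance_from_pim(Pim())
        assert dm["x", "y"] == pytest.approx(0.229, abs=1e-12)

    def test_zero_identity_maps_to_one(self):
        class Pim:
            labels = ["x", "y"]
            values = np.array([[100.0, 0.0], [0.0, 100.0]])
        assert distance_from_pim(Pim())["x", "y"] == 1.0

    def test_poisson_correction_monotone(self):
        class Pim:
            labels = ["x", "y"]
            values = np.array([[100.0, 50.0], [50.0, 100.0]])
        plain = distance_from_pim(Pim())["x", "y"]
        corrected = distance_from_pim(Pim(), correction="poisson")["x", "y"]
        assert corrected == pytest.approx(-np.log(0.5))
        assert corrected > plain


class TestNeighborJoining:
    def test_classic_five_taxon_example(self):
        # additive matrix of the well-known worked NJ example
        dm = DistanceMatrix([[0, 5, 9, 9, 8], [5, 0, 10, 10, 9], [9, 10, 0, 8, 7],
                             [9, 10, 8, 0, 3], [8, 9, 7, 3, 0]], ids=list("ABCDE"))
        tree = neighbor_joining(dm)
        back = leaf_distance_matrix(tree).filter(list("ABCDE"))
        assert np.allclose(back.data, dm.data, atol=1e-9)
        assert rf_distance(to_newick(tree), "((A:2,B:3):3,(D:2,E:1):1,C:4);") == 0

    def test_three_taxa_closed_form(self):
        d_ab, d_ac, d_bc = 4.0, 6.0, 8.0
        dm = DistanceMatrix([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]],
                            ids=list("ABC"))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)
        assert len(tree.children) == 3  # unrooted trifurcation

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix([[0, 6], [6, 0]], ids=["A", "B"])
        tree = neighbor_joining(dm)
        assert {t.name: t.length for t in tree.tips()} == {"A": 3.0, "B": 3.0}

    def test_additive_recovery_property(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            true = random_tree(int(rng.integers(4, 11)), rng)
            dm = leaf_distance_matrix(true)
            est = neighbor_joining(dm)
            assert rf_distance(to_newick(true), to_newick(est)) == 0
            back = leaf_distance_matrix(est).filter(dm.ids)
            assert np.abs(back.data - dm.data).max() < 1e-9

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        true = random_tree(6, rng)
        dm = leaf_distance_matrix(true)
        perm = list(rng.permutation(list(dm.ids)))
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm.filter(perm))
        assert rf_distance(to_newick(t1), to_newick(t2)) == 0

    def test_invalid_matrices_rejected(self):
        # asymmetry is caught by the DistanceMatrix container itself
        with pytest.raises(Exception, match="[Ss]ymmetric"):
            DistanceMatrix([[0, 1], [2, 0]], ids=["A", "B"])
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=["A", "B"])
        dm.data.flags.writeable = True
        dm.data[0, 1] = dm.data[1, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            neighbor_joining(dm)

    def test_agrees_with_reference_nj(self):
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(5)
        true = random_tree(7, rng)
        dm = leaf_distance_matrix(true)
        mine = neighbor_joining(dm)
        ref = skbio_nj(dm)
        assert rf_distance(to_newick(mine), str(ref)) == 0

    def test_deterministic_output(self):
        rng = np.random.default_rng(9)
        d = rng.random((6, 6)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=[f"L{i}" for i in range(6)])
        assert to_newick(neighbor_joining(dm)) == to_newick(neighbor_joining(dm))


class TestMidpointRoot:
    def test_two_leaf_unequal_branches(self):
        tree = from_newick("(A:2,B:4);")
        rooted = midpoint_root(tree)
        depths = {t.name: rooted.distance(t) for t in rooted.tips()}
        assert depths == {"A": 3.0, "B": 3.0}

    def test_caterpillar_diameter_endpoints_equidistant(self):
        tree = from_newick("(((A:5,B:1):1,C:1):1,D:1);")
        rooted = midpoint_root(tree)
        depths = {t.name: rooted.distance(t) for t in rooted.tips()}
        # diameter path is A..D, length 5 + 1 + 1 + 1 = 8
        assert depths["A"] == pytest.approx(4.0)
        assert depths["D"] == pytest.approx(4.0)

    def test_balanced_tree_keeps_deepest_pair_balanced(self):
        tree = from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = midpoint_root(tree)
        depths = sorted(rooted.distance(t) for t in rooted.tips())
        assert depths == [2.0, 2.0, 2.0, 2.0]

    def test_property_equidistance_and_length_conservation(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            tree = random_tree(int(rng.integers(3, 12)), rng)
            total = total_branch_length(tree)
            rooted = midpoint_root(tree)
            assert total_branch_length(rooted) == pytest.approx(total, abs=1e-9)
            tt = leaf_distance_matrix(rooted)
            a, b = max(itertools.combinations(tt.ids, 2), key=lambda p: tt[p])
            tips = {t.name: t for t in rooted.tips()}
            da, db = rooted.distance(tips[a]), rooted.distance(tips[b])
            assert da == pytest.approx(db, abs=1e-9)
            assert da + db == pytest.approx(tt[a, b], abs=1e-9)

    def test_agrees_with_reference_midpoint(self):
        rng = np.random.default_rng(8)
        tree = random_tree(8, rng)
        mine = midpoint_root(tree.copy())
        ref = tree.copy().root_at_midpoint()
        mine_depth = max(mine.distance(t) for t in mine.tips())
        ref_depth = max(ref.distance(t) for t in ref.tips())
        assert mine_depth == pytest.approx(ref_depth, abs=1e-9)

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            midpoint_root(from_newick("(A:1);"))


class TestNewick:
    def test_two_leaf_rooted_shape(self):
        tree = midpoint_root(from_newick("(A:2,B:4);"))
        assert to_newick(tree) in ("(A:3.0,B:3.0);", "(B:3.0,A:3.0);")

    def test_roundtrip_random_tree(self):
        rng = np.random.default_rng(4)
        tree = random_tree(20, rng)
        text = to_newick(tree)
        assert to_newick(from_newick(text)) == text

    def test_pipe_labels_survive(self):
        text = to_newick(from_newick("('jgi|ChlNC64A|41714':1.5,B:2);"))
        back = from_newick(text)
        assert sorted(t.name for t in back.tips()) == ["B", "jgi|ChlNC64A|41714"]

    def test_parse_error_on_malformed(self):
        with pytest.raises(NewickError):
            from_newick("((A:1,B:2;")

    def test_branch_lengths_six_significant_digits(self):
        tree = from_newick("(A:0.123456789,B:1);")
        assert "0.123457" in to_newick(tree)
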