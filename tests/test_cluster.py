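"""Row normalization, Manhattan distances, complete linkage, tree queries."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from vdrassay import (complete_linkage, cut_partition, is_clade, row_normalize,
                      species_distance, to_newick)
from vdrassay.cluster import Dendrogram

from .oracles import naive_complete_linkage


class TestRowNormalize:
    def test_zscore_sample_sd(self, matrix_factory):
        m = matrix_factory([[1.0, 2.0, 3.0], [1.0, 1.0, 3.0]], "XYZ")
        out = row_normalize(m).values
        assert np.allclose(out.loc["a0"], [-1.0, 0.0, 1.0])

    def test_constant_row_maps_to_zeros(self, matrix_factory):
        m = matrix_factory([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], "XYZ")
        out = row_normalize(m).values
        assert np.allclose(out.loc["a0"], 0.0)

    def test_zscore_idempotent(self, matrix_factory):
        m = matrix_factory(np.random.default_rng(0).normal(size=(4, 5)), "ABCDE")
        once = row_normalize(m)
        twice = row_normalize(once)
        assert np.allclose(once.values, twice.values)

    def test_minmax_range(self, matrix_factory):
        m = matrix_factory([[1.0, 3.0, 2.0]], "XYZ")
        out = row_normalize(m, "minmax").values
        assert np.allclose(out.loc["a0"], [0.0, 1.0, 0.5])

    def test_unknown_method_rejected(self, matrix_factory):
        m = matrix_factory([[1.0, 2.0]], "XY")
        with pytest.raises(ValueError, match="zscore"):
            row_normalize(m, "quantile")


class TestSpeciesDistance:
    def test_identical_columns_at_zero(self, matrix_factory):
        m = matrix_factory([[1.0, 1.0], [2.0, 2.0]], "XY")
        assert species_distance(m).loc["X", "Y"] == 0.0

    def test_hand_arithmetic(self, matrix_factory):
        m = matrix_factory([[1.0, 4.0], [2.0, 6.0]], "XY")
        assert species_distance(m).loc["X", "Y"] == 7.0

    def test_metric_properties_vs_brute_force(self, matrix_factory):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(6, 5))
        m = matrix_factory(vals, "ABCDE")
        d = species_distance(m).to_numpy()
        brute = np.array([[np.sum(np.abs(vals[:, i] - vals[:, j])) for j in range(5)]
                          for i in range(5)])
        assert np.allclose(d, brute)
        assert np.allclose(d, d.T)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestCompleteLinkage:
    def test_hand_worked_three_leaf_merges(self, toy_distance):
        tree = complete_linkage(toy_distance)
        (a, b, h1), (c, d, h2) = tree.merges
        assert {a, b} == {0, 1} and h1 == 1.0     # A joins B at 1
        assert h2 == 5.0                           # then C at max(5, 4) = 5

    def test_equal_distances_merge_at_single_height(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = complete_linkage(d, tuple("WXYZ"))
        assert all(h == 2.0 for _, _, h in tree.merges)
        # declared tie rule: (0,1) first, then (2,3), then the two pairs
        assert tree.merges[0][:2] == (0, 1)
        assert tree.merges[1][:2] == (2, 3)

    def test_heights_are_max_within_cluster_distance(self, planted):
        matrix, _, _ = planted
        dist = species_distance(row_normalize(matrix))
        tree = complete_linkage(dist)
        sets = tree.node_leafsets()
        n = tree.n_leaves
        for i, (a, b, h) in enumerate(tree.merges):
            members = sorted(sets[n + i])
            expected = max(dist.loc[x, y] for x in members for y in members)
            assert h == pytest.approx(expected)

    def test_invariant_to_row_and_column_order(self, planted):
        matrix, _, _ = planted
        norm = row_normalize(matrix)
        tree = complete_linkage(species_distance(norm))
        rng = np.random.default_rng(1)
        shuffled_vals = norm.values.sample(frac=1.0, random_state=3)[
            list(rng.permutation(norm.species))]
        from vdrassay import AssayMatrix
        shuffled = AssayMatrix(shuffled_vals, norm.annotations.loc[shuffled_vals.index])
        tree2 = complete_linkage(species_distance(shuffled))
        assert set(tree.node_leafsets()) == set(tree2.node_leafsets())

    @pytest.mark.parametrize("trial", range(20))
    def test_agreement_with_naive_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(6, 11))
        profile = rng.normal(size=(7, n))
        d = np.array([[np.sum(np.abs(profile[:, i] - profile[:, j])) for j in range(n)]
                      for i in range(n)])
        leaves = tuple(f"s{i}" for i in range(n))
        tree = complete_linkage(d, leaves)
        oracle = naive_complete_linkage(d)
        sets = tree.node_leafsets()
        for i, (a, b, h) in enumerate(tree.merges):
            oa, ob, oh = oracle[i]
            assert h == pytest.approx(oh)
            got = {frozenset(sets[a]), frozenset(sets[b])}
            want = {frozenset(leaves[x] for x in oa), frozenset(leaves[x] for x in ob)}
            assert got == want

    def test_agreement_with_scipy_on_tie_free_matrix(self):
        # independent implementation cross-check where tie-breaking is moot
        rng = np.random.default_rng(9)
        profile = rng.normal(size=(10, 7))
        n = 7
        d = np.array([[np.sum(np.abs(profile[:, i] - profile[:, j])) for j in range(n)]
                      for i in range(n)])
        tree = complete_linkage(d, tuple(f"s{i}" for i in range(n)))
        Z = scipy_linkage(squareform(d), method="complete")
        assert np.allclose(sorted(h for _, _, h in tree.merges), sorted(Z[:, 2]))
        coph = squareform(cophenet(Z))
        sets = tree.node_leafsets()
        # cophenetic distance of each pair must match merge heights
        for i, (a, b, h) in enumerate(tree.merges):
            x = min(sets[a], key=lambda s: int(s[1:]))
            y = min(sets[b], key=lambda s: int(s[1:]))
            assert coph[int(x[1:]), int(y[1:])] == pytest.approx(h)

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            complete_linkage(np.zeros((1, 1)), ("A",))


class TestCutPartition:
    def test_k1_is_everything(self, toy_distance):
        tree = complete_linkage(toy_distance)
        assert cut_partition(tree, 1) == [frozenset("ABC")]

    def test_kn_is_singletons(self, toy_distance):
        tree = complete_linkage(toy_distance)
        assert set(cut_partition(tree, 3)) == {frozenset("A"), frozenset("B"), frozenset("C")}

    def test_k2_toy(self, toy_distance):
        tree = complete_linkage(toy_distance)
        assert set(cut_partition(tree, 2)) == {frozenset("AB"), frozenset("C")}

    def test_k_out_of_range(self, toy_distance):
        tree = complete_linkage(toy_distance)
        with pytest.raises(ValueError):
            cut_partition(tree, 0)
        with pytest.raises(ValueError):
            cut_partition(tree, 4)


class TestIsClade:
    def test_root_and_singletons_are_clades(self, toy_distance):
        tree = complete_linkage(toy_distance)
        assert is_clade(tree, {"A", "B", "C"})
        assert is_clade(tree, {"B"})

    def test_non_clade_pair(self, toy_distance):
        tree = complete_linkage(toy_distance)
        assert is_clade(tree, {"A", "B"})
        assert not is_clade(tree, {"A", "C"})

    def test_unknown_leaf_rejected(self, toy_distance):
        tree = complete_linkage(toy_distance)
        with pytest.raises(ValueError, match="unknown"):
            is_clade(tree, {"A", "Q"})


class TestNewick:
    def test_three_leaf_branch_lengths(self, toy_distance):
        # half-height convention: leaves of the first merge sit h/2 = 0.5 deep
        nwk = to_newick(complete_linkage(toy_distance))
        assert nwk == "((A:0.5,B:0.5):2,C:2.5);"

    def test_single_merge_pair(self):
        tree = Dendrogram(((0, 1, 3.0),), ("A", "B"))
        assert to_newick(tree) == "(A:1.5,B:1.5);"

    def test_round_trip_preserves_clades(self, planted):
        import dendropy
        matrix, _, _ = planted
        tree = complete_linkage(species_distance(row_normalize(matrix)))
        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        parsed_clades = {frozenset(leaf.taxon.label for leaf in node.leaf_iter())
                        for node in parsed.preorder_node_iter()}
        ours = set(tree.node_leafsets())
        assert ours <= parsed_clades

    def test_ultrametric_root_to_leaf_depths(self, planted):
        import dendropy
        matrix, _, _ = planted
        tree = complete_linkage(species_distance(row_normalize(matrix)))
        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        depths = [leaf.distance_from_root() for leaf in parsed.leaf_node_iter()]
        assert np.allclose(depths, tree.merges[-1][2] / 2, rtol=1e-5)
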