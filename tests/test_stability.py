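"""Bootstrap recapitulation and leave-out coregulator importance."""

import numpy as np
import pytest

from vdrassay import (ClusterPattern, bootstrap_recapitulation, complete_linkage,
                      coregulator_importance, cut_partition, recapitulation_check,
                      row_normalize, simulate_assay_matrix, species_distance)
from vdrassay.cluster import manhattan_condensed

from .oracles import enumerate_recapitulation


def toy_matrix_4sp(matrix_factory, noise=0.35, seed=0):
    """3 assays x 4 species; two informative rows separate {P,Q} from {R,S}."""
    rng = np.random.default_rng(seed)
    base = np.array([
        [0.0, 0.1, 1.0, 1.1],     # informative
        [0.1, 0.0, 1.1, 1.0],     # informative
        [0.5, 0.5, 0.5, 0.5],     # flat
    ])
    vals = base + rng.normal(0, noise, size=base.shape)
    return matrix_factory(vals, "PQRS", coregs=[{"SRC1"}, {"SRC1"}, set()])


class TestRecapitulationCheck:
    def test_reference_matrix_matches_by_construction(self, planted):
        matrix, truth, pattern = planted
        tree = complete_linkage(species_distance(row_normalize(matrix)))
        match, clades = recapitulation_check(tree, pattern)
        assert match and all(clades.values())

    def test_swapped_members_fail(self, planted):
        matrix, truth, pattern = planted
        g1, g2 = (sorted(g) for g in truth.true_partition)
        swapped = ClusterPattern.from_lists(
            [[g2[0]] + g1[1:], [g1[0]] + g2[1:]])
        tree = complete_linkage(species_distance(row_normalize(matrix)))
        match, _ = recapitulation_check(tree, swapped)
        assert not match

    def test_leaf_mismatch_rejected(self, planted):
        matrix, _, pattern = planted
        bad = ClusterPattern.from_lists([["X"], ["Y"]])
        tree = complete_linkage(species_distance(row_normalize(matrix)))
        with pytest.raises(ValueError, match="species"):
            recapitulation_check(tree, bad)

    def test_partition_match_implies_groups_are_clades(self, planted):
        # at k=2 the cut components are descendant sets of the root's children
        matrix, truth, pattern = planted
        for seed in range(10):
            m, t = simulate_assay_matrix(seed=seed, noise_sd=2.0, effect_size=2.0)
            tree = complete_linkage(species_distance(row_normalize(m)))
            pat = ClusterPattern.from_lists(
                [sorted(g) for g in t.true_partition],
                {"C1": sorted(t.true_partition[0]), "C2": sorted(t.true_partition[1])})
            match, clades = recapitulation_check(tree, pat)
            if match:
                assert all(clades.values())


class TestBootstrapRecapitulation:
    def test_duplicated_columns_are_unbreakable(self, matrix_factory):
        # exact group structure: resampling rows cannot separate identical columns
        vals = np.array([[0.0, 0.0, 1.0], [0.2, 0.2, 0.9], [0.1, 0.1, 0.7],
                         [0.4, 0.4, 0.0]])
        m = matrix_factory(vals, "XYZ", coregs=[{"SRC1"}, set(), set(), set()])
        pattern = ClusterPattern.from_lists([["X", "Y"], ["Z"]])
        rep = bootstrap_recapitulation(m, pattern, B=200, seed=0)
        assert rep.overall_recapitulation == 1.0

    def test_matches_exhaustive_enumeration(self, matrix_factory):
        m = toy_matrix_4sp(matrix_factory)
        pattern = ClusterPattern.from_lists([["P", "Q"], ["R", "S"]],
                                            {"left": ["P", "Q"]})
        vals = m.values.to_numpy()
        leaves = tuple(m.species)

        def score(sub, lv):
            tree = complete_linkage(manhattan_condensed(sub), lv)
            match, clades = recapitulation_check(tree, pattern)
            return match and all(clades.values())

        exact = enumerate_recapitulation(vals, leaves, score)
        B = 4000
        rep = bootstrap_recapitulation(m, pattern, B=B, seed=123)
        tol = 3 * np.sqrt(exact * (1 - exact) / B) + 1e-12
        assert 0 < exact < 1  # the toy is deliberately breakable
        assert abs(rep.overall_recapitulation - exact) <= tol

    def test_rates_are_probabilities_and_joint_rate_is_min_bound(self, planted):
        matrix, _, pattern = planted
        rep = bootstrap_recapitulation(row_normalize(matrix), pattern, B=300, seed=4)
        assert 0 <= rep.overall_recapitulation <= 1
        for rate in rep.subcluster_recapitulation.values():
            assert 0 <= rate <= 1
        assert rep.overall_recapitulation <= min(rep.subcluster_recapitulation.values())
        assert rep.overall_recapitulation <= rep.partition_recapitulation

    def test_full_determinism(self, planted):
        matrix, _, pattern = planted
        norm = row_normalize(matrix)
        a = bootstrap_recapitulation(norm, pattern, B=150, seed=9, mode="stratified")
        b = bootstrap_recapitulation(norm, pattern, B=150, seed=9, mode="stratified")
        assert a.to_dict() == b.to_dict()

    def test_column_order_invariance_under_matched_seed(self, planted):
        matrix, _, pattern = planted
        norm = row_normalize(matrix)
        rep = bootstrap_recapitulation(norm, pattern, B=200, seed=21)
        from vdrassay import AssayMatrix
        rev = AssayMatrix(norm.values[list(reversed(norm.species))], norm.annotations)
        rep2 = bootstrap_recapitulation(rev, pattern, B=200, seed=21)
        assert rep.overall_recapitulation == rep2.overall_recapitulation

    def test_stratified_preserves_signature_counts(self, planted):
        matrix, _, pattern = planted
        norm = row_normalize(matrix)
        rep = bootstrap_recapitulation(norm, pattern, B=100, seed=2, mode="stratified")
        assert rep.mode == "stratified"
        assert rep.n_bootstrap == 100

    def test_validation(self, planted):
        matrix, _, pattern = planted
        with pytest.raises(ValueError, match="B"):
            bootstrap_recapitulation(matrix, pattern, B=0, seed=0)
        bad = ClusterPattern.from_lists([["nope"], ["hVDR"]])
        with pytest.raises(ValueError, match="species"):
            bootstrap_recapitulation(matrix, bad, B=10, seed=0)


class TestCoregulatorImportance:
    def test_planted_drivers_rank_highest(self, planted):
        matrix, truth, pattern = planted
        imp = coregulator_importance(row_normalize(matrix), pattern, B=300, seed=1)
        top2 = {g for g, _ in imp.ranked()[:2]}
        assert top2 == set(truth.driver_coregulators) == {"RXR_WT", "SRC1"}

    def test_importance_bounded(self, planted):
        matrix, _, pattern = planted
        imp = coregulator_importance(row_normalize(matrix), pattern, B=200, seed=8)
        for value in imp.values():
            assert -1.0 <= value <= 1.0

    def test_absent_coregulator_reports_zero_with_warning(self, matrix_factory):
        vals = np.array([[0.0, 0.1, 1.0, 1.1], [0.1, 0.0, 1.1, 1.0],
                         [0.5, 0.4, 0.5, 0.6]])
        m = matrix_factory(vals, "PQRS", coregs=[{"SRC1"}, set(), set()])
        pattern = ClusterPattern.from_lists([["P", "Q"], ["R", "S"]])
        with pytest.warns(UserWarning, match="GRIP1"):
            imp = coregulator_importance(m, pattern, B=50, seed=0,
                                         coregulators=("SRC1", "GRIP1"))
        assert imp["GRIP1"] == 0.0
        assert "GRIP1" in imp.warnings

    def test_removing_all_informative_rows_raises(self, matrix_factory):
        vals = np.array([[0.0, 0.0, 1.0, 1.0], [0.1, 0.0, 1.1, 1.0]])
        m = matrix_factory(vals, "PQRS", coregs=[{"SRC1"}, {"SRC1"}])
        pattern = ClusterPattern.from_lists([["P", "Q"], ["R", "S"]])
        with pytest.raises(ValueError, match="<2 rows"):
            coregulator_importance(m, pattern, B=10, seed=0, coregulators=("SRC1",))

    def test_determinism(self, planted):
        matrix, _, pattern = planted
        norm = row_normalize(matrix)
        a = coregulator_importance(norm, pattern, B=100, seed=3)
        b = coregulator_importance(norm, pattern, B=100, seed=3)
        assert a.to_dict() == b.to_dict()
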