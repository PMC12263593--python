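"""FC construction: parcellation, correlation, vectorization, assembly,
edge indexing and the ROI-coverage exclusion procedure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectoprint.fc import (
    ConnectomeVector,
    RegionalTimeSeries,
    assemble_population,
    compute_fc,
    edge_index_to_region_pair,
    edge_subset_for_regions,
    exclude_low_coverage_rois,
    n_edges,
    parcellate,
    region_pair_to_index,
    unvectorize,
    vectorize_upper,
)


class TestParcellate:
    def test_single_voxel_regions_reorder_rows(self, rng):
        x = rng.standard_normal((4, 10))
        labels = {0: 30, 1: 10, 2: 40, 3: 20}
        ts = parcellate(x, labels)
        assert ts.region_ids == [10, 20, 30, 40]
        np.testing.assert_array_equal(ts.values, x[[1, 3, 0, 2]])

    def test_constant_voxels_average(self):
        x = np.vstack([np.ones(5), 3 * np.ones(5), np.zeros(5)])
        ts = parcellate(x, {0: 1, 1: 1, 2: 2})
        np.testing.assert_array_equal(ts.values[0], 2 * np.ones(5))

    def test_matches_bruteforce_region_means(self, rng):
        x = rng.standard_normal((20, 15))
        labels = {v: int(rng.integers(5)) for v in range(20)}
        ts = parcellate(x, labels)
        for row, region in enumerate(ts.region_ids):
            members = [v for v, lab in labels.items() if lab == region]
            expected = sum(x[v] for v in members) / len(members)
            np.testing.assert_allclose(ts.values[row], expected)

    def test_unlabeled_voxel_index_rejected(self, rng):
        with pytest.raises(ValueError, match="outside"):
            parcellate(rng.standard_normal((3, 5)), {0: 1, 5: 2})


class TestComputeFc:
    def test_affine_dependence_gives_unit_correlation(self, rng):
        base = rng.standard_normal(30)
        ts = RegionalTimeSeries(np.vstack([base, 2 * base + 1]), [0, 1])
        np.testing.assert_allclose(compute_fc(ts)[0, 1], 1.0)

    def test_negated_row_gives_minus_one(self, rng):
        base = rng.standard_normal(30)
        ts = RegionalTimeSeries(np.vstack([base, -base]), [0, 1])
        np.testing.assert_allclose(compute_fc(ts)[0, 1], -1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.standard_normal((4, 50))
        corr = compute_fc(RegionalTimeSeries(x, list(range(4))))
        for i in range(4):
            for j in range(4):
                cov = np.mean((x[i] - x[i].mean()) * (x[j] - x[j].mean()))
                expected = cov / (x[i].std() * x[j].std())
                np.testing.assert_allclose(corr[i, j], expected, atol=1e-12)

    def test_zero_variance_region_zeroed_with_warning(self, rng, caplog):
        x = rng.standard_normal((3, 20))
        x[1] = 5.0
        with caplog.at_level("WARNING"):
            corr = compute_fc(RegionalTimeSeries(x, [0, 1, 2]))
        assert "zero-variance" in caplog.text
        assert corr[1, 0] == corr[0, 1] == corr[1, 2] == 0.0
        assert corr[1, 1] == 1.0
        assert np.isfinite(corr).all()

    def test_valid_correlation_matrix_when_overdetermined(self, rng):
        x = rng.standard_normal((6, 40))
        corr = compute_fc(RegionalTimeSeries(x, list(range(6))))
        assert np.linalg.eigvalsh(corr).min() >= -1e-8

    def test_too_few_timepoints_rejected(self, rng):
        with pytest.raises(ValueError, match="3 timepoints"):
            compute_fc(RegionalTimeSeries(rng.standard_normal((3, 2)), [0, 1, 2]))


class TestVectorizeUpper:
    @pytest.mark.parametrize("r,expected", [(840, 352380), (116, 6670), (115, 6555)])
    def test_atlas_sized_feature_pools(self, r, expected):
        vec = vectorize_upper(np.eye(r))
        assert len(vec) == expected == n_edges(r)

    def test_smallest_case(self):
        vec = vectorize_upper(np.array([[1.0, 0.3], [0.3, 1.0]]))
        np.testing.assert_array_equal(vec.values, [0.3])

    def test_asymmetry_rejected(self):
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="asymmetry"):
            vectorize_upper(bad)

    def test_nonunit_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            vectorize_upper(0.5 * np.eye(3))

    def test_roundtrip_with_unvectorize(self, rng):
        x = rng.standard_normal((7, 30))
        corr = compute_fc(RegionalTimeSeries(x, list(range(7))))
        vec = vectorize_upper(corr)
        np.testing.assert_array_equal(vectorize_upper(unvectorize(vec)).values, vec.values)


class TestEdgeIndexing:
    def test_full_enumeration_r3(self):
        assert [edge_index_to_region_pair(k, 3) for k in range(3)] == [(0, 1), (0, 2), (1, 2)]

    def test_last_edge_of_craddock_pool(self):
        rows, cols = np.triu_indices(840, k=1)  # independent enumeration oracle
        assert edge_index_to_region_pair(352379, 840) == (rows[-1], cols[-1]) == (838, 839)

    @given(st.integers(min_value=0, max_value=n_edges(12) - 1))
    @settings(derandomize=True)
    def test_bijection_at_r12(self, k):
        i, j = edge_index_to_region_pair(k, 12)
        assert region_pair_to_index(i, j, 12) == k

    @given(st.integers(min_value=2, max_value=60), st.data())
    @settings(derandomize=True, max_examples=50)
    def test_matches_triu_enumeration(self, r, data):
        k = data.draw(st.integers(min_value=0, max_value=n_edges(r) - 1))
        rows, cols = np.triu_indices(r, k=1)
        assert edge_index_to_region_pair(k, r) == (rows[k], cols[k])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            edge_index_to_region_pair(3, 3)
        with pytest.raises(ValueError):
            region_pair_to_index(2, 1, 5)


def _vec(values, r, subject, task="rest"):
    return ConnectomeVector(np.asarray(values, float), r=r, subject_id=subject, task=task)


class TestAssemblePopulation:
    def test_single_subject(self):
        v = _vec([0.1, 0.2, 0.3], 3, "s1")
        M = assemble_population([v], ["s1"])
        assert M.values.shape == (3, 1)
        np.testing.assert_array_equal(M.values[:, 0], v.values)

    def test_column_order_follows_subject_order(self, rng):
        vecs = [_vec(rng.uniform(-1, 1, 3), 3, s) for s in ["a", "b", "c"]]
        M1 = assemble_population(vecs, ["a", "b", "c"])
        M2 = assemble_population(vecs, ["c", "a", "b"])
        np.testing.assert_array_equal(M2.values[:, 1], M1.values[:, 0])
        np.testing.assert_array_equal(M2.values[:, 0], M1.values[:, 2])

    def test_columns_recover_stored_vectors_bitwise(self, default_study, rest_matrix):
        for j, s in enumerate(rest_matrix.subject_ids[:5]):
            np.testing.assert_array_equal(
                rest_matrix.values[:, j], default_study.connectomes[(s, "rest")].values
            )

    def test_mixed_r_task_or_duplicate_rejected(self, rng):
        a = _vec(rng.uniform(-1, 1, 3), 3, "a")
        with pytest.raises(ValueError, match="mixed region counts"):
            assemble_population([a, _vec(rng.uniform(-1, 1, 6), 4, "b")], ["a", "b"])
        with pytest.raises(ValueError, match="mixed tasks"):
            assemble_population([a, _vec(rng.uniform(-1, 1, 3), 3, "b", task="smt")], ["a", "b"])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_population([a, _vec(rng.uniform(-1, 1, 3), 3, "a")], ["a"])


class TestCoverageExclusion:
    def test_uniform_intensity_excludes_nothing(self):
        images = np.ones((3, 12))
        labels = {v: v % 4 for v in range(12)}
        retained, excluded = exclude_low_coverage_rois(images, labels)
        assert excluded == []
        assert retained == [0, 1, 2, 3]

    def test_zero_intensity_region_excluded(self):
        images = np.ones((2, 10))
        labels = {v: (0 if v < 5 else 1) for v in range(10)}
        images[1, 5:] = 0.0  # region 1 dark in subject 1
        retained, excluded = exclude_low_coverage_rois(images, labels)
        assert excluded == [1]
        assert retained == [0]

    def test_matches_hand_computed_exclusion(self, rng):
        """100-voxel, 10-region instance checked against a direct per-subject
        per-region coverage loop."""
        images = rng.uniform(0.5, 2.0, size=(4, 100))
        labels = {v: v // 10 for v in range(100)}
        retained, excluded = exclude_low_coverage_rois(images, labels, 0.7, 0.5)
        expected_excluded = set()
        for region in range(10):
            voxels = [v for v in range(100) if labels[v] == region]
            for s in range(4):
                mask = images[s] > 0.7 * images[s].mean()
                coverage = np.mean([mask[v] for v in voxels])
                if coverage < 0.5:
                    expected_excluded.add(region)
        assert set(excluded) == expected_excluded
        assert sorted(retained + excluded) == list(range(10))

    def test_boundary_coverage_retained(self):
        # region 0: exactly half its voxels in the mask -> coverage 0.5, kept
        images = np.array([[1.0, 0.0, 1.0, 1.0]])
        labels = {0: 0, 1: 0, 2: 1, 3: 1}
        retained, excluded = exclude_low_coverage_rois(images, labels, mask_fraction=0.7)
        assert 0 in retained and excluded == []

    def test_edge_subset_drops_edges_touching_excluded(self):
        kept = edge_subset_for_regions([0, 2, 3], r=4)
        # canonical edges for r=4: (0,1) (0,2) (0,3) (1,2) (1,3) (2,3)
        np.testing.assert_array_equal(kept, [1, 2, 5])
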