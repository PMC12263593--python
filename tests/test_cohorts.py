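"""Age-cohort partitioning, per-cohort selection, intersection matrices
and consensus features."""

import numpy as np
import pandas as pd
import pytest

from connectoprint.cohorts import (
    consensus_features,
    consensus_regions,
    intersection_matrix,
    mean_offdiagonal,
    partition_cohorts,
    per_cohort_selection,
)
from connectoprint.fc import edge_index_to_region_pair, n_edges
from connectoprint.leverage import FeatureSet, leverage_scores, sample_random_features, select_top_k


def _metadata(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"s{j:04d}" for j in range(n)],
            "age": rng.uniform(18, 88, n),
            "sex": ["M" if j % 2 else "F" for j in range(n)],
        }
    )


def _fs(indices, m=1000):
    return FeatureSet(indices=np.asarray(list(indices), int), m=m)


class TestPartitionCohorts:
    def test_two_cohorts_are_age_ordered(self):
        cohorts = partition_cohorts(_metadata(100), cohort_size=50)
        assert [len(c) for c in cohorts] == [50, 50]
        assert cohorts[0].age_max <= cohorts[1].age_min

    def test_remainder_dropped_by_default(self):
        cohorts = partition_cohorts(_metadata(652), cohort_size=50)
        assert len(cohorts) == 13
        assert sum(len(c) for c in cohorts) == 650

    def test_remainder_merged_into_last(self):
        cohorts = partition_cohorts(_metadata(652), cohort_size=50, remainder_policy="merge_last")
        assert len(cohorts) == 13
        assert len(cohorts[-1]) == 52

    def test_stratified_partition_filters_sex(self):
        cohorts = partition_cohorts(_metadata(100), cohort_size=20, stratum="M")
        assert all(c.stratum == "M" for c in cohorts)
        assert sum(len(c) for c in cohorts) == 40  # 50 males -> 2 full cohorts of 20

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="fewer subjects"):
            partition_cohorts(_metadata(10), cohort_size=50)

    def test_age_sort_is_deterministic_under_ties(self):
        meta = _metadata(8)
        meta["age"] = 40.0  # all tied: order falls back to subject_id
        cohorts = partition_cohorts(meta, cohort_size=4)
        assert cohorts[0].subject_ids == sorted(meta["subject_id"])[:4]


class TestPerCohortSelection:
    def test_single_cohort_equals_global_selection(self, default_study, rest_matrix):
        cohorts = partition_cohorts(default_study.metadata, cohort_size=len(rest_matrix.subject_ids))
        [fs] = per_cohort_selection(rest_matrix, cohorts, k=80)
        global_fs = select_top_k(leverage_scores(rest_matrix), 80)
        np.testing.assert_array_equal(fs.indices, global_fs.indices)

    def test_duplicated_cohort_gives_identical_sets(self, default_study, rest_matrix):
        cohorts = partition_cohorts(default_study.metadata, cohort_size=50)
        sets = per_cohort_selection(rest_matrix, cohorts + cohorts, k=60)
        np.testing.assert_array_equal(sets[0].indices, sets[2].indices)
        np.testing.assert_array_equal(sets[1].indices, sets[3].indices)

    def test_cohorts_recover_planted_signature(self):
        """Each cohort's top-k set is dominated by the planted fingerprint
        edges (>= 50% at k = n_signature_edges, 10 seeds)."""
        from connectoprint.synthetic import SimulationConfig, generate_study

        fractions = []
        for seed in range(10):
            study = generate_study(SimulationConfig(seed=seed))
            M = study.population_matrix("rest")
            cohorts = partition_cohorts(study.metadata, cohort_size=20)
            sets = per_cohort_selection(M, cohorts, k=study.config.n_signature_edges)
            truth = set(study.truth["signature_edges"].tolist())
            for fs in sets:
                fractions.append(len(fs.as_set() & truth) / fs.k)
        assert min(fractions) >= 0.5


class TestIntersectionMatrix:
    def test_identical_sets_all_hundred(self):
        mat = intersection_matrix([_fs(range(10)), _fs(range(10))])
        np.testing.assert_allclose(mat.values, 100.0)

    def test_disjoint_sets_zero_offdiagonal(self):
        mat = intersection_matrix([_fs(range(10)), _fs(range(10, 20))])
        assert mat.values[0, 1] == 0.0
        assert mat.values[0, 0] == 100.0

    def test_half_overlap_is_fifty_percent(self):
        mat = intersection_matrix([_fs(range(1, 11)), _fs(range(6, 16))])
        assert mat.values[0, 1] == pytest.approx(50.0)

    def test_unequal_k_rejected(self):
        with pytest.raises(ValueError, match="unequal sizes"):
            intersection_matrix([_fs(range(10)), _fs(range(5))])

    def test_self_intersection_idempotent(self):
        mat = intersection_matrix([_fs(range(7))] * 3)
        np.testing.assert_allclose(mat.values, 100.0)


class TestMeanOffdiagonal:
    def _mat(self, values):
        c = values.shape[0]
        from connectoprint.cohorts import IntersectionMatrix

        return IntersectionMatrix(values, [f"c{i}" for i in range(c)], "rest", 10)

    def test_uniform_offdiagonal_same_either_scope(self):
        v = np.full((3, 3), 40.0)
        np.fill_diagonal(v, 100.0)
        mat = self._mat(v)
        assert mean_offdiagonal(mat, "consecutive") == 40.0
        assert mean_offdiagonal(mat, "all_pairs") == 40.0

    def test_consecutive_uses_superdiagonal_only(self):
        v = np.full((3, 3), 100.0)
        v[0, 1] = v[1, 0] = 50.0
        v[1, 2] = v[2, 1] = 30.0
        v[0, 2] = v[2, 0] = 10.0
        mat = self._mat(v)
        assert mean_offdiagonal(mat, "consecutive") == 40.0
        assert mean_offdiagonal(mat, "all_pairs") == 30.0

    def test_random_sets_match_hypergeometric_null_scale(self):
        """Mean pairwise intersection of random subsets equals 100*k/m on
        average (10% of a 1,000-feature pool here)."""
        rng = np.random.default_rng(0)
        m, k = 1000, 100
        sets = [sample_random_features(m, k, rng=rng) for _ in range(30)]
        mat = intersection_matrix(sets)
        observed = mean_offdiagonal(mat, "all_pairs")
        assert abs(observed - 100 * k / m) < 1.0


class TestConsensus:
    def test_identical_sets_return_the_set(self):
        fs = _fs(range(5))
        out = consensus_features([fs, fs, fs])
        np.testing.assert_array_equal(out.indices, fs.indices)
        assert out.provenance == "consensus"

    def test_one_disjoint_set_empties_consensus(self, caplog):
        with caplog.at_level("WARNING"):
            out = consensus_features([_fs(range(5)), _fs(range(10, 15))])
        assert out.k == 0
        assert "empty" in caplog.text

    def test_consensus_precision_on_planted_signature(self):
        """Consensus across synthetic cohorts is almost entirely planted
        fingerprint edges (precision >= 0.8 over 10 seeds)."""
        from connectoprint.synthetic import SimulationConfig, generate_study

        precisions = []
        for seed in range(10):
            study = generate_study(SimulationConfig(seed=seed))
            M = study.population_matrix("rest")
            cohorts = partition_cohorts(study.metadata, cohort_size=20)
            sets = per_cohort_selection(M, cohorts, k=study.config.n_signature_edges)
            cons = consensus_features(sets)
            truth = set(study.truth["signature_edges"].tolist())
            precisions.append(len(cons.as_set() & truth) / max(cons.k, 1))
        assert np.mean(precisions) >= 0.8


class TestStabilityInvariants:
    def test_stability_exceeds_random_null_without_drift(self):
        """With no age drift and default noise, the all-pairs mean
        intersection beats the random-subset null level (100*k/m) by a wide
        margin (>= 10 percentage points)."""
        from connectoprint.synthetic import SimulationConfig, generate_study

        study = generate_study(SimulationConfig(seed=4, n_drift_edges=0))
        M = study.population_matrix("rest")
        cohorts = partition_cohorts(study.metadata, cohort_size=20)
        k = study.config.n_signature_edges
        mat = intersection_matrix(per_cohort_selection(M, cohorts, k))
        null_level = 100 * k / M.m
        assert mean_offdiagonal(mat, "all_pairs") >= null_level + 10

    def test_sex_stratified_run_uses_same_machinery(self, default_study, rest_matrix):
        """Stratified analyses are plain metadata filters: the intersection
        matrix of a male-only partition satisfies the same invariants."""
        cohorts = partition_cohorts(default_study.metadata, cohort_size=20, stratum="M")
        sets = per_cohort_selection(rest_matrix, cohorts, k=50)
        mat = intersection_matrix(sets, [c.label for c in cohorts])
        assert np.allclose(np.diag(mat.values), 100.0)
        assert np.allclose(mat.values, mat.values.T)
        assert mat.values.min() >= 0 and mat.values.max() <= 100


class TestConsensusRegions:
    def test_single_edge_counts_both_endpoints(self):
        fs = _fs([0], m=n_edges(5))  # edge 0 = (0, 1) at any r
        assert consensus_regions(fs, r=5) == {0: 1, 1: 1}

    def test_shared_endpoint_accumulates(self):
        # edges (0,1) and (0,2) for r=5 are indices 0 and 1
        fs = _fs([0, 1], m=n_edges(5))
        counts = consensus_regions(fs, r=5)
        assert counts[0] == 2 and counts[1] == 1 and counts[2] == 1

    def test_matches_bruteforce_tally(self, rng):
        r = 20
        fs = _fs(rng.choice(n_edges(r), 30, replace=False), m=n_edges(r))
        counts = consensus_regions(fs, r)
        expected: dict = {}
        for k in fs.indices:
            i, j = edge_index_to_region_pair(int(k), r)
            expected[i] = expected.get(i, 0) + 1
            expected[j] = expected.get(j, 0) + 1
        assert counts == expected
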