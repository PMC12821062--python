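"""Stability metrics, model filtering, co-assignment/PAC, consensus cuts
and centroid merging — hand-computed cases plus structural properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from phenostable.stability import (
    ConsensusMatrix,
    StabilityReport,
    coassignment_matrix,
    consensus_partition,
    filter_models,
    merge_to_coarse,
    pac,
    visit_accuracies,
)


class TestVisitAccuracies:
    def test_hand_enumeration(self):
        """First visits (A,B,A); follow-ups P1:(A,A,B), P2:(B), P3:(A,A):
        visit-wise 5/6, patient-wise mean(2/3, 1, 1) = 8/9."""
        vw, pw = visit_accuracies(
            {"P1": 0, "P2": 1, "P3": 0},
            {"P1": [0, 0, 1], "P2": [1], "P3": [0, 0]},
        )
        assert vw == pytest.approx(5 / 6)
        assert pw == pytest.approx(8 / 9)

    def test_perfect_agreement(self):
        vw, pw = visit_accuracies({"a": 2, "b": 3}, {"a": [2, 2], "b": [3]})
        assert vw == 1.0 and pw == 1.0

    def test_no_followups_undefined(self):
        with pytest.raises(ValueError):
            visit_accuracies({"a": 0}, {})

    def test_unknown_patient_rejected(self):
        with pytest.raises(KeyError):
            visit_accuracies({"a": 0}, {"b": [0]})


class TestFilterModels:
    def _reports(self, accs):
        return [StabilityReport(i, a, a) for i, a in enumerate(accs)]

    def test_arithmetic_threshold(self):
        """Accuracies (.62,.60,.56,.50), retention .9: threshold .558 keeps
        the three models at .62, .60 and .56 (0.560 > 0.558)."""
        reports = self._reports([0.62, 0.60, 0.56, 0.50])
        kept = filter_models(reports, 0.9)
        assert reports[0].threshold_used == pytest.approx(0.558)
        assert kept == [0, 1, 2]

    def test_all_equal_all_kept(self):
        assert filter_models(self._reports([0.4] * 5), 0.9) == list(range(5))

    def test_single_model_kept(self):
        assert filter_models(self._reports([0.1]), 0.9) == [0]

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_never_empties_ensemble(self, accs):
        assert len(filter_models(self._reports(accs), 0.9)) >= 1


class TestCoassignment:
    def test_hand_count(self):
        cm = coassignment_matrix(
            [np.array([1, 1, 2]), np.array([1, 2, 2])], ["a", "b", "c"]
        )
        assert cm.M[0, 1] == 0.5
        assert cm.M[0, 2] == 0.0
        assert cm.M[1, 2] == 0.5

    def test_single_labeling_binary(self):
        cm = coassignment_matrix([np.array([1, 2, 1])], ["a", "b", "c"])
        assert set(np.unique(cm.M)) <= {0.0, 1.0}

    def test_repeated_labeling_idempotent(self):
        lab = np.array([1, 2, 2, 3])
        m1 = coassignment_matrix([lab], list("abcd")).M
        mk = coassignment_matrix([lab] * 7, list("abcd")).M
        np.testing.assert_array_equal(m1, mk)

    def test_entries_multiples_of_inverse_count(self):
        rng = np.random.default_rng(0)
        labelings = [rng.integers(0, 3, size=8) for _ in range(5)]
        cm = coassignment_matrix(labelings, [f"p{i}" for i in range(8)])
        np.testing.assert_allclose(cm.M, cm.M.T)
        scaled = cm.M * 5
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-12)

    def test_mismatched_length_rejected(self):
        with pytest.raises(ValueError):
            coassignment_matrix([np.array([1, 2])], ["a", "b", "c"])


def matrix_from_upper(vals):
    """Build a 4x4 consensus matrix with the given 6 upper-triangle values."""
    M = np.eye(4)
    iu = np.triu_indices(4, k=1)
    M[iu] = vals
    M[(iu[1], iu[0])] = vals
    return ConsensusMatrix(M=M, patient_ids=list("abcd"), n_models_used=100)


class TestPAC:
    def test_strict_bounds_hand_count(self):
        """Pairs (1.0, 0.0, 0.5, 0.89, 0.10, 0.90): only 0.5 and 0.89 lie
        strictly inside (0.1, 0.9) -> PAC 2/6."""
        cm = matrix_from_upper([1.0, 0.0, 0.5, 0.89, 0.10, 0.90])
        assert pac(cm) == pytest.approx(2 / 6)

    def test_unanimous_consensus_zero(self):
        cm = coassignment_matrix([np.array([1, 1, 2])] * 4, list("abc"))
        assert pac(cm) == 0.0

    def test_invalid_bounds(self):
        cm = matrix_from_upper([0.5] * 6)
        with pytest.raises(ValueError):
            pac(cm, 0.9, 0.1)


class TestConsensusPartition:
    def test_two_perfect_blocks(self):
        labelings = [np.array([1, 1, 1, 2, 2])] * 3
        cm = coassignment_matrix(labelings, list("abcde"))
        labels = consensus_partition(cm, 2)
        assert adjusted_rand_score(labels, [1, 1, 1, 2, 2]) == 1.0
        # labels ordered by decreasing size
        assert (labels[:3] == 1).all()

    def test_k_equals_n_singletons(self):
        cm = coassignment_matrix([np.array([1, 2, 3])], list("abc"))
        assert len(set(consensus_partition(cm, 3))) == 3

    def test_three_noisy_blocks_recovered(self):
        """Within-block co-assignment 0.9, between 0.1 (n=30): every
        within-block dissimilarity (0.1) is below every between-block one
        (0.9), so average linkage must merge blocks first; ARI 1.0."""
        truth = np.repeat([0, 1, 2], 10)
        M = np.where(truth[:, None] == truth[None, :], 0.9, 0.1)
        np.fill_diagonal(M, 1.0)
        cm = ConsensusMatrix(M=M, patient_ids=[f"p{i}" for i in range(30)], n_models_used=10)
        labels = consensus_partition(cm, 3)
        assert adjusted_rand_score(labels, truth) == 1.0

    def test_invariant_to_patient_reordering(self):
        rng = np.random.default_rng(1)
        labelings = [rng.integers(0, 3, size=12) for _ in range(6)]
        ids = [f"p{i}" for i in range(12)]
        cm = coassignment_matrix(labelings, ids)
        labels = consensus_partition(cm, 3)
        perm = rng.permutation(12)
        cm_p = coassignment_matrix([l[perm] for l in labelings], [ids[i] for i in perm])
        labels_p = consensus_partition(cm_p, 3)
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_k_too_large_rejected(self):
        cm = coassignment_matrix([np.array([1, 2])], list("ab"))
        with pytest.raises(ValueError):
            consensus_partition(cm, 3)


class TestMergeToCoarse:
    def test_closest_pair_merged(self):
        fine = np.array([1, 2, 3])
        X = np.array([[0.0], [1.0], [10.0]])
        merged = merge_to_coarse(fine, X, 2)
        assert merged.merge_map[1] == merged.merge_map[2] != merged.merge_map[3]

    def test_identity_when_target_equals_fine(self):
        fine = np.array([1, 2, 3])
        X = np.array([[0.0], [5.0], [10.0]])
        merged = merge_to_coarse(fine, X, 3)
        assert sorted(merged.merge_map.values()) == [1, 2, 3]
        # identity as a partition: each fine cluster its own coarse cluster
        assert len(set(merged.merge_map.values())) == 3

    def test_weighted_agglomeration_by_hand(self):
        """Centroids (0,2,3,10), unit sizes, target 2: (2,3)->2.5 then
        (0,2.5)->5/3, leaving partition {{0,2,3},{10}}."""
        fine = np.array([1, 2, 3, 4])
        X = np.array([[0.0], [2.0], [3.0], [10.0]])
        merged = merge_to_coarse(fine, X, 2)
        g1 = {merged.merge_map[1], merged.merge_map[2], merged.merge_map[3]}
        assert len(g1) == 1
        assert merged.merge_map[4] not in g1

    def test_coarse_labels_consistent_with_map(self):
        fine = np.array([1, 1, 2, 3, 3])
        X = np.array([[0.0], [0.1], [0.2], [9.0], [9.1]])
        merged = merge_to_coarse(fine, X, 2)
        for f, c in zip(merged.fine_labels, merged.coarse_labels):
            assert merged.merge_map[int(f)] == c

    def test_bad_target_rejected(self):
        fine = np.array([1, 2])
        X = np.zeros((2, 1))
        with pytest.raises(ValueError):
            merge_to_coarse(fine, X, 0)
        with pytest.raises(ValueError):
            merge_to_coarse(fine, X, 3)


class TestPacSeparationTrend:
    def test_pac_decreases_with_separation(self):
        """Better-separated planted blobs yield less ambiguous ensembles."""
        from phenostable.gemini import run_ensemble
        from phenostable.preprocess import FeatureMatrix, apply_scaler, fit_scaler

        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1, 2], 30)
        base = rng.normal(size=(90, 8))
        pacs = []
        for sep in (1.0, 6.0):
            X = base.copy()
            X[:, :3] += sep * np.eye(3)[labels]
            fm = FeatureMatrix(
                values=X,
                feature_names=[f"f{j}" for j in range(8)],
                variable_of=[f"f{j}" for j in range(8)],
                patient_ids=[f"p{i}" for i in range(90)],
                visit_indices=np.zeros(90, dtype=int),
            )
            fm = apply_scaler(fm, fit_scaler(fm))
            ens = run_ensemble(fm, fm, n_models=6, n_clusters=3, base_seed=0)
            cm = coassignment_matrix([a.hard for a in ens.df_assignments], fm.patient_ids)
            pacs.append(pac(cm))
        assert pacs[1] < pacs[0]
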