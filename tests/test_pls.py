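import numpy as np
import pytest

import socialpls as sp
from socialpls.pls import (
    MeanCenteredPLS,
    build_mean_centered_matrix,
    compute_brain_scores,
    crossblock_covariance_pct,
    decompose,
)
from conftest import make_subjects


class TestMeanCenteredMatrix:
    def test_identical_cells_center_to_zero(self):
        m = np.ones((4, 2))
        subs = make_subjects([m, m], ["young", "older"], ["a", "b"])
        stacked = build_mean_centered_matrix(subs)
        np.testing.assert_allclose(stacked.data, 0.0)

    def test_two_cell_symmetry(self):
        subs = make_subjects(
            [np.array([[1.0, 3.0]])], ["young"], ["a", "b"]
        )
        stacked = build_mean_centered_matrix(subs)
        np.testing.assert_allclose(stacked.data[:, 0], [-1.0, 1.0])

    def test_hand_centering_3x2(self):
        # one group, three conditions, two voxels
        m = np.array([[1.0, 2.0, 6.0], [0.0, 3.0, 3.0]])
        subs = make_subjects([m], ["g"], ["a", "b", "c"])
        stacked = build_mean_centered_matrix(subs)
        expected = np.array([[-2.0, -2.0], [-1.0, 1.0], [3.0, 1.0]])
        np.testing.assert_allclose(stacked.data, expected)

    def test_columns_sum_to_zero_after_centering(self, analysis_subjects):
        stacked = build_mean_centered_matrix(analysis_subjects)
        np.testing.assert_allclose(
            stacked.data.sum(axis=0), 0.0, atol=1e-9
        )

    def test_missing_cell_named(self):
        subs = make_subjects(
            [np.ones((2, 2)), np.ones((2, 2))], ["young", "young"], ["a", "b"]
        )
        # forge a subject claiming an unseen group ordering problem:
        subs[1] = sp.SubjectActivity("x", "older", ("a", "b"), np.ones((2, 2)))
        stacked = build_mean_centered_matrix(subs)  # both cells populated: fine
        assert len(stacked.cells) == 4


class TestDecompose:
    def test_rank_one_all_covariance_on_lv1(self):
        u = np.array([1.0, -1.0])[:, None]
        v = np.ones((1, 5))
        dec = decompose(u @ v)
        pct = dec.covariance_pct
        assert pct[0] == pytest.approx(100.0)
        np.testing.assert_allclose(pct[1:], 0.0, atol=1e-9)

    def test_known_singular_values_2x2(self):
        m = np.diag([2.0, 1.0])
        dec = decompose(m)
        np.testing.assert_allclose(dec.singular_values, [2.0, 1.0])
        np.testing.assert_allclose(dec.covariance_pct, [80.0, 20.0])

    def test_oracle_equivalence_random_matrix(self):
        """SVD agrees with an eigendecomposition of M M^T (brute-force oracle)."""
        rng = np.random.default_rng(0)
        m = rng.normal(size=(6, 50))
        dec = decompose(m)
        evals, evecs = np.linalg.eigh(m @ m.T)
        oracle_s = np.sqrt(np.clip(evals[::-1], 0, None))
        np.testing.assert_allclose(dec.singular_values, oracle_s, atol=1e-10)
        recon = (
            dec.design_saliences
            @ np.diag(dec.singular_values)
            @ dec.voxel_saliences.T
        )
        assert np.abs(recon - m).max() < 1e-8

    def test_salience_columns_orthonormal(self, fitted_task_pls):
        V = fitted_task_pls.voxel_saliences
        U = fitted_task_pls.design_saliences
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
        np.testing.assert_allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-8)

    def test_singular_values_non_increasing(self, fitted_task_pls):
        s = fitted_task_pls.singular_values
        assert np.all(np.diff(s) <= 1e-12)

    def test_sign_convention_largest_design_salience_positive(self):
        rng = np.random.default_rng(3)
        dec = decompose(rng.normal(size=(5, 20)))
        for k in range(dec.singular_values.size):
            col = dec.design_saliences[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            decompose(np.array([[1.0, np.nan]]))


class TestCovariancePct:
    @pytest.mark.parametrize(
        "s, expected",
        [
            ([1.0, 0.0, 0.0], [100.0, 0.0, 0.0]),
            ([2.0, 1.0], [80.0, 20.0]),
            ([1.0, 1.0, 1.0, 1.0], [25.0] * 4),
        ],
    )
    def test_known_values(self, s, expected):
        np.testing.assert_allclose(crossblock_covariance_pct(s), expected)

    def test_sums_to_100(self, fitted_task_pls):
        assert fitted_task_pls.covariance_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            crossblock_covariance_pct([0.0, 0.0])


class TestBrainScores:
    def test_one_hot_salience_projects_single_voxel(self):
        subs = make_subjects(
            [np.array([[1.0], [7.0], [3.0]])], ["g"], ["a"]
        )
        V = np.zeros((3, 1))
        V[1, 0] = 1.0
        scores = compute_brain_scores(V, subs)
        assert scores[0, 0, 0] == pytest.approx(7.0)

    def test_hand_dot_product(self):
        subs = make_subjects([np.array([[1.0], [2.0], [0.0]])], ["g"], ["a"])
        V = np.array([[0.6], [0.8], [0.0]])
        assert compute_brain_scores(V, subs)[0, 0, 0] == pytest.approx(2.2)

    def test_dimension_mismatch_rejected(self):
        subs = make_subjects([np.ones((4, 1))], ["g"], ["a"])
        with pytest.raises(ValueError, match="voxels"):
            compute_brain_scores(np.ones((3, 1)), subs)


class TestModelInvariances:
    def test_constant_shift_leaves_model_unchanged(self, analysis_subjects):
        """Grand-mean centering absorbs any constant added everywhere."""
        base = MeanCenteredPLS(analysis_subjects).fit(n_perm=0, n_boot=0)
        shifted_subs = [
            sp.SubjectActivity(s.subject_id, s.group, s.conditions, s.matrix + 11.5)
            for s in analysis_subjects
        ]
        shifted = MeanCenteredPLS(shifted_subs).fit(n_perm=0, n_boot=0)
        np.testing.assert_allclose(
            base.singular_values, shifted.singular_values, atol=1e-8
        )
        np.testing.assert_allclose(
            base.voxel_saliences[:, :2], shifted.voxel_saliences[:, :2], atol=1e-6
        )

    def test_lv_count_is_cells_minus_one(self, fitted_task_pls):
        s = fitted_task_pls.singular_values
        n_cells = len(fitted_task_pls.cells)
        assert np.sum(s > 1e-8 * s[0]) == n_cells - 1

    def test_planted_salience_recovery(self, default_dataset, fitted_task_pls):
        """Estimated LV1/LV2 voxel saliences match the planted patterns."""
        nv = default_dataset.n_voxels
        for k, eff in enumerate(default_dataset.truth):
            pat = eff.pattern(nv)
            r = np.corrcoef(fitted_task_pls.voxel_saliences[:, k], pat)[0, 1]
            assert abs(r) > 0.9

    def test_summary_mentions_lvs_and_pvalues(self, fitted_task_pls):
        text = fitted_task_pls.summary()
        assert "cov %" in text and "permutations: 50" in text

    def test_score_cis_bracket_cell_means(self, fitted_task_pls):
        means = fitted_task_pls.cell_mean_scores()[:, 0]
        cis = fitted_task_pls.score_cis[:, 0, :]
        # planted LV1: intervals should be near the cell means and ordered
        assert np.all(cis[:, 0] <= cis[:, 1])
        inside = (means >= cis[:, 0] - 1) & (means <= cis[:, 1] + 1)
        assert inside.all()
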