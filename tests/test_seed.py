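import logging

import numpy as np
import pytest

import socialpls as sp
from socialpls.design import CONDITIONS, generate_design
from socialpls.seed import (
    SeedPLS,
    SeedSpec,
    build_seed_correlation_matrix,
    correlation_map_per_cell,
    default_seed_table,
    extract_seed_activity,
    lv_seed_correlations,
    seed_decompose,
)
from socialpls.simulate import plant_seed_coupling, simulate_dataset
from conftest import make_subjects


class TestSeedSpec:
    def test_interior_peak_has_27_voxels(self, space):
        seed = SeedSpec.from_peak(space, ijk=(5, 6, 9), name="dmpfc")
        assert seed.neighborhood.size == 27

    def test_corner_peak_clipped_with_warning(self, caplog):
        small = sp.default_space((2, 2, 2))
        with caplog.at_level(logging.WARNING):
            seed = SeedSpec.from_peak(small, ijk=(0, 0, 0), name="corner")
        assert seed.neighborhood.size == 8
        assert "outside the mask" in caplog.text

    def test_out_of_mask_peak_rejected(self, space):
        with pytest.raises(ValueError, match="outside the mask"):
            SeedSpec.from_peak(space, ijk=(50, 0, 0))

    def test_mm_seeds_resolve_in_default_space(self, space):
        """Both shipped medial-PFC seeds fall inside the synthetic grid."""
        for _, row in default_seed_table().iterrows():
            seed = SeedSpec.from_peak(
                space, mm=(row.x_mm, row.y_mm, row.z_mm), name=row["name"]
            )
            assert seed.neighborhood.size == 27


class TestSeedExtraction:
    def test_constant_neighborhood_returns_value(self, space):
        seed = SeedSpec.from_peak(space, ijk=(5, 6, 9))
        m = np.zeros((space.n_voxels, 2))
        m[seed.neighborhood, 0] = 4.5
        subs = make_subjects([m], ["g"], ["a", "b"])
        vals = extract_seed_activity(subs, seed)
        assert vals[0, 0] == pytest.approx(4.5)
        assert vals[0, 1] == pytest.approx(0.0)


class TestCorrelationMaps:
    def _subjects_with_voxel(self, voxel_vals, seed_like):
        subs = []
        for i, (v, s) in enumerate(zip(voxel_vals, seed_like)):
            m = np.zeros((10, 1))
            m[:3, 0] = s  # "seed" voxels 0..2
            m[5, 0] = v
            subs.append(
                sp.SubjectActivity(f"s{i}", "g", ("a",), m)
            )
        return subs

    def test_voxel_equal_to_seed_r1(self):
        seed_like = [1.0, 2.0, 3.0, 4.0]
        subs = self._subjects_with_voxel(seed_like, seed_like)
        vals = np.array([[s] for s in seed_like])
        r = correlation_map_per_cell(subs, vals, ("g", "a"))
        assert r[5] == pytest.approx(1.0)

    def test_voxel_negated_seed_r_minus1(self):
        seed_like = [1.0, 2.0, 3.0, 4.0]
        subs = self._subjects_with_voxel([-s for s in seed_like], seed_like)
        vals = np.array([[s] for s in seed_like])
        assert correlation_map_per_cell(subs, vals, ("g", "a"))[5] == pytest.approx(-1.0)

    def test_hand_pearson(self):
        subs = self._subjects_with_voxel([2, 1, 4, 3, 5], [1, 2, 3, 4, 5])
        vals = np.array([[s] for s in [1, 2, 3, 4, 5]], dtype=float)
        assert correlation_map_per_cell(subs, vals, ("g", "a"))[5] == pytest.approx(0.8)

    def test_zero_variance_maps_to_zero(self):
        subs = self._subjects_with_voxel([0, 0, 0], [1.0, 2.0, 3.0])
        vals = np.array([[s] for s in [1.0, 2.0, 3.0]])
        assert correlation_map_per_cell(subs, vals, ("g", "a"))[5] == 0.0

    def test_small_cell_rejected(self):
        subs = self._subjects_with_voxel([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            correlation_map_per_cell(subs, np.ones((2, 1)), ("g", "a"))

    def test_scale_invariance(self, analysis_subjects, space):
        seed = SeedSpec.from_peak(space, ijk=(5, 6, 9))
        a = build_seed_correlation_matrix(analysis_subjects[:10], seed)
        scaled = [
            sp.SubjectActivity(s.subject_id, s.group, s.conditions, 3.7 * s.matrix)
            for s in analysis_subjects[:10]
        ]
        b = build_seed_correlation_matrix(scaled, seed)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)


class TestSeedDecompose:
    def test_shared_pattern_is_rank_one(self):
        row = np.linspace(-1, 1, 30)
        stacked = np.tile(row, (6, 1))
        dec = seed_decompose(
            sp.StackedDataMatrix(
                cells=tuple(("g", str(i)) for i in range(6)),
                data=stacked, cell_means=stacked, grand_mean=row,
            )
        )
        assert dec.covariance_pct[0] == pytest.approx(100.0)

    def test_orthogonal_equal_norm_patterns_split_50_50(self):
        a = np.zeros(20)
        b = np.zeros(20)
        a[:5] = 1.0
        b[10:15] = 1.0
        stacked = np.stack([a, b])
        dec = seed_decompose(
            sp.StackedDataMatrix(
                cells=(("g", "x"), ("g", "y")),
                data=stacked, cell_means=stacked, grand_mean=stacked.mean(0),
            )
        )
        np.testing.assert_allclose(dec.covariance_pct, [50.0, 50.0], atol=1e-9)

    def test_oracle_equivalence_random_stack(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(10, 100))
        dec = seed_decompose(
            sp.StackedDataMatrix(
                cells=tuple(("g", str(i)) for i in range(10)),
                data=m, cell_means=m, grand_mean=m.mean(0),
            )
        )
        evals = np.linalg.eigvalsh(m @ m.T)[::-1]
        np.testing.assert_allclose(
            dec.singular_values, np.sqrt(np.clip(evals, 0, None)), atol=1e-10
        )


class TestLVSeedCorrelations:
    def test_scores_proportional_to_seed_give_r1(self, space):
        seed = SeedSpec.from_peak(space, ijk=(5, 6, 9))
        rng = np.random.default_rng(0)
        subs = []
        for i in range(8):
            m = np.zeros((space.n_voxels, 1))
            m[seed.neighborhood, 0] = rng.normal()
            subs.append(sp.SubjectActivity(f"s{i}", "g", ("a",), m))
        vals = extract_seed_activity(subs, seed)
        # salience concentrated on the seed: scores are affine in seed value
        V = np.zeros((space.n_voxels, 1))
        V[seed.neighborhood, 0] = 1.0
        out = lv_seed_correlations(V, subs, vals, n_boot=20, rng=0)
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_noise_r_small(self, space):
        rng = np.random.default_rng(1)
        n = 400
        seed = SeedSpec.from_peak(space, ijk=(5, 6, 9))
        subs = [
            sp.SubjectActivity(f"s{i}", "g", ("a",), rng.normal(size=(space.n_voxels, 1)))
            for i in range(n)
        ]
        vals = rng.normal(size=(n, 1))  # independent of any voxel
        V = np.zeros((space.n_voxels, 1))
        V[100, 0] = 1.0
        out = lv_seed_correlations(V, subs, vals, n_boot=10, rng=0)
        assert abs(out.iloc[0]["r"]) < 2 / np.sqrt(n) * 2


class TestPlantedCouplingRecovery:
    def test_planted_cell_recovered_with_expected_correlation(self):
        """Planted r=0.6 coupling in one cell: the matched LV's correlation is
        largest in that cell and sits in the Monte-Carlo-derived band."""
        design = generate_design(
            5, 14, 5, CONDITIONS, groups=(("young", 200),), rng=0
        )
        ds = simulate_dataset(
            design=design, effects=(), noise_sd=1.0, seed=80, behavioral=False
        )
        space = sp.default_space()
        seed = SeedSpec.from_peak(space, ijk=(5, 6, 9), name="s")
        targets = np.arange(1200, 1264)
        ds = plant_seed_coupling(ds, seed, targets, {("young", "partner"): 0.6}, rng=0)
        subs = sp.exclude_conditions(list(ds.subjects), ("famous",))
        res = SeedPLS(subs, seed).fit(n_perm=0, n_boot=0, n_boot_corr=20)
        pat = np.zeros(space.n_voxels)
        pat[targets] = 1.0
        match = [
            abs(np.corrcoef(res.voxel_saliences[:, j], pat)[0, 1]) for j in range(5)
        ]
        j = int(np.argmax(match))
        sc = res.seed_correlations
        lv = sc[sc.lv == j + 1]
        best = lv.loc[lv.r.abs().idxmax()]
        assert (best.group, best.condition) == ("young", "partner")
        assert 0.7 < abs(best.r) < 0.95

    def test_two_cell_coupling_dominates_lv1_over_targets(self):
        """Couplings planted in two cells: LV1 saliences express the planted
        pattern over the target voxels."""
        design = generate_design(
            5, 14, 5, CONDITIONS, groups=(("young", 100), ("older", 100)), rng=1
        )
        ds = simulate_dataset(
            design=design, effects=(), noise_sd=1.0, seed=81, behavioral=False
        )
        space = sp.default_space()
        seed = SeedSpec.from_peak(space, ijk=(5, 6, 9), name="s")
        t1, t2 = np.arange(1200, 1264), np.arange(980, 1044)
        ds = plant_seed_coupling(ds, seed, t1, {("young", "partner"): 0.6}, rng=1)
        ds = plant_seed_coupling(ds, seed, t2, {("older", "self"): 0.6}, rng=2)
        subs = sp.exclude_conditions(list(ds.subjects), ("famous",))
        res = SeedPLS(subs, seed).fit(n_perm=0, n_boot=0, n_boot_corr=10)
        union = np.concatenate([t1, t2])
        # over the planted support, the leading LVs carry the coupling
        mean_loading = max(
            abs(res.voxel_saliences[union, j]).mean()
            / abs(res.voxel_saliences[:, j]).mean()
            for j in range(3)
        )
        assert mean_loading > 3.0

    def test_control_condition_dropped_by_default(self, analysis_subjects, space):
        seed = SeedSpec.from_peak(space, ijk=(5, 6, 9))
        model = SeedPLS(analysis_subjects, seed)
        assert "control" not in model.conditions
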