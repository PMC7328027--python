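import numpy as np
import pandas as pd
import pytest

import socialpls as sp
from socialpls.design import CONDITIONS, default_design, generate_design
from socialpls.simulate import (
    TABLE1_TARGETS,
    PlantedEffect,
    default_effects,
    plant_seed_coupling,
    simulate_behavioral,
    simulate_dataset,
    simulate_subject_activity,
    simulate_subject_blocks,
)


@pytest.fixture(scope="module")
def design():
    return default_design(rng=0)


def test_contrast_must_sum_to_zero():
    with pytest.raises(ValueError, match="sum"):
        PlantedEffect("bad", np.array([0]), {("young", "self"): 1.0}, 1.0)


def test_noise_free_subject_equals_planted_pattern(design):
    eff = PlantedEffect(
        "e",
        np.array([2, 5]),
        {("young", "self"): 1.0, ("young", "control"): -1.0},
        amplitude=3.0,
    )
    rng = np.random.default_rng(0)
    s = simulate_subject_activity(design, (eff,), "young", 0.0, rng, n_voxels=10)
    expected = np.zeros((10, 7))
    j_self, j_ctrl = CONDITIONS.index("self"), CONDITIONS.index("control")
    expected[[2, 5], j_self] = 3.0
    expected[[2, 5], j_ctrl] = -3.0
    np.testing.assert_array_equal(s.matrix, expected)


def test_effect_absent_for_other_group(design):
    eff = PlantedEffect(
        "e", np.array([0]), {("young", "self"): 1.0, ("young", "control"): -1.0}, 2.0
    )
    rng = np.random.default_rng(0)
    s = simulate_subject_activity(design, (eff,), "older", 0.0, rng, n_voxels=4)
    np.testing.assert_array_equal(s.matrix, np.zeros((4, 7)))


def test_unknown_group_rejected(design):
    with pytest.raises(ValueError, match="group"):
        simulate_subject_activity(
            design, (), "middle", 1.0, np.random.default_rng(0), n_voxels=4
        )


def test_null_moments_recovered(design):
    """With no effects, per-voxel means ~0 and sds ~noise_sd over 1000 subjects."""
    rng = np.random.default_rng(5)
    mats = np.stack(
        [
            simulate_subject_activity(design, (), "young", 2.0, rng, 30).matrix
            for _ in range(1000)
        ]
    )
    assert np.all(np.abs(mats.mean(axis=0)) < 2.0 * 3 / np.sqrt(1000))
    assert np.all(np.abs(mats.std(axis=0) - 2.0) < 0.3)


def test_dataset_determinism():
    a = simulate_dataset(seed=11, mask_shape=(6, 6, 8))
    b = simulate_dataset(seed=11, mask_shape=(6, 6, 8))
    for sa, sb in zip(a.subjects, b.subjects):
        np.testing.assert_array_equal(sa.matrix, sb.matrix)
    pd.testing.assert_frame_equal(a.behavioral, b.behavioral)


def test_dataset_group_sizes_match_design():
    ds = simulate_dataset(seed=0, mask_shape=(6, 6, 8))
    assert len(ds.subjects_in("young")) == 29
    assert len(ds.subjects_in("older")) == 27


def test_default_effects_orthogonal_and_80_20():
    e1, e2 = default_effects(1728)
    assert not np.intersect1d(e1.voxel_indices, e2.voxel_indices).size
    w1 = np.array(list(e1.contrast.values()))
    w2 = [e1.contrast.get(c, 0.0) * w for c, w in e2.contrast.items()]
    assert abs(sum(w2)) < 1e-12  # cell contrasts orthogonal
    s1 = e1.amplitude * np.linalg.norm(w1) * np.sqrt(e1.voxel_indices.size)
    s2 = (
        e2.amplitude
        * np.linalg.norm(list(e2.contrast.values()))
        * np.sqrt(e2.voxel_indices.size)
    )
    np.testing.assert_allclose(100 * s1**2 / (s1**2 + s2**2), 80.0, atol=1e-9)


# -- behavioral simulation -------------------------------------------------


def test_behavioral_mean_recovery_large_n():
    rng = np.random.default_rng(0)
    df = simulate_behavioral(
        {"partner": 32.83}, {"partner": 6.80}, 10_000, (0, 40), rng
    )
    se = 6.80 / np.sqrt(10_000)
    # latent mean is calibrated so the clipped expectation hits the target
    assert abs(df["partner"].mean() - 32.83) < 3 * se
    assert df["partner"].between(0, 40).all()


def test_behavioral_sd_zero_is_constant():
    rng = np.random.default_rng(0)
    df = simulate_behavioral({"c": 5.0}, {"c": 0.0}, 50, (0, 40), rng)
    assert (df["c"] == 5.0).all()


def test_behavioral_zero_mean_at_bound_all_zero():
    rng = np.random.default_rng(0)
    df = simulate_behavioral({"acq": 0.0}, {"acq": 0.0}, 29, (0, 40), rng)
    assert (df["acq"] == 0.0).all()


def test_behavioral_mean_outside_bounds_rejected():
    with pytest.raises(ValueError, match="outside bounds"):
        simulate_behavioral({"c": 50.0}, {"c": 1.0}, 5, (0, 40), np.random.default_rng(0))


def test_behavioral_table_within_instrument_ranges():
    ds = simulate_dataset(seed=3, mask_shape=(6, 6, 8))
    t = ds.behavioral
    assert t.whoto_total.between(0, 40).all()
    assert t.ios.between(1, 7).all()
    assert set(t.group) == {"young", "older"}
    assert set(t.condition) == set(TABLE1_TARGETS["whoto_total"]["young"])


# -- block-level expansion -------------------------------------------------


def test_block_roundtrip_recovers_condition_matrix(design):
    rng = np.random.default_rng(2)
    subj = simulate_subject_activity(
        design, default_effects(1728), "young", 1.0, rng, 1728, "sub"
    )
    blocks = simulate_subject_blocks(design, subj, within_block_sd=0.0, rng=0)
    rebuilt = sp.average_condition_activity(blocks, design.conditions, group="young")
    np.testing.assert_allclose(rebuilt.matrix, subj.matrix, atol=1e-10)


# -- seed coupling ---------------------------------------------------------


def _seeded_dataset(n_per_group, seed, mask_shape=(12, 12, 12)):
    design = generate_design(
        5, 14, 5, CONDITIONS, groups=(("young", n_per_group),), rng=seed
    )
    return simulate_dataset(
        design=design, mask_shape=mask_shape, effects=(), noise_sd=1.0,
        seed=seed, behavioral=False,
    )


def test_coupling_r1_is_affine_map_of_seed(space=None):
    ds = _seeded_dataset(30, 0)
    sp_space = sp.default_space()
    seed = sp.SeedSpec.from_peak(sp_space, ijk=(5, 6, 9), name="s")
    ds2 = plant_seed_coupling(ds, seed, np.array([7]), {("young", "partner"): 1.0})
    j = CONDITIONS.index("partner")
    seed_vals = np.array([s.matrix[seed.neighborhood, j].mean() for s in ds2.subjects])
    voxel = np.array([s.matrix[7, j] for s in ds2.subjects])
    assert abs(np.corrcoef(seed_vals, voxel)[0, 1]) > 1 - 1e-9


def test_coupling_r0_near_zero_at_n400():
    ds = _seeded_dataset(400, 4, mask_shape=(6, 6, 8))
    sp_space = sp.default_space((6, 6, 8))
    seed = sp.SeedSpec.from_peak(sp_space, ijk=(3, 3, 4), name="s")
    ds2 = plant_seed_coupling(ds, seed, np.array([7]), {("young", "partner"): 0.0})
    j = CONDITIONS.index("partner")
    seed_vals = np.array([s.matrix[seed.neighborhood, j].mean() for s in ds2.subjects])
    voxel = np.array([s.matrix[7, j] for s in ds2.subjects])
    assert abs(np.corrcoef(seed_vals, voxel)[0, 1]) < 0.1


def test_coupling_r06_recovered_at_n500():
    ds = _seeded_dataset(500, 2, mask_shape=(6, 6, 8))
    sp_space = sp.default_space((6, 6, 8))
    seed = sp.SeedSpec.from_peak(sp_space, ijk=(3, 3, 4), name="s")
    ds2 = plant_seed_coupling(ds, seed, np.array([7, 9]), {("young", "partner"): 0.6})
    j = CONDITIONS.index("partner")
    seed_vals = np.array([s.matrix[seed.neighborhood, j].mean() for s in ds2.subjects])
    for v in (7, 9):
        voxel = np.array([s.matrix[v, j] for s in ds2.subjects])
        assert 0.5 < np.corrcoef(seed_vals, voxel)[0, 1] < 0.7


def test_coupling_rejects_invalid_r_and_overlap():
    ds = _seeded_dataset(10, 3, mask_shape=(6, 6, 8))
    sp_space = sp.default_space((6, 6, 8))
    seed = sp.SeedSpec.from_peak(sp_space, ijk=(3, 3, 4), name="s")
    with pytest.raises(ValueError, match="<= 1"):
        plant_seed_coupling(ds, seed, np.array([7]), {("young", "partner"): 1.5})
    with pytest.raises(ValueError, match="disjoint"):
        plant_seed_coupling(
            ds, seed, seed.neighborhood[:1], {("young", "partner"): 0.5}
        )
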