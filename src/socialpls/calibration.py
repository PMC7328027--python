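"""Validation studies on synthetic data: calibration and recovery rates.

These functions run the full analysis pipeline repeatedly against the
generator's ground truth and summarize how well inference behaves:

* permutation p-values under a null generator (uniformity),
* recovery of the two planted task latent variables at the study's
  sample sizes (29 + 27),
* bootstrap-ratio specificity/sensitivity at a known signal-to-noise,
* recovery of a planted seed-voxel coupling in seed PLS.

They are ordinary package functionality — the same checks a user should
run after changing the pipeline — and are what the acceptance machinery
executes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import exclude_conditions
from .design import CONDITIONS, generate_design
from .pls import MeanCenteredPLS
from .seed import SeedPLS, SeedSpec
from .simulate import PlantedEffect, plant_seed_coupling, simulate_dataset
from .space import default_space

__all__ = [
    "null_permutation_pvalues",
    "task_lv_recovery",
    "bsr_calibration",
    "seed_coupling_recovery",
    "TaskRecoveryResult",
    "BsrCalibrationResult",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(2 * n) % (2**31)][: 2 * n]


def null_permutation_pvalues(
    n_replicates: int = 200,
    n_perm: int = 100,
    mask_shape: tuple[int, int, int] = (5, 5, 8),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """LV1 permutation p-values over replicates of a no-effect generator.

    Under the null the observed singular value is exchangeable with the
    permuted ones, so these p-values should be (discretely) uniform.  A
    reduced voxel grid keeps the study cheap; the null distribution of the
    p-value does not depend on the grid size.
    """
    seeds = _child_seeds(seed, n_replicates)
    ps = np.empty(n_replicates)
    for i in range(n_replicates):
        ds = simulate_dataset(
            mask_shape=mask_shape,
            effects=(),
            noise_sd=noise_sd,
            seed=seeds[2 * i],
            behavioral=False,
        )
        subs = exclude_conditions(list(ds.subjects), ("famous",))
        res = MeanCenteredPLS(subs).fit(
            n_perm=n_perm, n_boot=0, rng=seeds[2 * i + 1]
        )
        ps[i] = res.p_values[0]
    return ps


@dataclass(frozen=True)
class TaskRecoveryResult:
    salience_correlations: np.ndarray  # (n_replicates, 2) |r| per planted LV
    p_values: np.ndarray  # (n_replicates, 2)
    covariance_pct: np.ndarray  # (n_replicates, 2)

    @property
    def recovery_rate(self) -> float:
        """Fraction of replicates with both LVs recovered (|r|>0.9, p<=0.05)."""
        ok = (self.salience_correlations > 0.9).all(axis=1) & (
            self.p_values <= 0.05
        ).all(axis=1)
        return float(ok.mean())


def task_lv_recovery(
    n_replicates: int = 50,
    n_perm: int = 100,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> TaskRecoveryResult:
    """Recover the two planted orthogonal LVs at the study sample sizes.

    The default generator plants a social-vs-control contrast and a
    young-only partner/self contrast with an 80/20 covariance split;
    recovery compares estimated voxel saliences against the planted
    patterns and checks permutation significance.
    """
    seeds = _child_seeds(seed, n_replicates)
    corrs = np.empty((n_replicates, 2))
    ps = np.empty((n_replicates, 2))
    pct = np.empty((n_replicates, 2))
    for i in range(n_replicates):
        ds = simulate_dataset(
            noise_sd=noise_sd, seed=seeds[2 * i], behavioral=False
        )
        subs = exclude_conditions(list(ds.subjects), ("famous",))
        res = MeanCenteredPLS(subs).fit(
            n_perm=n_perm, n_boot=0, rng=seeds[2 * i + 1]
        )
        for k, eff in enumerate(ds.truth):
            pat = eff.pattern(ds.n_voxels)
            corrs[i, k] = abs(
                np.corrcoef(res.voxel_saliences[:, k], pat)[0, 1]
            )
            ps[i, k] = res.p_values[k]
            pct[i, k] = res.covariance_pct[k]
    return TaskRecoveryResult(
        salience_correlations=corrs, p_values=ps, covariance_pct=pct
    )


def _bsr_effect(n_voxels: int, amplitude: float) -> PlantedEffect:
    contrast = {
        (g, "partner"): 1.0 for g in ("young", "older")
    }
    contrast.update({(g, "self"): 1.0 for g in ("young", "older")})
    contrast.update({(g, "parent_child"): -1.0 for g in ("young", "older")})
    contrast.update({(g, "friend"): -1.0 for g in ("young", "older")})
    start = n_voxels // 16
    return PlantedEffect(
        name="bsr_calibration",
        voxel_indices=np.arange(start, start + 64),
        contrast=contrast,
        amplitude=amplitude,
    )


@dataclass(frozen=True)
class BsrCalibrationResult:
    null_rates: np.ndarray  # per replicate, % of null voxels flagged on LV1
    sensitivities: np.ndarray  # per replicate, fraction of signal voxels flagged

    @property
    def null_rate_pct(self) -> float:
        return float(self.null_rates.mean())

    @property
    def sensitivity(self) -> float:
        return float(self.sensitivities.mean())


def bsr_calibration(
    n_replicates: int = 50,
    n_boot: int = 100,
    amplitude: float = 1.5,
    noise_sd: float = 1.0,
    cutoff: float = 2.58,
    seed: int = 0,
) -> BsrCalibrationResult:
    """Bootstrap-ratio specificity and sensitivity on LV1.

    One +/-1 cell contrast is planted on 64 voxels at
    ``amplitude / noise_sd`` signal-to-noise; the rate of null voxels with
    |BSR| above the cutoff should sit near the nominal two-tailed 1%, and
    planted voxels should essentially always be flagged.
    """
    seeds = _child_seeds(seed, n_replicates)
    null_rates = np.empty(n_replicates)
    sens = np.empty(n_replicates)
    for i in range(n_replicates):
        ds = simulate_dataset(
            effects=(_bsr_effect(12**3, amplitude),),
            noise_sd=noise_sd,
            seed=seeds[2 * i],
            behavioral=False,
        )
        subs = exclude_conditions(list(ds.subjects), ("famous",))
        res = MeanCenteredPLS(subs).fit(
            n_perm=0, n_boot=n_boot, rng=seeds[2 * i + 1]
        )
        bsr = res.bootstrap_ratios[:, 0]
        signal = np.zeros(ds.n_voxels, dtype=bool)
        signal[ds.truth[0].voxel_indices] = True
        finite = np.isfinite(bsr)
        null_rates[i] = 100.0 * np.mean(
            np.abs(bsr[~signal & finite]) >= cutoff
        )
        sens[i] = np.mean(np.abs(bsr[signal & finite]) >= cutoff)
    return BsrCalibrationResult(null_rates=null_rates, sensitivities=sens)


def seed_coupling_recovery(
    n_replicates: int = 50,
    n_per_group: int = 100,
    r: float = 0.6,
    n_targets: int = 64,
    seed: int = 0,
) -> float:
    """Rate at which a planted single-cell seed coupling is recovered.

    A coupling of strength ``r`` between a 27-voxel seed and a target
    region is planted in the (young, partner) cell only.  A replicate
    counts as recovered when, on the LV whose voxel saliences best match
    the planted pattern (among the first three), the planted cell carries
    the largest |brain-score x seed| correlation of all cells.
    """
    seeds = _child_seeds(seed, n_replicates)
    space = default_space()
    hits = 0
    for i in range(n_replicates):
        design = generate_design(
            5, 14, 5, CONDITIONS,
            groups=(("young", n_per_group), ("older", n_per_group)),
            rng=seeds[2 * i],
        )
        ds = simulate_dataset(
            design=design, effects=(), noise_sd=1.0,
            seed=seeds[2 * i], behavioral=False,
        )
        roi = SeedSpec.from_peak(space, ijk=(5, 6, 9), name="seed")
        targets = np.arange(1200, 1200 + n_targets)
        ds = plant_seed_coupling(
            ds, roi, targets, {("young", "partner"): r}, rng=seeds[2 * i + 1]
        )
        subs = exclude_conditions(list(ds.subjects), ("famous",))
        res = SeedPLS(subs, roi).fit(n_perm=0, n_boot=0, n_boot_corr=10)
        pat = np.zeros(space.n_voxels)
        pat[targets] = 1.0
        match = [
            abs(np.corrcoef(res.voxel_saliences[:, j], pat)[0, 1])
            for j in range(3)
        ]
        j = int(np.argmax(match))
        sc = res.seed_correlations
        lv = sc[sc.lv == j + 1]
        best = lv.loc[lv.r.abs().idxmax()]
        hits += (best.group, best.condition) == ("young", "partner")
    return hits / n_replicates
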