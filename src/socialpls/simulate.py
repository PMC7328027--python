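"""Synthetic behavioral and voxel-level data with planted latent structure.

No subject-level scan data exist for this task, so analyses are exercised
against a generator that emulates the statistical structure the pipeline
assumes: two age cohorts (young n=29, older n=27), per-subject voxel x
condition block-averaged activity over the seven task conditions, planted
group x condition contrast patterns (the ground truth for latent-variable
recovery), seed-coupled voxel sets (ground truth for seed-PLS recovery),
and behavioral tables drawn around the study's reported instrument
summaries.

Noise is i.i.d. Gaussian at the block-average level — the granularity the
analyses consume — so no temporal autocorrelation or hemodynamic model is
simulated.  Within-subject block-to-block variability is exposed as a
parameter of :func:`simulate_subject_blocks`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import BlockSeries, SubjectActivity
from .design import (
    ANALYSIS_CONDITIONS,
    CONDITIONS,
    GROUPS,
    StudyDesign,
    default_design,
)

__all__ = [
    "PlantedEffect",
    "SyntheticDataset",
    "default_effects",
    "simulate_subject_activity",
    "simulate_dataset",
    "simulate_behavioral",
    "simulate_behavioral_table",
    "simulate_subject_blocks",
    "plant_seed_coupling",
    "TABLE1_TARGETS",
]

#: Reported instrument summaries (mean, sd) per measure/group/condition,
#: used as the generator's behavioral targets.
TABLE1_TARGETS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "whoto_total": {
        "young": {
            "partner": (32.83, 6.80),
            "parent_child": (22.31, 8.46),
            "friend": (6.97, 7.56),
            "acquaintance": (0.0, 0.0),
        },
        "older": {
            "partner": (36.70, 6.59),
            "parent_child": (17.04, 9.65),
            "friend": (4.70, 5.59),
            "acquaintance": (0.0, 0.0),
        },
    },
    "ios": {
        "young": {
            "partner": (4.83, 1.23),
            "parent_child": (2.93, 1.39),
            "friend": (2.97, 1.55),
            "acquaintance": (1.55, 0.69),
        },
        "older": {
            "partner": (5.22, 1.45),
            "parent_child": (3.52, 1.50),
            "friend": (2.89, 1.53),
            "acquaintance": (2.30, 1.38),
        },
    },
    "relationship_length_years": {
        "young": {
            "partner": (3.66, 2.45),
            "parent_child": (22.90, 4.81),
            "friend": (6.96, 5.49),
            "acquaintance": (4.20, 4.01),
        },
        "older": {
            "partner": (36.29, 12.42),
            "parent_child": (29.27, 2.44),
            "friend": (29.15, 13.30),
            "acquaintance": (29.88, 16.37),
        },
    },
}

WHOTO_BOUNDS = (0.0, 40.0)
IOS_BOUNDS = (1.0, 7.0)


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth latent variable: voxels, cell contrast, amplitude.

    ``contrast`` maps (group, condition) cells to signed weights that sum
    to zero (a deviation pattern); cells not listed carry weight 0.
    ``voxel_weights`` (default all ones) give the spatial pattern over
    ``voxel_indices``.
    """

    name: str
    voxel_indices: np.ndarray
    contrast: dict[tuple[str, str], float]
    amplitude: float
    description: str = ""
    voxel_weights: np.ndarray | None = None

    def __post_init__(self):
        idx = np.asarray(self.voxel_indices, dtype=int)
        if idx.size and idx.min() < 0:
            raise ValueError("voxel indices must be non-negative")
        total = sum(self.contrast.values())
        if abs(total) > 1e-9:
            raise ValueError(
                f"effect {self.name!r}: contrast weights sum to {total}, not 0"
            )
        w = self.voxel_weights
        w = np.ones(idx.size) if w is None else np.asarray(w, dtype=float)
        if w.shape != (idx.size,):
            raise ValueError("voxel_weights length must match voxel_indices")
        object.__setattr__(self, "voxel_indices", idx)
        object.__setattr__(self, "voxel_weights", w)

    def pattern(self, n_voxels: int) -> np.ndarray:
        """Spatial pattern as a full-length voxel vector."""
        if self.voxel_indices.size and self.voxel_indices.max() >= n_voxels:
            raise ValueError(
                f"effect {self.name!r}: voxel index "
                f"{int(self.voxel_indices.max())} outside mask of {n_voxels}"
            )
        v = np.zeros(n_voxels)
        v[self.voxel_indices] = self.voxel_weights
        return v


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated study: design, activity, behavioral table, ground truth."""

    design: StudyDesign
    mask_shape: tuple[int, int, int]
    subjects: tuple[SubjectActivity, ...]
    behavioral: pd.DataFrame
    truth: tuple[PlantedEffect, ...]
    noise_sd: float
    rng_seed: int | None
    seed_couplings: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.mask_shape))

    def subjects_in(self, group: str) -> list[SubjectActivity]:
        return [s for s in self.subjects if s.group == group]

    def truth_manifest(self) -> dict:
        """JSON-serializable record of the planted ground truth."""
        return {
            "mask_shape": list(self.mask_shape),
            "noise_sd": self.noise_sd,
            "rng_seed": self.rng_seed,
            "effects": [
                {
                    "name": e.name,
                    "amplitude": e.amplitude,
                    "voxel_indices": e.voxel_indices.tolist(),
                    "voxel_weights": e.voxel_weights.tolist(),
                    "contrast": {f"{g}|{c}": w for (g, c), w in e.contrast.items()},
                    "description": e.description,
                }
                for e in self.truth
            ],
            "seed_couplings": {
                f"{g}|{c}": r for (g, c), r in self.seed_couplings.items()
            },
        }

    def write_truth(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.truth_manifest(), indent=2))
        return path


def default_effects(n_voxels: int = 12 * 12 * 12) -> tuple[PlantedEffect, ...]:
    """Two orthogonal planted latent variables emulating the task contrasts.

    Effect 1 separates every social condition (and self) from the motor
    control in both groups; effect 2 differentiates partner and self from
    parent and friend in the young group only.  Disjoint 64-voxel supports
    keep the spatial patterns orthogonal, and the amplitudes are set so the
    planted crossblock-covariance split is exactly 80 / 20.
    """
    social = ("partner", "parent_child", "friend", "acquaintance", "self")
    c1 = {(g, c): 1.0 for g, _ in GROUPS for c in social}
    c1.update({(g, "control"): -5.0 for g, _ in GROUPS})
    c2 = {
        ("young", "partner"): 1.0,
        ("young", "self"): 1.0,
        ("young", "parent_child"): -1.0,
        ("young", "friend"): -1.0,
    }
    k = 64
    if n_voxels < 4 * k:
        raise ValueError(f"mask of {n_voxels} voxels too small for default effects")
    start1, start2 = n_voxels // 16, n_voxels // 2
    # ||c1|| = sqrt(60), ||c2|| = 2; equal supports, so amplitude sqrt(60)/4
    # makes the second singular value exactly half the first (80/20 split).
    return (
        PlantedEffect(
            name="social_vs_control",
            voxel_indices=np.arange(start1, start1 + k),
            contrast=c1,
            amplitude=1.0,
            description="all social others and self vs motor control, both groups",
        ),
        PlantedEffect(
            name="partner_self_young",
            voxel_indices=np.arange(start2, start2 + k),
            contrast=c2,
            amplitude=float(np.sqrt(60) / 4),
            description="partner and self vs parent and friend, young adults only",
        ),
    )


def simulate_subject_activity(
    design: StudyDesign,
    truth: tuple[PlantedEffect, ...],
    group: str,
    noise_sd: float,
    rng: np.random.Generator,
    n_voxels: int,
    subject_id: str = "sub",
) -> SubjectActivity:
    """One subject's voxel x condition matrix: planted signal + Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if group not in design.group_labels:
        raise ValueError(f"group {group!r} not in design groups {design.group_labels}")
    conds = design.conditions
    signal = np.zeros((n_voxels, len(conds)))
    for e in truth:
        pat = e.pattern(n_voxels)
        for j, c in enumerate(conds):
            w = e.contrast.get((group, c), 0.0)
            if w:
                signal[:, j] += e.amplitude * w * pat
    noise = rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd else 0.0
    return SubjectActivity(
        subject_id=subject_id, group=group, conditions=conds, matrix=signal + noise
    )


def simulate_dataset(
    design: StudyDesign | None = None,
    mask_shape: tuple[int, int, int] = (12, 12, 12),
    effects: tuple[PlantedEffect, ...] | None = None,
    noise_sd: float = 1.0,
    seed: int | None = 0,
    behavioral: bool = True,
) -> SyntheticDataset:
    """Generate a full synthetic study under the default conditions.

    Defaults mirror the study: groups of 29 and 27, the 5x14x5 block design
    over seven conditions, a 12x12x12 voxel grid, unit noise, and the two
    planted latent variables of :func:`default_effects`.  Identical seeds
    yield byte-identical datasets.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = default_design(rng=rng.integers(2**31))
    n_voxels = int(np.prod(mask_shape))
    if effects is None:
        effects = default_effects(n_voxels)
    subjects = []
    for group, n in design.groups:
        for i in range(n):
            subjects.append(
                simulate_subject_activity(
                    design,
                    effects,
                    group,
                    noise_sd,
                    rng,
                    n_voxels,
                    subject_id=f"{group}-{i + 1:02d}",
                )
            )
    beh = (
        simulate_behavioral_table(design, rng=rng)
        if behavioral
        else pd.DataFrame()
    )
    return SyntheticDataset(
        design=design,
        mask_shape=tuple(mask_shape),
        subjects=tuple(subjects),
        behavioral=beh,
        truth=tuple(effects),
        noise_sd=noise_sd,
        rng_seed=seed,
    )


def simulate_behavioral(
    means: dict[str, float],
    sds: dict[str, float],
    n: int,
    bounds: tuple[float, float],
    rng: np.random.Generator,
    integer: bool = False,
) -> pd.DataFrame:
    """Clipped-Gaussian draws per condition within an instrument's range.

    Draws are truncated by clipping to ``bounds``.  The latent Gaussian mean
    is calibrated so the *clipped* distribution's expectation equals the
    requested mean (clipping alone would bias targets near a bound, e.g. a
    partner attachment score of ~33 on a 0-40 instrument, by about half a
    point).  With ``integer=True`` values are rounded (for the 1-7
    pictorial scale).
    """
    lo, hi = bounds
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("bounds must be finite")
    out = {}
    for cond, mu in means.items():
        sd = sds[cond]
        if sd < 0:
            raise ValueError(f"sd for {cond!r} must be >= 0")
        if not lo <= mu <= hi:
            raise ValueError(f"mean {mu} for {cond!r} outside bounds {bounds}")
        if sd == 0:
            vals = np.full(n, mu)
        else:
            latent = _latent_mean_for_clipped_target(mu, sd, lo, hi)
            vals = np.clip(rng.normal(latent, sd, size=n), lo, hi)
        out[cond] = np.rint(vals) if integer else vals
    return pd.DataFrame(out)


def _clipped_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """E[clip(X, lo, hi)] for X ~ N(mu, sd^2), in closed form."""
    from scipy import stats as _st

    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(
        mu
        + sd * (_st.norm.pdf(a) - _st.norm.pdf(b))
        + (lo - mu) * _st.norm.cdf(a)
        + (hi - mu) * _st.norm.sf(b)
    )


def _latent_mean_for_clipped_target(
    target: float, sd: float, lo: float, hi: float
) -> float:
    """Latent Gaussian mean whose clipped expectation equals ``target``."""
    from scipy import optimize

    if target <= lo:
        # the clipped mean can only reach lo in the limit; a point mass at
        # the bound (sd effectively irrelevant) is the faithful reading
        return lo - 10 * sd
    if target >= hi:
        return hi + 10 * sd
    f = lambda m: _clipped_normal_mean(m, sd, lo, hi) - target
    return float(optimize.brentq(f, lo - 10 * sd, hi + 10 * sd, xtol=1e-10))


def simulate_behavioral_table(
    design: StudyDesign | None = None,
    targets: dict | None = None,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Tidy behavioral table emulating the reported instrument summaries.

    Columns: subject_id, group, condition, whoto_total, ios,
    relationship_length_years.
    """
    rng = np.random.default_rng(rng)
    if design is None:
        design = default_design(rng=rng.integers(2**31))
    targets = targets or TABLE1_TARGETS
    bounds = {
        "whoto_total": WHOTO_BOUNDS,
        "ios": IOS_BOUNDS,
        "relationship_length_years": (0.0, 120.0),
    }
    integer = {"whoto_total": False, "ios": True, "relationship_length_years": False}
    frames = []
    for group, n in design.groups:
        draws = {}
        for measure, per_group in targets.items():
            cells = per_group[group]
            means = {c: mv[0] for c, mv in cells.items()}
            sds = {c: mv[1] for c, mv in cells.items()}
            draws[measure] = simulate_behavioral(
                means, sds, n, bounds[measure], rng, integer=integer[measure]
            )
        conditions = list(next(iter(targets.values()))[group])
        for i in range(n):
            for c in conditions:
                frames.append(
                    {
                        "subject_id": f"{group}-{i + 1:02d}",
                        "group": group,
                        "condition": c,
                        **{m: draws[m][c].iloc[i] for m in targets},
                    }
                )
    return pd.DataFrame(frames)


def simulate_subject_blocks(
    design: StudyDesign,
    subject: SubjectActivity,
    within_block_sd: float = 0.0,
    baseline_level: float = 100.0,
    rng: np.random.Generator | int | None = 0,
) -> list[BlockSeries]:
    """Expand a subject's condition means into per-block series + fixations.

    Each block's voxel means are the subject's condition column plus the
    fixation baseline plus block-to-block noise; fixation vectors get
    independent noise of the same scale, so block-averaging after baseline
    normalization recovers the condition matrix as blocks accumulate.
    """
    rng = np.random.default_rng(rng)
    blocks: list[BlockSeries] = []
    order = design.block_order or tuple(
        tuple(design.conditions) * design.blocks_per_condition_per_run
        for _ in range(design.n_runs)
    )
    nv = subject.n_voxels
    for run, run_order in enumerate(order):
        for blk, cond in enumerate(run_order):
            if cond not in subject.conditions:
                continue
            fix = baseline_level + rng.normal(0, within_block_sd, nv)
            val = (
                baseline_level
                + subject.column(cond)
                + rng.normal(0, within_block_sd, nv)
            )
            blocks.append(
                BlockSeries(
                    subject_id=subject.subject_id,
                    run=run,
                    block=blk,
                    condition=cond,
                    voxel_values=val,
                    preceding_fixation=fix,
                )
            )
    return blocks


def plant_seed_coupling(
    dataset: SyntheticDataset,
    seed: "object",
    target_voxels: np.ndarray,
    r_by_cell: dict[tuple[str, str], float],
    rng: np.random.Generator | int | None = 0,
    shared_residual: float = 0.5,
) -> SyntheticDataset:
    """Rewrite target voxels so they correlate with the seed across subjects.

    For each (group, condition) cell with target correlation r, the target
    voxels' values are rebuilt as ``r * z + sqrt(1 - r^2) * residual``
    (scaled by the dataset noise sd), where z is the standardized
    seed-neighborhood mean across that cell's subjects.  The residual mixes
    a region-level component shared by all target voxels
    (``shared_residual`` fraction of residual variance) with voxel-specific
    noise: a genuinely coupled region fluctuates coherently, and the shared
    part keeps the region-aggregate correlation near the planted per-voxel
    level instead of inflating toward 1 by averaging.  Empirical per-voxel
    correlations approach r as the group size grows; cells not listed keep
    their original (independent) noise, i.e. r ~ 0.
    """
    if not 0.0 <= shared_residual <= 1.0:
        raise ValueError("shared_residual must be in [0, 1]")
    for cell, r in r_by_cell.items():
        if abs(r) > 1:
            raise ValueError(f"|r| must be <= 1, got {r} for cell {cell}")
    target_voxels = np.asarray(target_voxels, dtype=int)
    seed_idx = np.asarray(seed.neighborhood, dtype=int)
    if np.intersect1d(target_voxels, seed_idx).size:
        raise ValueError("target voxels must be disjoint from the seed voxels")
    rng = np.random.default_rng(rng)
    sd = dataset.noise_sd if dataset.noise_sd > 0 else 1.0
    matrices = {s.subject_id: s.matrix.copy() for s in dataset.subjects}
    for (group, cond), r in r_by_cell.items():
        members = dataset.subjects_in(group)
        if not members:
            raise ValueError(f"no subjects in group {group!r}")
        j = members[0].conditions.index(cond)
        seed_vals = np.array([m.matrix[seed_idx, j].mean() for m in members])
        z = seed_vals - seed_vals.mean()
        norm = z.std()
        z = z / norm if norm > 0 else z
        shared = rng.normal(0, 1, len(members))
        for v in target_voxels:
            eps = (
                np.sqrt(shared_residual) * shared
                + np.sqrt(1 - shared_residual) * rng.normal(0, 1, len(members))
            )
            new = sd * (r * z + np.sqrt(1 - r**2) * eps)
            for m, val in zip(members, new):
                matrices[m.subject_id][v, j] = val
    subjects = tuple(
        replace(s, matrix=matrices[s.subject_id]) for s in dataset.subjects
    )
    couplings = dict(dataset.seed_couplings)
    couplings.update(r_by_cell)
    return replace(dataset, subjects=subjects, seed_couplings=couplings)
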