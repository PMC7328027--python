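"""Seed PLS: functional connectivity of a seed region with all voxels.

A seed region of interest is a peak voxel plus its 26 cubic neighbors.
Per group x condition cell, the seed's mean activity is correlated across
that cell's participants with every voxel, and the stacked cell x voxel
correlation matrix is decomposed by SVD (uncentered: correlations are
already reference-free).  Latent variables then describe patterns of
seed-coupled connectivity and how they differ across conditions and
groups; per cell, the correlation between participants' LV brain scores
and their seed activity summarizes how strongly that cell expresses the
pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .activity import SubjectActivity, exclude_conditions
from .pls import (
    PLSDecomposition,
    StackedDataMatrix,
    _cell_mean_scores,
    _group_order,
    compute_brain_scores,
    decompose,
)
from .resampling import (
    BootstrapResult,
    PermutationResult,
    bootstrap_saliences,
    permutation_pvalue,
    threshold_bsr,
)
from .space import VoxelSpace

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSpec",
    "default_seed_table",
    "extract_seed_activity",
    "correlation_map_per_cell",
    "build_seed_correlation_matrix",
    "seed_decompose",
    "lv_seed_correlations",
    "SeedPLS",
    "SeedPLSResults",
]

#: The two medial-prefrontal seeds used in the connectivity analyses
#: (peak MNI mm coordinates from the task analysis).
DEFAULT_SEEDS_MM: dict[str, tuple[float, float, float]] = {
    "dmpfc": (-6.0, 54.0, 30.0),
    "vmpfc": (-2.0, 50.0, -18.0),
}


@dataclass(frozen=True)
class SeedSpec:
    """Named seed ROI: a peak voxel and its in-mask cubic neighborhood."""

    name: str
    peak_ijk: tuple[int, int, int]
    neighborhood: np.ndarray  # flattened in-mask vector indices
    peak_mm: tuple[float, float, float] | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "neighborhood", np.asarray(self.neighborhood, dtype=int)
        )

    @classmethod
    def from_peak(
        cls,
        space: VoxelSpace,
        ijk: tuple[int, int, int] | None = None,
        mm: tuple[float, float, float] | None = None,
        name: str = "seed",
    ) -> "SeedSpec":
        """Build the 3x3x3 cube around a peak (voxel or mm coordinates).

        The 3x3x3 cube is the unique shape with exactly 26 neighbors under
        full face/edge/corner adjacency.  Out-of-mask neighbors are dropped
        with a warning; an out-of-mask peak is an error.
        """
        if (ijk is None) == (mm is None):
            raise ValueError("give exactly one of ijk or mm")
        if ijk is None:
            ijk = tuple(int(v) for v in np.atleast_1d(space.mm_to_ijk(np.asarray(mm))))
        ijk = tuple(int(v) for v in ijk)
        if not space.in_bounds(ijk) or not space.mask[ijk]:
            raise ValueError(f"seed peak {ijk} is outside the mask")
        members = []
        dropped = 0
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    v = (ijk[0] + di, ijk[1] + dj, ijk[2] + dk)
                    if space.in_bounds(v) and space.mask[v]:
                        members.append(space.vector_index(v))
                    else:
                        dropped += 1
        if dropped:
            logger.warning(
                "seed %r at %s: %d of 27 cube voxels outside the mask, dropped",
                name,
                ijk,
                dropped,
            )
        return cls(
            name=name,
            peak_ijk=ijk,
            neighborhood=np.array(sorted(members)),
            peak_mm=tuple(np.atleast_1d(space.ijk_to_mm(ijk)).tolist()),
        )


def default_seed_table() -> pd.DataFrame:
    """Shipped seed definitions (name, x_mm, y_mm, z_mm)."""
    return pd.DataFrame(
        [{"name": n, "x_mm": x, "y_mm": y, "z_mm": z} for n, (x, y, z) in DEFAULT_SEEDS_MM.items()]
    )


def load_seed_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "x_mm", "y_mm", "z_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"seed table missing column(s): {sorted(missing)}")
    return df


def extract_seed_activity(
    subjects: Sequence[SubjectActivity], seed: SeedSpec
) -> np.ndarray:
    """(n_subjects, n_conditions) mean activity over the seed neighborhood."""
    nv = subjects[0].n_voxels
    if seed.neighborhood.size == 0 or seed.neighborhood.max() >= nv:
        raise ValueError(f"seed {seed.name!r} voxels outside the {nv}-voxel mask")
    return np.stack([s.matrix[seed.neighborhood].mean(axis=0) for s in subjects])


def correlation_map_per_cell(
    subjects: Sequence[SubjectActivity],
    seed_values: np.ndarray,
    cell: tuple[str, str],
) -> np.ndarray:
    """Per-voxel Pearson correlation of seed with voxel activity in one cell.

    Computed across the cell's participants.  A zero-variance seed or voxel
    yields r = 0 (with a log notice) rather than a non-finite value.
    """
    group, cond = cell
    conds = subjects[0].conditions
    j = conds.index(cond)
    idx = [i for i, s in enumerate(subjects) if s.group == group]
    if len(idx) < 3:
        raise ValueError(f"cell {cell} has {len(idx)} participants; need >= 3")
    x = seed_values[idx, j]
    Y = np.stack([subjects[i].matrix[:, j] for i in idx])  # (n, voxels)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(Yc**2, axis=0))
    if sx == 0 or np.any(sy == 0):
        logger.info("zero-variance seed or voxel(s) in cell %s: r set to 0", cell)
    denom = sx * np.where(sy > 0, sy, 1.0)
    r = np.where((sx > 0) & (sy > 0), Yc.T @ xc / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def build_seed_correlation_matrix(
    subjects: Sequence[SubjectActivity], seed: SeedSpec
) -> StackedDataMatrix:
    """Stack per-cell seed correlation maps into a cells x voxels matrix."""
    seed_values = extract_seed_activity(subjects, seed)
    groups = _group_order(subjects)
    conds = subjects[0].conditions
    cells = tuple((g, c) for g in groups for c in conds)
    if len(cells) < 2:
        raise ValueError("need at least 2 group x condition cells")
    rows = np.stack(
        [correlation_map_per_cell(subjects, seed_values, cell) for cell in cells]
    )
    return StackedDataMatrix(
        cells=cells, data=rows, cell_means=rows, grand_mean=rows.mean(axis=0)
    )


def seed_decompose(corr: StackedDataMatrix, center: bool = False) -> PLSDecomposition:
    """SVD of the stacked correlation matrix (uncentered by default)."""
    data = corr.data - corr.data.mean(axis=0) if center else corr.data
    return decompose(np.asarray(data, dtype=float))


def lv_seed_correlations(
    voxel_saliences: np.ndarray,
    subjects: Sequence[SubjectActivity],
    seed_values: np.ndarray,
    n_boot: int = 1000,
    ci: float = 95.0,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Per-cell correlation between LV brain scores and seed activity.

    For each (group, condition) cell and each LV, the Pearson correlation
    across the cell's participants between their brain scores and their
    seed values, with bootstrap percentile confidence intervals.  Cells
    with fewer than 3 participants are reported as missing.
    """
    rng = np.random.default_rng(rng)
    scores = compute_brain_scores(voxel_saliences, subjects)
    groups = _group_order(subjects)
    conds = subjects[0].conditions
    rows = []
    for g in groups:
        idx = np.array([i for i, s in enumerate(subjects) if s.group == g])
        for j, c in enumerate(conds):
            for k in range(voxel_saliences.shape[1]):
                rec = {"group": g, "condition": c, "lv": k + 1}
                if idx.size < 3:
                    logger.info("cell (%s, %s) has n=%d < 3: skipped", g, c, idx.size)
                    rec.update({"r": np.nan, "ci_lo": np.nan, "ci_hi": np.nan})
                else:
                    a = scores[idx, j, k]
                    b = seed_values[idx, j]
                    rec["r"] = _safe_corr(a, b)
                    boots = np.empty(n_boot)
                    for t in range(n_boot):
                        bi = rng.integers(0, idx.size, idx.size)
                        boots[t] = _safe_corr(a[bi], b[bi])
                    lo, hi = (100 - ci) / 2, 100 - (100 - ci) / 2
                    rec["ci_lo"] = float(np.percentile(boots, lo))
                    rec["ci_hi"] = float(np.percentile(boots, hi))
                rows.append(rec)
    return pd.DataFrame(rows)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


class SeedPLS:
    """Seed-PLS connectivity model for one seed region.

    Parameters
    ----------
    subjects
        Per-subject voxel x condition activities.
    seed
        :class:`SeedSpec` naming the ROI.
    drop_conditions
        Conditions excluded before correlation (default: the motor
        control; connectivity is examined over social conditions + self).
    """

    def __init__(
        self,
        subjects: Sequence[SubjectActivity],
        seed: SeedSpec,
        drop_conditions: tuple[str, ...] = ("control",),
    ):
        drop = tuple(c for c in drop_conditions if c in subjects[0].conditions)
        self.subjects = exclude_conditions(list(subjects), drop) if drop else list(subjects)
        self.seed = seed
        self.conditions = self.subjects[0].conditions
        self.groups = _group_order(self.subjects)
        self.cells = tuple((g, c) for g in self.groups for c in self.conditions)

    def _pipeline(self, subjects: Sequence[SubjectActivity]) -> PLSDecomposition:
        return seed_decompose(build_seed_correlation_matrix(subjects, self.seed))

    def fit(
        self,
        n_perm: int = 500,
        n_boot: int = 100,
        rng: np.random.Generator | int | None = None,
        align: str = "procrustes",
        n_boot_corr: int = 500,
    ) -> "SeedPLSResults":
        rng = np.random.default_rng(rng)
        corr = build_seed_correlation_matrix(self.subjects, self.seed)
        dec = seed_decompose(corr)
        seed_values = extract_seed_activity(self.subjects, self.seed)
        perm = (
            permutation_pvalue(self._pipeline, self.subjects, n_perm, rng)
            if n_perm
            else None
        )
        boot = (
            bootstrap_saliences(
                self._pipeline,
                self.subjects,
                n_boot,
                rng,
                align=align,
                score_fn=lambda subs, V: _cell_mean_scores(subs, V, self.cells),
            )
            if n_boot
            else None
        )
        seed_corr = lv_seed_correlations(
            dec.voxel_saliences,
            self.subjects,
            seed_values,
            n_boot=n_boot_corr,
            rng=rng,
        )
        return SeedPLSResults(
            model=self,
            correlation_matrix=corr,
            decomposition=dec,
            seed_values=seed_values,
            permutation=perm,
            bootstrap=boot,
            seed_correlations=seed_corr,
        )


@dataclass
class SeedPLSResults:
    """Fitted seed-PLS: connectivity LVs plus per-cell seed correlations."""

    model: SeedPLS
    correlation_matrix: StackedDataMatrix
    decomposition: PLSDecomposition
    seed_values: np.ndarray  # (n_subjects, n_conditions)
    permutation: PermutationResult | None
    bootstrap: BootstrapResult | None
    seed_correlations: pd.DataFrame

    @property
    def cells(self) -> tuple[tuple[str, str], ...]:
        return self.correlation_matrix.cells

    @property
    def design_saliences(self) -> np.ndarray:
        return self.decomposition.design_saliences

    @property
    def voxel_saliences(self) -> np.ndarray:
        return self.decomposition.voxel_saliences

    @property
    def singular_values(self) -> np.ndarray:
        return self.decomposition.singular_values

    @property
    def covariance_pct(self) -> np.ndarray:
        return self.decomposition.covariance_pct

    @property
    def p_values(self) -> np.ndarray | None:
        return None if self.permutation is None else self.permutation.p_values

    @property
    def bootstrap_ratios(self) -> np.ndarray | None:
        return None if self.bootstrap is None else self.bootstrap.bootstrap_ratios

    def reliable_voxels(self, cutoff: float = 2.58) -> np.ndarray | None:
        return (
            None
            if self.bootstrap_ratios is None
            else threshold_bsr(self.bootstrap_ratios, cutoff)
        )

    def lv_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "lv": np.arange(1, self.singular_values.size + 1),
                "singular_value": self.singular_values,
                "covariance_pct": self.covariance_pct,
            }
        )
        if self.p_values is not None:
            df["p_perm"] = self.p_values
        return df

    def summary(self, n_lv: int | None = None) -> str:
        n_lv = n_lv or min(5, self.singular_values.size)
        lines = [
            f"{type(self).__name__}  (seed: {self.model.seed.name})",
            "=" * 60,
            f"subjects: {len(self.model.subjects)}  "
            f"groups: {', '.join(self.model.groups)}",
            f"conditions: {', '.join(self.model.conditions)}",
            f"seed voxels: {self.model.seed.neighborhood.size}  "
            f"peak ijk: {self.model.seed.peak_ijk}",
            "-" * 60,
            f"{'LV':>3} {'singular':>10} {'cov %':>8} {'p(perm)':>9}",
        ]
        for k in range(n_lv):
            p = "" if self.p_values is None else f"{self.p_values[k]:9.4f}"
            lines.append(
                f"{k + 1:>3} {self.singular_values[k]:10.3f} "
                f"{self.covariance_pct[k]:8.2f} {p:>9}"
            )
        return "\n".join(lines)

    def plot_seed_correlations(self, lv: int = 1, ax=None):
        """Bar plot of per-cell seed correlations for one LV, with CIs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        sub = self.seed_correlations[self.seed_correlations["lv"] == lv]
        labels = [f"{g}\n{c}" for g, c in zip(sub["group"], sub["condition"])]
        x = np.arange(len(sub))
        yerr = np.abs(
            np.stack([sub["r"] - sub["ci_lo"], sub["ci_hi"] - sub["r"]])
        )
        ax.bar(x, sub["r"], yerr=yerr, capsize=2)
        ax.set_xticks(x, labels, fontsize=7)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_ylabel(f"seed-score r (LV{lv})")
        return ax

    def save(self, out_dir: str | Path, space=None) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.lv_table().to_csv(out / "latent_variables.tsv", sep="\t", index=False)
        cells = pd.DataFrame(self.cells, columns=["group", "condition"])
        pd.concat(
            [cells, pd.DataFrame(self.design_saliences).add_prefix("lv")], axis=1
        ).to_csv(out / "design_saliences.tsv", sep="\t", index=False)
        self.seed_correlations.to_csv(out / "seed_correlations.csv", index=False)
        if self.permutation is not None:
            pd.DataFrame(
                self.permutation.null_singular_values,
                columns=[
                    f"lv{k + 1}"
                    for k in range(self.permutation.null_singular_values.shape[1])
                ],
            ).to_csv(out / "permutation_null.tsv", sep="\t", index=False)
        if space is not None:
            for k in range(min(len(self.cells), self.voxel_saliences.shape[1])):
                space.write_map(
                    self.voxel_saliences[:, k], out / f"salience_lv{k + 1}.nii.gz"
                )
                if self.bootstrap_ratios is not None:
                    bsr = np.where(
                        np.isfinite(self.bootstrap_ratios[:, k]),
                        self.bootstrap_ratios[:, k],
                        0.0,
                    )
                    space.write_map(bsr, out / f"bsr_lv{k + 1}.nii.gz")
        return out
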