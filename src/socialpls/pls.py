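"""Mean-centered task PLS.

The group x condition cell means of baseline-normalized activity are
expressed as voxel-wise deviations from the grand mean over all cells and
decomposed by SVD.  Each latent variable (LV) pairs a design salience
vector (one weight per group x condition cell) with a voxel salience map
and a singular value measuring their covariance; the squared singular
values, as percentages of their sum, are the crossblock covariance
accounted for.  Projecting a participant's condition activity onto an LV's
voxel saliences (a dot product over voxels) gives that participant's brain
score for the condition.

Because LV significance is assessed in one multivariate step by
permutation, and voxel reliability in an independent bootstrap step, no
voxel-wise multiple-comparison correction is applied.

The :class:`MeanCenteredPLS` model wraps the pipeline; ``fit()`` returns a
:class:`TaskPLSResults` carrying saliences, singular values, covariance
percentages, brain scores, permutation p-values and bootstrap ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .activity import SubjectActivity
from .resampling import (
    BootstrapResult,
    PermutationResult,
    bootstrap_saliences,
    permutation_pvalue,
    threshold_bsr,
)

__all__ = [
    "StackedDataMatrix",
    "PLSDecomposition",
    "build_mean_centered_matrix",
    "decompose",
    "crossblock_covariance_pct",
    "compute_brain_scores",
    "MeanCenteredPLS",
    "TaskPLSResults",
]


@dataclass(frozen=True)
class StackedDataMatrix:
    """Centered cell x voxel matrix with its cell bookkeeping."""

    cells: tuple[tuple[str, str], ...]  # ordered (group, condition)
    data: np.ndarray  # centered (n_cells, n_voxels)
    cell_means: np.ndarray  # uncentered (n_cells, n_voxels)
    grand_mean: np.ndarray  # (n_voxels,)

    @property
    def row_index(self) -> dict[tuple[str, str], int]:
        return {cell: i for i, cell in enumerate(self.cells)}


@dataclass(frozen=True)
class PLSDecomposition:
    """SVD of a stacked matrix: design/voxel saliences + singular values."""

    design_saliences: np.ndarray  # (n_cells, L), orthonormal columns
    singular_values: np.ndarray  # (L,), non-increasing
    voxel_saliences: np.ndarray  # (n_voxels, L), orthonormal columns

    @property
    def covariance_pct(self) -> np.ndarray:
        return crossblock_covariance_pct(self.singular_values)


def _group_order(subjects: Sequence[SubjectActivity]) -> tuple[str, ...]:
    seen: list[str] = []
    for s in subjects:
        if s.group not in seen:
            seen.append(s.group)
    return tuple(seen)


def build_mean_centered_matrix(
    subjects: Sequence[SubjectActivity],
    center: str = "grand",
) -> StackedDataMatrix:
    """Stack group x condition cell means and subtract the grand mean.

    ``center='grand'`` subtracts the per-voxel mean over all rows (the
    default, a single centering with groups stacked); ``center='group'``
    centers within each group's rows; ``center='none'`` skips centering.
    After grand centering every voxel column sums to zero across rows.
    """
    if not subjects:
        raise ValueError("no subjects supplied")
    conditions = subjects[0].conditions
    groups = _group_order(subjects)
    cells = tuple((g, c) for g in groups for c in conditions)
    if len(cells) < 2:
        raise ValueError("need at least 2 group x condition cells")
    nv = subjects[0].n_voxels
    rows = np.empty((len(cells), nv))
    for i, (g, c) in enumerate(cells):
        j = conditions.index(c)
        members = [s.matrix[:, j] for s in subjects if s.group == g]
        if not members:
            raise ValueError(f"cell (group={g!r}, condition={c!r}) has no subjects")
        rows[i] = np.mean(members, axis=0)
    grand = rows.mean(axis=0)
    if center == "grand":
        data = rows - grand
    elif center == "group":
        data = rows.copy()
        for g in groups:
            idx = [i for i, (gg, _) in enumerate(cells) if gg == g]
            data[idx] -= rows[idx].mean(axis=0)
    elif center == "none":
        data = rows.copy()
    else:
        raise ValueError(f"unknown centering {center!r}")
    return StackedDataMatrix(cells=cells, data=data, cell_means=rows, grand_mean=grand)


def decompose(m: StackedDataMatrix | np.ndarray) -> PLSDecomposition:
    """Thin SVD of the stacked cell x voxel matrix.

    LV signs are fixed so each LV's largest-magnitude design salience is
    positive (the SVD sign is arbitrary; a convention is needed for stable
    bootstrap alignment and tests).
    """
    data = m.data if isinstance(m, StackedDataMatrix) else np.asarray(m, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(data, full_matrices=False)
    V = Vt.T
    for k in range(s.size):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    return PLSDecomposition(
        design_saliences=U, singular_values=s, voxel_saliences=V
    )


def crossblock_covariance_pct(singular_values: np.ndarray) -> np.ndarray:
    """Percent crossblock covariance per LV: 100 * s_k^2 / sum_j s_j^2."""
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be >= 0")
    total = np.sum(s**2)
    if total == 0:
        raise ValueError("all singular values are zero")
    return 100.0 * s**2 / total


def compute_brain_scores(
    voxel_saliences: np.ndarray, subjects: Sequence[SubjectActivity]
) -> np.ndarray:
    """Project subjects onto voxel saliences: (n_subjects, n_conditions, L).

    score(subject, condition, k) = sum over voxels of salience_k * activity.
    """
    V = np.asarray(voxel_saliences, dtype=float)
    nv = V.shape[0]
    for s in subjects:
        if s.n_voxels != nv:
            raise ValueError(
                f"subject {s.subject_id} has {s.n_voxels} voxels, saliences {nv}"
            )
    return np.stack([s.matrix.T @ V for s in subjects])  # (n, C, L)


def _cell_mean_scores(
    subjects: Sequence[SubjectActivity],
    V: np.ndarray,
    cells: tuple[tuple[str, str], ...],
) -> np.ndarray:
    scores = compute_brain_scores(V, subjects)
    conditions = subjects[0].conditions
    out = np.empty((len(cells), V.shape[1]))
    groups = np.array([s.group for s in subjects])
    for i, (g, c) in enumerate(cells):
        out[i] = scores[groups == g, conditions.index(c), :].mean(axis=0)
    return out


class MeanCenteredPLS:
    """Mean-centered task PLS model over a list of subject activities.

    Parameters
    ----------
    subjects
        Per-subject voxel x condition activities, identical condition order.
    center
        ``'grand'`` (default) or ``'group'`` mean-centering.

    ``fit()`` runs the decomposition plus permutation and bootstrap
    inference and returns a :class:`TaskPLSResults`.
    """

    def __init__(self, subjects: Sequence[SubjectActivity], center: str = "grand"):
        if not subjects:
            raise ValueError("no subjects supplied")
        conds = subjects[0].conditions
        for s in subjects:
            if s.conditions != conds:
                raise ValueError(
                    f"subject {s.subject_id} condition order differs: "
                    f"{s.conditions} vs {conds}"
                )
        self.subjects = list(subjects)
        self.center = center
        self.conditions = conds
        self.groups = _group_order(subjects)
        self.cells = tuple((g, c) for g in self.groups for c in conds)

    # pipeline: the full rebuild applied to any (permuted/resampled) subjects
    def _pipeline(self, subjects: Sequence[SubjectActivity]) -> PLSDecomposition:
        return decompose(build_mean_centered_matrix(subjects, center=self.center))

    def fit(
        self,
        n_perm: int = 500,
        n_boot: int = 100,
        rng: np.random.Generator | int | None = None,
        align: str = "procrustes",
    ) -> "TaskPLSResults":
        rng = np.random.default_rng(rng)
        stacked = build_mean_centered_matrix(self.subjects, center=self.center)
        dec = decompose(stacked)
        brain_scores = compute_brain_scores(dec.voxel_saliences, self.subjects)
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
        return TaskPLSResults(
            model=self,
            stacked=stacked,
            decomposition=dec,
            brain_scores=brain_scores,
            permutation=perm,
            bootstrap=boot,
        )


@dataclass
class TaskPLSResults:
    """Fitted task-PLS: saliences, covariance %, p-values, BSRs, scores."""

    model: MeanCenteredPLS
    stacked: StackedDataMatrix
    decomposition: PLSDecomposition
    brain_scores: np.ndarray  # (n_subjects, n_conditions, L)
    permutation: PermutationResult | None
    bootstrap: BootstrapResult | None

    # -- convenience views ---------------------------------------------

    @property
    def cells(self) -> tuple[tuple[str, str], ...]:
        return self.stacked.cells

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

    @property
    def score_cis(self) -> np.ndarray | None:
        return None if self.bootstrap is None else self.bootstrap.score_cis

    def cell_mean_scores(self) -> np.ndarray:
        """(cells, L) mean brain score per group x condition cell."""
        return _cell_mean_scores(
            self.model.subjects, self.voxel_saliences, self.cells
        )

    def reliable_voxels(self, cutoff: float = 2.58) -> np.ndarray | None:
        return (
            None
            if self.bootstrap_ratios is None
            else threshold_bsr(self.bootstrap_ratios, cutoff)
        )

    # -- reporting -----------------------------------------------------

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
        """Plain-text overview of the fitted decomposition."""
        n_lv = n_lv or min(5, self.singular_values.size)
        lines = [
            f"{type(self).__name__}",
            "=" * 60,
            f"subjects: {len(self.model.subjects)}  "
            f"groups: {', '.join(self.model.groups)}",
            f"conditions: {', '.join(self.model.conditions)}",
            f"voxels: {self.voxel_saliences.shape[0]}  "
            f"cells: {len(self.cells)}  centering: {self.model.center}",
            "-" * 60,
            f"{'LV':>3} {'singular':>10} {'cov %':>8} {'p(perm)':>9}",
        ]
        for k in range(n_lv):
            p = "" if self.p_values is None else f"{self.p_values[k]:9.4f}"
            lines.append(
                f"{k + 1:>3} {self.singular_values[k]:10.3f} "
                f"{self.covariance_pct[k]:8.2f} {p:>9}"
            )
        if self.permutation is not None:
            lines.append(f"permutations: {self.permutation.n_permutations}")
        if self.bootstrap is not None:
            lines.append(
                f"bootstrap iterations: {self.bootstrap.n_iterations} "
                f"(alignment: {self.bootstrap.alignment_applied})"
            )
        return "\n".join(lines)

    def plot_brain_scores(self, lv: int = 1, ax=None):
        """Bar plot of cell-mean brain scores for one LV, with CIs if fitted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        means = self.cell_mean_scores()[:, lv - 1]
        labels = [f"{g}\n{c}" for g, c in self.cells]
        x = np.arange(len(labels))
        yerr = None
        if self.score_cis is not None:
            ci = self.score_cis[:, lv - 1, :]
            yerr = np.abs(ci.T - means)
        ax.bar(x, means, yerr=yerr, capsize=2)
        ax.set_xticks(x, labels, fontsize=7)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_ylabel(f"brain score (LV{lv})")
        return ax

    def save(self, out_dir: str | Path, space=None) -> Path:
        """Serialize to a directory: TSV/CSV tables and, given a space, NIfTIs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.lv_table().to_csv(out / "latent_variables.tsv", sep="\t", index=False)
        cells = pd.DataFrame(self.cells, columns=["group", "condition"])
        pd.concat(
            [cells, pd.DataFrame(self.design_saliences).add_prefix("lv")], axis=1
        ).to_csv(out / "design_saliences.tsv", sep="\t", index=False)
        rows = []
        for i, s in enumerate(self.model.subjects):
            for j, c in enumerate(self.model.conditions):
                rec = {"subject_id": s.subject_id, "group": s.group, "condition": c}
                for k in range(self.brain_scores.shape[2]):
                    rec[f"lv{k + 1}"] = self.brain_scores[i, j, k]
                rows.append(rec)
        pd.DataFrame(rows).to_csv(out / "brain_scores.csv", index=False)
        if self.permutation is not None:
            pd.DataFrame(
                self.permutation.null_singular_values,
                columns=[
                    f"lv{k + 1}"
                    for k in range(self.permutation.null_singular_values.shape[1])
                ],
            ).to_csv(out / "permutation_null.tsv", sep="\t", index=False)
        if space is not None:
            n_lv = len(self.cells) - 1 if self.model.center == "grand" else len(self.cells)
            for k in range(min(n_lv, self.voxel_saliences.shape[1])):
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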