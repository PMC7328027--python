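"""Permutation significance and bootstrap reliability for PLS decompositions.

Significance of each latent variable is assessed by randomly reordering
each participant's condition labels (group labels untouched), fully
recomputing the decomposition, and counting how often the permuted singular
value meets or exceeds the observed one.  Reliability of voxel saliences is
assessed by resampling participants with replacement within group,
recomputing, aligning the resampled saliences to the original (orthogonal
procrustes by default; the axis and sign of an SVD are arbitrary across
resamples), and forming bootstrap ratios salience / SE — Z-like statistics
conventionally thresholded at 2.58 (two-tailed p < 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .activity import SubjectActivity

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "BootstrapResult",
    "permute_conditions",
    "permutation_pvalue",
    "bootstrap_saliences",
    "align_resample",
    "procrustes_rotation",
    "threshold_bsr",
]


class Decomposition(Protocol):
    design_saliences: np.ndarray  # (cells, L)
    singular_values: np.ndarray  # (L,)
    voxel_saliences: np.ndarray  # (voxels, L)


#: A pipeline rebuilds the full decomposition from a subject list.
Pipeline = Callable[[Sequence[SubjectActivity]], Decomposition]


@dataclass(frozen=True)
class PermutationResult:
    n_permutations: int
    observed_singular_values: np.ndarray  # (L,)
    null_singular_values: np.ndarray  # (n_permutations, L)
    p_values: np.ndarray  # (L,)


@dataclass(frozen=True)
class BootstrapResult:
    n_iterations: int
    salience_se: np.ndarray  # (voxels, L)
    bootstrap_ratios: np.ndarray  # (voxels, L); +/-inf where se == 0
    score_cis: np.ndarray | None  # (cells, L, 2) percentile bounds, or None
    alignment_applied: str  # "procrustes" | "signs" | "none"


def permute_conditions(
    subjects: Sequence[SubjectActivity], rng: np.random.Generator
) -> list[SubjectActivity]:
    """Independently shuffle each subject's condition labels.

    Voxel data and group labels are untouched; only which column carries
    which condition label changes, so the multiset of each subject's
    columns is preserved.
    """
    out = []
    for s in subjects:
        k = len(s.conditions)
        perm = rng.permutation(k)
        out.append(dc_replace(s, matrix=s.matrix[:, perm]))
    return out


def permutation_pvalue(
    pipeline: Pipeline,
    subjects: Sequence[SubjectActivity],
    n_perm: int,
    rng: np.random.Generator | int | None = None,
    correction: bool = False,
) -> PermutationResult:
    """Permutation p-value per LV: P(permuted s_k >= observed s_k).

    The pipeline (condition averaging, centering, SVD) is fully recomputed
    for every permutation.  ``correction=True`` applies the
    (count + 1) / (n + 1) adjustment; the default reports the raw
    proportion, whose smallest nonzero value at 500 permutations is 0.002.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    observed = np.asarray(pipeline(subjects).singular_values, dtype=float)
    null = np.empty((n_perm, observed.size))
    for i in range(n_perm):
        null[i] = pipeline(permute_conditions(subjects, rng)).singular_values
    exceed = (null >= observed[None, :]).sum(axis=0)
    p = (exceed + 1) / (n_perm + 1) if correction else exceed / n_perm
    return PermutationResult(
        n_permutations=n_perm,
        observed_singular_values=observed,
        null_singular_values=null,
        p_values=p.astype(float),
    )


def procrustes_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal matrix R minimizing ||source @ R - target||_F."""
    R, _ = orthogonal_procrustes(source, target)
    return R


def _sign_flips(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    dots = np.einsum("ij,ij->j", source, target)
    return np.diag(np.where(dots < 0, -1.0, 1.0))


def align_resample(
    reference_saliences: np.ndarray,
    resampled_saliences: np.ndarray,
    method: str = "procrustes",
) -> np.ndarray:
    """Rotate (or sign-flip) resampled saliences onto the reference.

    Alignment is an orthogonal transform, so it never changes the column
    space.  A rank-deficient reference makes the procrustes rotation
    ill-determined; alignment then falls back to per-column sign flips.
    """
    ref = np.asarray(reference_saliences, dtype=float)
    res = np.asarray(resampled_saliences, dtype=float)
    if ref.shape != res.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {res.shape}")
    if method == "none":
        return res
    if method == "signs":
        return res @ _sign_flips(res, ref)
    if method != "procrustes":
        raise ValueError(f"unknown alignment method {method!r}")
    if np.linalg.matrix_rank(ref) < min(ref.shape):
        logger.info("rank-deficient reference; falling back to sign-flip alignment")
        return res @ _sign_flips(res, ref)
    return res @ procrustes_rotation(res, ref)


def _stratified_resample(
    subjects: Sequence[SubjectActivity], rng: np.random.Generator
) -> list[SubjectActivity]:
    groups: dict[str, list[SubjectActivity]] = {}
    for s in subjects:
        groups.setdefault(s.group, []).append(s)
    out = []
    for members in groups.values():
        idx = rng.integers(0, len(members), size=len(members))
        out.extend(members[i] for i in idx)
    return out


def bootstrap_saliences(
    pipeline: Pipeline,
    subjects: Sequence[SubjectActivity],
    n_boot: int,
    rng: np.random.Generator | int | None = None,
    align: str = "procrustes",
    score_fn: Callable[[Sequence[SubjectActivity], np.ndarray], np.ndarray]
    | None = None,
    ci: float = 95.0,
) -> BootstrapResult:
    """Bootstrap standard errors and bootstrap ratios for voxel saliences.

    Participants are resampled with replacement within group (stratified,
    preserving the group x condition design), the pipeline is recomputed,
    and the resampled voxel saliences are aligned to the originals.  As is
    conventional for this method family, the bootstrapped quantity is the
    singular-value-scaled salience (the voxel's covariance with the design
    contrast, free of the unit-norm constraint): the SE is the per-voxel
    standard deviation of the aligned scaled saliences and
    BSR = original scaled salience / SE (a +/-inf sentinel where SE is
    zero).  The ratio is scale-free, so thresholds read as Z-like values.

    ``score_fn(resampled_subjects, aligned_voxel_saliences)`` may return a
    (cells, L) array of cell-mean brain scores; percentile intervals over
    bootstrap iterations are then reported as ``score_cis``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if align not in ("procrustes", "signs", "none"):
        raise ValueError(f"unknown alignment method {align!r}")
    counts: dict[str, int] = {}
    for s in subjects:
        counts[s.group] = counts.get(s.group, 0) + 1
    if any(n < 2 for n in counts.values()):
        raise ValueError(f"every group needs n >= 2, got {counts}")
    rng = np.random.default_rng(rng)
    ref = pipeline(subjects)
    V_ref = np.asarray(ref.voxel_saliences, dtype=float)
    U_ref = np.asarray(ref.design_saliences, dtype=float)
    VS_ref = V_ref * np.asarray(ref.singular_values, dtype=float)[None, :]
    boot_VS = np.empty((n_boot, *V_ref.shape))
    boot_scores = [] if score_fn is not None else None
    n_redrawn = 0
    ref_rank_ok = np.linalg.matrix_rank(U_ref) == min(U_ref.shape)
    for b in range(n_boot):
        while True:
            sample = _stratified_resample(subjects, rng)
            if {s.group for s in sample} == set(counts):
                break
            n_redrawn += 1  # pragma: no cover - cannot occur with resampling
            logger.warning("degenerate bootstrap draw redrawn (%d)", n_redrawn)
        d = pipeline(sample)
        V_b = np.asarray(d.voxel_saliences, dtype=float)
        VS_b = V_b * np.asarray(d.singular_values, dtype=float)[None, :]
        if align == "procrustes":
            # rotation determined on the (small) design-side saliences and
            # applied to both sides, keeping the pairing intact
            U_b = np.asarray(d.design_saliences, dtype=float)
            R = (
                procrustes_rotation(U_b, U_ref)
                if ref_rank_ok
                else _sign_flips(U_b, U_ref)
            )
            VS_b, V_b = VS_b @ R, V_b @ R
        elif align != "none":
            flips = _sign_flips(V_b, V_ref)
            VS_b, V_b = VS_b @ flips, V_b @ flips
        boot_VS[b] = VS_b
        if boot_scores is not None:
            boot_scores.append(score_fn(sample, V_b))
    se = boot_VS.std(axis=0, ddof=1)
    # float rounding in the mean leaves ~1e-16 residue even for bit-identical
    # resamples; snap those to the exact-zero degenerate case
    tol = 1e-12 * max(1.0, float(np.abs(boot_VS).max(initial=0.0)))
    se[se < tol] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(
            se > 0, VS_ref / np.where(se > 0, se, 1.0), np.inf * np.sign(VS_ref)
        )
    score_cis = None
    if boot_scores is not None:
        arr = np.asarray(boot_scores)  # (n_boot, cells, L)
        lo, hi = (100 - ci) / 2, 100 - (100 - ci) / 2
        score_cis = np.stack(
            [np.percentile(arr, lo, axis=0), np.percentile(arr, hi, axis=0)], axis=-1
        )
    return BootstrapResult(
        n_iterations=n_boot,
        salience_se=se,
        bootstrap_ratios=bsr,
        score_cis=score_cis,
        alignment_applied=align,
    )


def threshold_bsr(bsr: np.ndarray, cutoff: float = 2.58) -> np.ndarray:
    """Signed reliability mask: +1 / -1 where finite |BSR| >= cutoff, else 0.

    Non-finite bootstrap ratios (zero-SE sentinels) are excluded from maps.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    b = np.asarray(bsr, dtype=float)
    finite = np.isfinite(b)
    out = np.zeros(b.shape, dtype=np.int8)
    hit = finite & (np.abs(b) >= cutoff)
    out[hit] = np.sign(b[hit]).astype(np.int8)
    return out
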