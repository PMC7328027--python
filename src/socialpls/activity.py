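"""Reduce block-level signal to per-subject voxel x condition matrices.

The analyses consume, per subject, one baseline-normalized activity value
per voxel per condition: block means are normalized against the fixation
period preceding each block and then averaged over that condition's blocks.
Baseline normalization is subtraction by default (difference from the
preceding fixation); percent signal change is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BlockSeries",
    "SubjectActivity",
    "baseline_normalize_block",
    "average_condition_activity",
    "exclude_conditions",
]


@dataclass(frozen=True)
class BlockSeries:
    """One block's per-voxel mean signal plus its preceding fixation mean."""

    subject_id: str
    run: int
    block: int
    condition: str
    voxel_values: np.ndarray
    preceding_fixation: np.ndarray | None = None


@dataclass(frozen=True)
class SubjectActivity:
    """One subject's voxel x condition matrix of baseline-normalized activity."""

    subject_id: str
    group: str
    conditions: tuple[str, ...]
    matrix: np.ndarray  # (n_voxels, n_conditions)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(self.conditions):
            raise ValueError(
                f"matrix shape {m.shape} does not match "
                f"{len(self.conditions)} conditions"
            )
        if not np.all(np.isfinite(m)):
            raise ValueError("activity matrix contains non-finite entries")
        object.__setattr__(self, "matrix", m)

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    def column(self, condition: str) -> np.ndarray:
        return self.matrix[:, self.conditions.index(condition)]


def baseline_normalize_block(block: BlockSeries, mode: str = "subtract") -> np.ndarray:
    """Normalize one block's voxel means against its preceding fixation.

    ``mode='subtract'`` returns ``block - fixation``; ``mode='percent'``
    returns ``100 * (block - fixation) / fixation``.
    """
    if block.preceding_fixation is None:
        raise ValueError(
            f"block run={block.run} block={block.block} "
            f"({block.condition}) has no preceding fixation"
        )
    fix = np.asarray(block.preceding_fixation, dtype=float)
    val = np.asarray(block.voxel_values, dtype=float)
    if not np.all(np.isfinite(fix)):
        raise ValueError(
            f"non-finite fixation baseline in run={block.run} block={block.block}"
        )
    if mode == "subtract":
        return val - fix
    if mode == "percent":
        return 100.0 * (val - fix) / fix
    raise ValueError(f"unknown normalization mode {mode!r}")


def average_condition_activity(
    blocks: list[BlockSeries],
    conditions_kept: tuple[str, ...],
    group: str = "",
    mode: str = "subtract",
) -> SubjectActivity:
    """Average normalized block vectors per condition into a SubjectActivity.

    Conditions not in ``conditions_kept`` are dropped; a kept condition with
    no blocks is an error.
    """
    if not blocks:
        raise ValueError("no blocks supplied")
    subject_id = blocks[0].subject_id
    by_cond: dict[str, list[np.ndarray]] = {c: [] for c in conditions_kept}
    for b in blocks:
        if b.condition in by_cond:
            by_cond[b.condition].append(baseline_normalize_block(b, mode=mode))
    missing = [c for c, vs in by_cond.items() if not vs]
    if missing:
        raise ValueError(f"kept condition(s) with zero blocks: {missing}")
    matrix = np.column_stack([np.mean(by_cond[c], axis=0) for c in conditions_kept])
    return SubjectActivity(
        subject_id=subject_id,
        group=group,
        conditions=tuple(conditions_kept),
        matrix=matrix,
    )


def exclude_conditions(
    subjects: list[SubjectActivity], drop: tuple[str, ...]
) -> list[SubjectActivity]:
    """Drop condition columns from every subject, preserving column order."""
    if not subjects:
        return []
    have = subjects[0].conditions
    unknown = [c for c in drop if c not in have]
    if unknown:
        raise ValueError(f"unknown condition label(s) {unknown}; have {have}")
    keep = tuple(c for c in have if c not in drop)
    if not keep:
        raise ValueError("cannot drop every condition")
    idx = [have.index(c) for c in keep]
    out = []
    for s in subjects:
        if s.conditions != have:
            raise ValueError(
                f"subject {s.subject_id} condition order {s.conditions} "
                f"differs from {have}"
            )
        out.append(replace(s, conditions=keep, matrix=s.matrix[:, idx]))
    return out
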