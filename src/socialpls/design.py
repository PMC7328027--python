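"""Experimental design skeleton for the block-design trait-judgment task.

The study presents blocks of trait-judgment trials, one known person per
block, across social-closeness conditions (romantic partner, parent/child,
close friend, familiar acquaintance, famous person, self) plus a motor
control condition.  Blocks are separated by fixation; each condition appears
an equal number of times per run, and block order is randomized within run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Condition labels in the order used throughout the package.
CONDITIONS: tuple[str, ...] = (
    "partner",
    "parent_child",
    "friend",
    "acquaintance",
    "famous",
    "self",
    "control",
)

#: Conditions entering the task-PLS analysis (famous is excluded: participants
#: reported difficulty holding an unfamiliar famous other in mind).
ANALYSIS_CONDITIONS: tuple[str, ...] = (
    "partner",
    "parent_child",
    "friend",
    "acquaintance",
    "self",
    "control",
)

#: Conditions entering the seed-PLS connectivity analysis (social + self only).
SEED_CONDITIONS: tuple[str, ...] = (
    "partner",
    "parent_child",
    "friend",
    "acquaintance",
    "self",
)

#: (group label, sample size) — young and older adult cohorts.
GROUPS: tuple[tuple[str, int], ...] = (("young", 29), ("older", 27))


class DesignError(ValueError):
    """Raised when design counts cannot form a balanced block allocation."""


@dataclass(frozen=True)
class StudyDesign:
    """The experiment skeleton: groups, conditions, run/block/trial counts.

    Parameters
    ----------
    groups
        ``(label, n_subjects)`` pairs.
    conditions
        Ordered condition labels.
    n_runs, blocks_per_run, trials_per_block
        Block-design counts.
    trial_duration_s, inter_trial_fixation_s, inter_block_fixation_s
        Timing, in seconds.
    block_order
        Per-run tuple of condition labels, one per block (randomized within
        run, balanced across conditions).
    """

    groups: tuple[tuple[str, int], ...]
    conditions: tuple[str, ...]
    n_runs: int
    blocks_per_run: int
    trials_per_block: int
    trial_duration_s: float = 3.0
    inter_trial_fixation_s: float = 1.0
    inter_block_fixation_s: float = 10.0
    block_order: tuple[tuple[str, ...], ...] = field(default=())

    @property
    def total_trials(self) -> int:
        return self.n_runs * self.blocks_per_run * self.trials_per_block

    @property
    def blocks_per_condition_per_run(self) -> int:
        return self.blocks_per_run // len(self.conditions)

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.groups)

    def group_size(self, group: str) -> int:
        for g, n in self.groups:
            if g == group:
                return n
        raise KeyError(f"unknown group {group!r}; known: {self.group_labels}")


def generate_design(
    n_runs: int,
    blocks_per_run: int,
    trials_per_block: int,
    conditions: tuple[str, ...] = CONDITIONS,
    groups: tuple[tuple[str, int], ...] = GROUPS,
    rng: np.random.Generator | int | None = None,
) -> StudyDesign:
    """Build a :class:`StudyDesign` with a randomized, balanced block order.

    Each condition receives ``blocks_per_run / len(conditions)`` blocks per
    run; the within-run order is randomized.  Counts that do not divide
    evenly are refused.
    """
    if min(n_runs, blocks_per_run, trials_per_block) < 1:
        raise DesignError("all design counts must be >= 1")
    if not conditions:
        raise DesignError("at least one condition is required")
    k = len(conditions)
    rem = blocks_per_run % k
    if rem:
        raise DesignError(
            f"blocks_per_run={blocks_per_run} is not divisible by "
            f"{k} conditions (remainder {rem})"
        )
    rng = np.random.default_rng(rng)
    per = blocks_per_run // k
    order: list[tuple[str, ...]] = []
    for _ in range(n_runs):
        run = np.repeat(np.arange(k), per)
        rng.shuffle(run)
        order.append(tuple(conditions[i] for i in run))
    return StudyDesign(
        groups=tuple(groups),
        conditions=tuple(conditions),
        n_runs=n_runs,
        blocks_per_run=blocks_per_run,
        trials_per_block=trials_per_block,
        block_order=tuple(order),
    )


def default_design(rng: np.random.Generator | int | None = 0) -> StudyDesign:
    """The study's design: 5 runs x 14 blocks x 5 trials, 7 conditions."""
    return generate_design(5, 14, 5, CONDITIONS, GROUPS, rng)
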