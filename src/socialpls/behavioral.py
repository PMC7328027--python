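"""Closeness-instrument scoring and group comparisons.

Two self-report instruments quantify closeness to known others:

* **WHOTO** — ten items asking for up to four most-important figures, in
  order.  Scored here as rank-weighted totals: a target listed at rank *r*
  (1-based) on an item contributes ``5 - r`` points, so a figure listed
  first on every item scores the instrument maximum of 40.
* **IOS** (Inclusion of Other in Self) — a single-item 1-7 pictorial scale
  of overlapping circles.

Group comparisons mirror the recomputable tests: pooled-variance two-sample
t/F tests from summary statistics (young vs older within condition) and the
Friedman rank test across conditions within subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WhotoResponse",
    "score_whoto",
    "GroupSummary",
    "TwoSampleResult",
    "pooled_two_sample_from_summary",
    "welch_two_sample_from_summary",
    "FriedmanResult",
    "friedman_test",
    "summarize_by_condition",
]

WHOTO_ITEMS = 10
WHOTO_MAX_LISTED = 4


@dataclass(frozen=True)
class WhotoResponse:
    """One subject's answer to one WHOTO item: an ordered list of figures."""

    subject_id: str
    item_id: int
    listed_figures: tuple[str, ...]

    def __post_init__(self):
        if not 1 <= self.item_id <= WHOTO_ITEMS:
            raise ValueError(f"item_id {self.item_id} outside 1..{WHOTO_ITEMS}")
        if len(self.listed_figures) > WHOTO_MAX_LISTED:
            raise ValueError(
                f"item {self.item_id}: {len(self.listed_figures)} figures "
                f"listed, maximum is {WHOTO_MAX_LISTED}"
            )
        if len(set(self.listed_figures)) != len(self.listed_figures):
            raise ValueError(f"item {self.item_id}: duplicate figures listed")


def score_whoto(responses: list[WhotoResponse], target: str) -> int:
    """Rank-weighted WHOTO total for one subject and one target figure.

    Per item, the target at rank r (1-based) contributes ``5 - r`` points;
    an unlisted target contributes 0.  Ten items, so the total is 0-40.
    """
    if len(responses) > WHOTO_ITEMS:
        raise ValueError(f"{len(responses)} items supplied; expected {WHOTO_ITEMS}")
    if len(responses) != WHOTO_ITEMS:
        raise ValueError(
            f"expected {WHOTO_ITEMS} items per subject, got {len(responses)}"
        )
    if len({r.item_id for r in responses}) != WHOTO_ITEMS:
        raise ValueError("duplicate or missing item ids")
    total = 0
    for r in responses:
        if target in r.listed_figures:
            rank = r.listed_figures.index(target) + 1
            total += 5 - rank
    return total


class GroupSummary(NamedTuple):
    n: int
    mean: float
    sd: float


class TwoSampleResult(NamedTuple):
    t: float
    F: float
    df: tuple[float, float]
    p: float


def pooled_two_sample_from_summary(
    a: GroupSummary | tuple, b: GroupSummary | tuple
) -> TwoSampleResult:
    """Pooled-variance two-sample t (and F = t^2) from (n, mean, sd) pairs.

    df = n_a + n_b - 2; two-tailed p from the t distribution.  Direction is
    b - a, so the t statistic is positive when group b's mean is larger.
    """
    a, b = GroupSummary(*a), GroupSummary(*b)
    for g in (a, b):
        if g.n < 2:
            raise ValueError(f"group n must be >= 2, got {g.n}")
        if g.sd < 0:
            raise ValueError("sd must be non-negative")
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        if a.mean == b.mean:
            return TwoSampleResult(0.0, 0.0, (1.0, float(df)), 1.0)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    t = (b.mean - a.mean) / se
    p = 2 * stats.t.sf(abs(t), df)
    return TwoSampleResult(float(t), float(t * t), (1.0, float(df)), float(p))


def welch_two_sample_from_summary(
    a: GroupSummary | tuple, b: GroupSummary | tuple
) -> TwoSampleResult:
    """Welch (unequal-variance) variant of the two-sample test."""
    a, b = GroupSummary(*a), GroupSummary(*b)
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0:
        if a.mean == b.mean:
            return TwoSampleResult(0.0, 0.0, (1.0, float(a.n + b.n - 2)), 1.0)
        raise ValueError("zero variance with unequal means: t undefined")
    t = (b.mean - a.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return TwoSampleResult(float(t), float(t * t), (1.0, float(df)), float(p))


class FriedmanResult(NamedTuple):
    chi2: float
    df: int
    p: float


def friedman_test(scores: np.ndarray) -> FriedmanResult:
    """Friedman rank test over a subjects x conditions matrix.

    Within-subject ranks (average ranks for ties);
    chi2 = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1), df = k - 1.
    """
    m = np.asarray(scores, dtype=float)
    if m.ndim != 2:
        raise ValueError("scores must be a 2-D subjects x conditions array")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 conditions, got {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing or non-finite cells are not allowed")
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    df = k - 1
    p = stats.chi2.sf(chi2, df)
    return FriedmanResult(float(chi2), df, float(p))


def summarize_by_condition(
    table: pd.DataFrame,
    measures: tuple[str, ...] = ("whoto_total", "ios", "relationship_length_years"),
) -> pd.DataFrame:
    """Per group x condition n / mean / sample sd (n-1 denominator).

    ``table`` is tidy: one row per (subject, group, condition) with measure
    columns.  A cell with a single observation reports sd as missing.
    """
    if table.empty:
        raise ValueError("behavioral table is empty")
    present = [m for m in measures if m in table.columns]
    rows = []
    for (group, cond), sub in table.groupby(["group", "condition"], sort=False):
        for m in present:
            vals = sub[m].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "group": group,
                    "condition": cond,
                    "measure": m,
                    "n": len(vals),
                    "mean": float(np.mean(vals)) if len(vals) else np.nan,
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
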