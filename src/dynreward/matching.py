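"""Generalized matching-law analysis of block-level choice allocation.

The generalized matching law relates the log choice ratio to the log
ratio of rewards actually received::

    log2(C_A / C_B) = s * log2(R_A / R_B) + log2(k)

The slope ``s`` (reward sensitivity) measures how closely choice
allocation tracks experienced reward frequencies — ``s = 1`` is strict
matching, ``s < 1`` undermatching; the intercept ``log2 k`` is a deck
bias.  Counts are taken over the *steady-state window*, within-block
trials 21-70 inclusive, and any block where a deck yielded no reward
(``R_A`` or ``R_B`` = 0) is excluded because its log ratio is undefined.
Block-level points are pooled within a group and fitted with OLS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .rl import SubjectData, TrialRecord

__all__ = [
    "BlockAggregate",
    "MatchingFit",
    "STEADY_STATE_WINDOW",
    "aggregate_block",
    "aggregate_subject",
    "filter_blocks",
    "fit_matching",
    "compare_sensitivity",
]

#: Default steady-state window: 1-based within-block trial indices, inclusive.
STEADY_STATE_WINDOW = (21, 70)


@dataclass(frozen=True)
class BlockAggregate:
    """Choice and reward counts for one block's steady-state window."""

    subject_id: str
    block_index: int
    c_A: int
    c_B: int
    r_A: int
    r_B: int

    def __post_init__(self) -> None:
        if min(self.c_A, self.c_B, self.r_A, self.r_B) < 0:
            raise ValueError("counts must be non-negative")
        if self.r_A > self.c_A or self.r_B > self.c_B:
            raise ValueError("reward count cannot exceed choice count")


@dataclass(frozen=True)
class MatchingFit:
    """OLS fit of the generalized matching law over block-level points."""

    sensitivity: float
    bias: float
    se_sensitivity: float
    r_squared: float
    n_points: int


def aggregate_block(
    trials: Sequence[TrialRecord],
    window: tuple[int, int] = STEADY_STATE_WINDOW,
    subject_id: str = "",
    allow_short: bool = False,
) -> BlockAggregate:
    """Count choices and rewards per deck over the steady-state window.

    ``trials`` must be the trials of a single block in temporal order;
    ``window`` is 1-based within-block and inclusive.  Blocks shorter
    than the window end raise unless ``allow_short`` truncates instead.
    """
    lo, hi = window
    if lo < 1 or hi < lo:
        raise ValueError(f"bad window {window}")
    if len(trials) < hi and not allow_short:
        raise ValueError(f"block has {len(trials)} trials, fewer than window end {hi}")
    c = {"A": 0, "B": 0}
    r = {"A": 0, "B": 0}
    for pos, t in enumerate(trials, start=1):
        if lo <= pos <= hi:
            c[t.choice] += 1
            r[t.choice] += t.reward
    block_index = trials[0].block_index if trials else 0
    return BlockAggregate(subject_id, block_index, c["A"], c["B"], r["A"], r["B"])


def aggregate_subject(
    data: SubjectData, window: tuple[int, int] = STEADY_STATE_WINDOW
) -> list[BlockAggregate]:
    """One BlockAggregate per block of a subject's session."""
    by_block: dict[int, list[TrialRecord]] = {}
    for t in data.trials:
        by_block.setdefault(t.block_index, []).append(t)
    return [
        aggregate_block(by_block[b], window, subject_id=data.subject_id)
        for b in sorted(by_block)
    ]


def filter_blocks(aggregates: Iterable[BlockAggregate]) -> list[BlockAggregate]:
    """Drop blocks with zero rewards from either deck (log-undefined)."""
    return [a for a in aggregates if a.r_A > 0 and a.r_B > 0]


def fit_matching(aggregates: Sequence[BlockAggregate]) -> MatchingFit:
    """Pooled OLS of log2 choice ratio on log2 reward ratio.

    Aggregates should already have passed :func:`filter_blocks`; blocks
    where a deck was never chosen (which can only survive the reward
    filter by inconsistency) are dropped defensively.
    """
    usable = [a for a in aggregates if a.c_A > 0 and a.c_B > 0 and a.r_A > 0 and a.r_B > 0]
    if len(usable) < 3:
        raise ValueError(f"need at least 3 usable block-level points, got {len(usable)}")
    x = np.log2([a.r_A / a.r_B for a in usable])
    y = np.log2([a.c_A / a.c_B for a in usable])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return MatchingFit(
        sensitivity=float(model.params[1]),
        bias=float(model.params[0]),
        se_sensitivity=float(model.bse[1]),
        r_squared=float(model.rsquared),
        n_points=len(usable),
    )


def compare_sensitivity(fit1: MatchingFit, fit2: MatchingFit) -> tuple[float, float]:
    """One-tailed t-test of slope difference between two matching fits.

    Returns ``(t, p)`` with ``t = (s1 - s2) / sqrt(se1^2 + se2^2)`` on
    ``n1 + n2 - 4`` degrees of freedom (two slopes and two intercepts
    estimated); ``p`` is the one-tailed probability of a difference at
    least this large in the direction ``s1 > s2``.
    """
    if fit1.se_sensitivity <= 0 or fit2.se_sensitivity <= 0:
        raise ValueError("both fits must carry positive slope standard errors")
    t = (fit1.sensitivity - fit2.sensitivity) / np.hypot(fit1.se_sensitivity, fit2.se_sensitivity)
    df = fit1.n_points + fit2.n_points - 4
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    p = float(stats.t.sf(t, df))
    return float(t), p
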