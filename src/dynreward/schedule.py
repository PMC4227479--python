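"""Reward environment of the dynamic reward task (DRT).

The DRT presents two decks, A and B, with fixed per-trial reward
probabilities inside a block; the advantageous deck alternates across
unsignalled blocks while the total gain probability stays at 0.6.  Rewards
are *non-baited*: the reward status of each deck is redrawn on every trial,
so unclaimed rewards never accumulate.

Probabilities come from small-integer gain ratios (1:6 and 1:3 at total
0.6).  The 1:6 split does not have a finite decimal form (3/35 and 18/35,
conventionally printed as 8.57% and 51.43%); blocks store the exact values
so invariants such as ``prob_A + prob_B == 0.6`` hold to within floating
point, and rounding happens only at display time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator

import numpy as np

__all__ = [
    "Block",
    "TaskSchedule",
    "probs_from_ratio",
    "make_schedule",
    "draw_reward",
    "SCHEDULE_LABELS",
    "TOTAL_GAIN_PROBABILITY",
]

#: Total probability of a 1-point gain summed over the two decks, shared by
#: the training schedule and every testing block.
TOTAL_GAIN_PROBABILITY = 0.6

# "training-swapped" is the training schedule with the deck roles mirrored;
# it exists so that per-subject randomization of which physical deck is
# advantageous stays self-describing in serialized trial data.
SCHEDULE_LABELS = ("training", "sequence-1", "sequence-2", "training-swapped")

DECKS = ("A", "B")


def probs_from_ratio(ratio_low_to_high: tuple[int, int], total: float) -> tuple[float, float]:
    """Split a total gain probability between two decks at a given ratio.

    Parameters
    ----------
    ratio_low_to_high
        Pair of positive integers ``(low, high)``; the returned
        probabilities satisfy ``p_high / p_low == high / low``.
    total
        Total gain probability ``p_low + p_high``, in ``(0, 1]``.

    Returns
    -------
    tuple of float
        ``(p_low, p_high)``, computed with exact rational arithmetic
        before the final conversion to float.

    Examples
    --------
    >>> probs_from_ratio((1, 6), 0.6)  # doctest: +ELLIPSIS
    (0.0857142..., 0.5142857...)
    """
    low, high = ratio_low_to_high
    if low <= 0 or high <= 0:
        raise ValueError(f"ratio components must be positive, got {ratio_low_to_high}")
    if not 0 < total <= 1:
        raise ValueError(f"total gain probability must be in (0, 1], got {total}")
    total_frac = Fraction(total).limit_denominator(10**9)
    p_low = total_frac * low / (low + high)
    p_high = total_frac * high / (low + high)
    return float(p_low), float(p_high)


@dataclass(frozen=True)
class Block:
    """One block of trials with fixed per-deck reward probabilities."""

    prob_A: float
    prob_B: float
    n_trials: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob_A <= 1.0 and 0.0 <= self.prob_B <= 1.0):
            raise ValueError(f"deck probabilities must lie in [0, 1]: {self.prob_A}, {self.prob_B}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be positive, got {self.n_trials}")

    def prob(self, deck: str) -> float:
        if deck == "A":
            return self.prob_A
        if deck == "B":
            return self.prob_B
        raise ValueError(f"unknown deck {deck!r}")

    @property
    def advantageous_deck(self) -> str:
        """Deck with the higher reward probability ('A' on ties)."""
        return "A" if self.prob_A >= self.prob_B else "B"


@dataclass(frozen=True)
class TaskSchedule:
    """Ordered sequence of blocks forming one DRT session."""

    blocks: tuple[Block, ...]
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not self.blocks:
            raise ValueError("a schedule needs at least one block")

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def __iter__(self) -> Iterator[Block]:
        return iter(self.blocks)

    def block_of_trial(self, trial_index: int) -> int:
        """1-based block index containing the 1-based session trial index."""
        if not 1 <= trial_index <= self.n_trials:
            raise ValueError(f"trial index {trial_index} outside session of {self.n_trials} trials")
        cum = 0
        for i, b in enumerate(self.blocks, start=1):
            cum += b.n_trials
            if trial_index <= cum:
                return i
        raise AssertionError("unreachable")

    def prob_matrix(self) -> np.ndarray:
        """Per-trial reward probabilities, shape ``(n_trials, 2)`` for decks (A, B)."""
        rows = []
        for b in self.blocks:
            rows.append(np.tile([b.prob_A, b.prob_B], (b.n_trials, 1)))
        return np.concatenate(rows, axis=0)

    def block_index_array(self) -> np.ndarray:
        """1-based block index of every trial, shape ``(n_trials,)``."""
        return np.repeat(np.arange(1, self.n_blocks + 1), [b.n_trials for b in self.blocks])

    # -- JSON config round-trip -------------------------------------------

    def to_json(self) -> str:
        payload = {
            "label": self.label,
            "blocks": [
                {"prob_A": b.prob_A, "prob_B": b.prob_B, "n_trials": b.n_trials} for b in self.blocks
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskSchedule":
        payload = json.loads(text)
        blocks = tuple(Block(b["prob_A"], b["prob_B"], int(b["n_trials"])) for b in payload["blocks"])
        return cls(blocks=blocks, label=payload["label"])


# Exact split of 0.6 at ratios 1:6 and 1:3.
_P_LOW_16, _P_HIGH_16 = probs_from_ratio((1, 6), TOTAL_GAIN_PROBABILITY)  # 3/35, 18/35
_P_LOW_13, _P_HIGH_13 = probs_from_ratio((1, 3), TOTAL_GAIN_PROBABILITY)  # 0.15, 0.45

# Testing sequences: per-block (prob_A, prob_B, n_trials).  The advantageous
# deck alternates every block and the gain ratio changes at each switch.
_SEQUENCE_1 = (
    (_P_HIGH_13, _P_LOW_13, 70),
    (_P_LOW_16, _P_HIGH_16, 80),
    (_P_HIGH_13, _P_LOW_13, 90),
    (_P_LOW_16, _P_HIGH_16, 90),
    (_P_HIGH_16, _P_LOW_16, 80),
    (_P_LOW_13, _P_HIGH_13, 70),
)
_SEQUENCE_2 = (
    (_P_HIGH_13, _P_LOW_13, 80),
    (_P_LOW_16, _P_HIGH_16, 70),
    (_P_HIGH_16, _P_LOW_16, 90),
    (_P_LOW_13, _P_HIGH_13, 80),
    (_P_HIGH_16, _P_LOW_16, 70),
    (_P_LOW_13, _P_HIGH_13, 90),
)


def make_schedule(label: str) -> TaskSchedule:
    """Build one of the canonical DRT schedules.

    ``training`` is a single 40-trial block at gain ratio 1:6 (deck A low);
    ``sequence-1`` and ``sequence-2`` are the two pseudorandom six-block
    testing sequences totalling 480 trials each.
    """
    if label == "training":
        blocks = (Block(_P_LOW_16, _P_HIGH_16, 40),)
    elif label == "training-swapped":
        blocks = (Block(_P_HIGH_16, _P_LOW_16, 40),)
    elif label == "sequence-1":
        blocks = tuple(Block(a, b, n) for a, b, n in _SEQUENCE_1)
    elif label == "sequence-2":
        blocks = tuple(Block(a, b, n) for a, b, n in _SEQUENCE_2)
    else:
        raise ValueError(f"unknown schedule label {label!r}; expected one of {SCHEDULE_LABELS}")
    return TaskSchedule(blocks=blocks, label=label)


def swap_decks(schedule: TaskSchedule) -> TaskSchedule:
    """Relabel decks A<->B in every block (used to randomize deck roles)."""
    return TaskSchedule(
        blocks=tuple(Block(b.prob_B, b.prob_A, b.n_trials) for b in schedule.blocks),
        label=schedule.label,
    )


def draw_reward(block: Block, choice: str, rng: np.random.Generator) -> int:
    """Draw the 0/1 reward for the chosen deck on one trial.

    Rewards are independent across trials (non-baited design): the unchosen
    deck's reward status is simply redrawn next trial, so only the chosen
    deck needs a draw.
    """
    p = block.prob(choice)
    return int(rng.random() < p)
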