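"""Q-learning model of DRT choice behaviour.

The model has two parts.  The value-updating rule adjusts the chosen
deck's expected value by a fraction ``alpha`` (the learning rate) of the
reward prediction error ``R(t) - Q(t)``::

    Q(t+1) = Q(t) + alpha * (R(t) - Q(t))

Only the chosen deck is updated: the non-baited design yields no feedback
about the unchosen deck, whose value carries over unchanged.  The softmax
choice rule converts the value difference into a choice probability::

    P_A = exp(beta * Q_A) / (exp(beta * Q_A) + exp(beta * Q_B))

``beta`` (choice perseveration, a.k.a. inverse temperature) scales how
strongly value differences drive choice; ``beta = 0`` is random choice.
Both decks start the session at ``Q = 0``.

Besides the scalar reference implementations, this module provides
vectorized kernels (:func:`simulate_many`, :func:`forward_signed_qdiff`)
that run whole cohorts or parameter grids through the 480-trial recursion
with NumPy; the scalar and vectorized paths are cross-checked in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .schedule import TaskSchedule, SCHEDULE_LABELS, make_schedule

__all__ = [
    "AgentParams",
    "QState",
    "TrialRecord",
    "SubjectData",
    "q_update",
    "choice_prob",
    "log_likelihood",
    "simulate_agent",
    "simulate_many",
    "forward_signed_qdiff",
    "loglik_from_qdiff",
    "mle_grid",
    "PROB_FLOOR",
]

#: Floor applied to per-trial choice probabilities before taking logs, so
#: likelihoods stay finite for extreme beta.
PROB_FLOOR = 1e-12

GROUPS = ("control", "low-psychosis", "high-psychosis")


@dataclass(frozen=True)
class AgentParams:
    """Learning rate and choice perseveration of one agent."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


@dataclass
class QState:
    """Expected values of the two decks, in reward units."""

    q_A: float = 0.0
    q_B: float = 0.0


@dataclass(frozen=True)
class TrialRecord:
    """One observed trial: the chosen deck and the 0/1 reward received."""

    block_index: int
    trial_index: int
    choice: str
    reward: int

    def __post_init__(self) -> None:
        if self.choice not in ("A", "B"):
            raise ValueError(f"choice must be 'A' or 'B', got {self.choice!r}")
        if self.reward not in (0, 1):
            raise ValueError(f"reward must be 0 or 1, got {self.reward!r}")


@dataclass
class SubjectData:
    """One subject's choice-reward sequence for one session."""

    subject_id: str
    group: str
    schedule_label: str
    trials: list[TrialRecord]
    covariates: dict[str, float] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_score(self) -> int:
        return sum(t.reward for t in self.trials)

    def choices_array(self) -> np.ndarray:
        """Choices encoded 0 for deck A, 1 for deck B."""
        return np.fromiter((0 if t.choice == "A" else 1 for t in self.trials), dtype=np.int8, count=self.n_trials)

    def rewards_array(self) -> np.ndarray:
        return np.fromiter((t.reward for t in self.trials), dtype=np.int8, count=self.n_trials)

    @classmethod
    def from_arrays(
        cls,
        subject_id: str,
        group: str,
        schedule: TaskSchedule,
        choices: np.ndarray,
        rewards: np.ndarray,
        covariates: dict[str, float] | None = None,
    ) -> "SubjectData":
        blocks = schedule.block_index_array()
        trials = [
            TrialRecord(int(blocks[t]), t + 1, "A" if choices[t] == 0 else "B", int(rewards[t]))
            for t in range(len(choices))
        ]
        return cls(subject_id, group, schedule.label, trials, dict(covariates or {}))


def q_update(q: float, reward: int, alpha: float) -> float:
    """Delta-rule update of an expected value toward the received reward."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return q + alpha * (reward - q)


def choice_prob(q: QState | tuple[float, float], beta: float) -> float:
    """Softmax probability of choosing deck A given the current Q-state."""
    if beta < 0.0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    if isinstance(q, QState):
        q_a, q_b = q.q_A, q.q_B
    else:
        q_a, q_b = q
    # expit of the scaled value difference is the stable two-option softmax
    return float(expit(beta * (q_a - q_b)))


def _validate_trial_count(data: SubjectData) -> None:
    if data.schedule_label in SCHEDULE_LABELS:
        expected = make_schedule(data.schedule_label).n_trials
        if data.n_trials != expected:
            raise ValueError(
                f"subject {data.subject_id}: {data.n_trials} trials recorded but schedule "
                f"{data.schedule_label!r} has {expected}"
            )


def log_likelihood(data: SubjectData, params: AgentParams) -> float:
    """Log-likelihood (natural log) of a subject's choices under the model.

    The Q-state is run forward from ``(0, 0)`` through the recorded
    choices and rewards; each trial contributes the log softmax
    probability of the *recorded* choice, evaluated at the pre-choice
    Q-state.
    """
    if data.n_trials == 0:
        raise ValueError("cannot compute a likelihood for an empty session")
    _validate_trial_count(data)
    q_a = q_b = 0.0
    ll = 0.0
    floor = math.log(PROB_FLOOR)
    for t in data.trials:
        p_a = expit(params.beta * (q_a - q_b))
        p = p_a if t.choice == "A" else 1.0 - p_a
        ll += max(math.log(p) if p > 0.0 else floor, floor)
        if t.choice == "A":
            q_a += params.alpha * (t.reward - q_a)
        else:
            q_b += params.alpha * (t.reward - q_b)
    return ll


# ---------------------------------------------------------------------------
# Vectorized kernels
# ---------------------------------------------------------------------------

def simulate_many(
    alphas: np.ndarray,
    betas: np.ndarray,
    schedule: TaskSchedule,
    u_choice: np.ndarray,
    u_reward: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate many independent agents through one schedule.

    Parameters
    ----------
    alphas, betas
        Per-agent parameters, shape ``(n,)``.
    u_choice, u_reward
        Pre-drawn uniforms, shape ``(n, n_trials)``; agent ``i`` chooses
        deck A on trial ``t`` iff ``u_choice[i, t] < P_A``, and the chosen
        deck pays iff ``u_reward[i, t] < p_chosen``.

    Returns
    -------
    (choices, rewards)
        ``int8`` arrays of shape ``(n, n_trials)``; choices are 0 for A,
        1 for B.
    """
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    probs = schedule.prob_matrix()
    n, n_trials = u_choice.shape
    if probs.shape[0] != n_trials:
        raise ValueError(f"uniforms cover {n_trials} trials but schedule has {probs.shape[0]}")
    q_a = np.zeros(n)
    q_b = np.zeros(n)
    choices = np.empty((n, n_trials), dtype=np.int8)
    rewards = np.empty((n, n_trials), dtype=np.int8)
    for t in range(n_trials):
        p_a = expit(betas * (q_a - q_b))
        c = (u_choice[:, t] >= p_a).astype(np.int8)  # 0 = A, 1 = B
        p_chosen = np.where(c == 0, probs[t, 0], probs[t, 1])
        r = (u_reward[:, t] < p_chosen).astype(np.int8)
        q_c = np.where(c == 0, q_a, q_b)
        q_new = q_c + alphas * (r - q_c)
        q_a = np.where(c == 0, q_new, q_a)
        q_b = np.where(c == 1, q_new, q_b)
        choices[:, t] = c
        rewards[:, t] = r
    return choices, rewards


def simulate_agent(
    params: AgentParams,
    schedule: TaskSchedule,
    rng: np.random.Generator,
    subject_id: str = "sim",
    group: str = "simulated",
) -> SubjectData:
    """Forward-simulate a single agent through a schedule."""
    n_trials = schedule.n_trials
    u_choice = rng.random((1, n_trials))
    u_reward = rng.random((1, n_trials))
    choices, rewards = simulate_many(
        np.array([params.alpha]), np.array([params.beta]), schedule, u_choice, u_reward
    )
    return SubjectData.from_arrays(subject_id, group, schedule, choices[0], rewards[0])


def forward_signed_qdiff(choices: np.ndarray, rewards: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Run the value recursion and return per-trial signed Q-differences.

    Entry ``[i, t]`` is ``Q_chosen - Q_unchosen`` at the pre-choice state
    of trial ``t`` for subject ``i``, signed toward the deck actually
    chosen.  The log-likelihood for any beta then follows from
    :func:`loglik_from_qdiff` without rerunning the recursion — the
    workhorse decomposition behind the MCMC sampler and grid fitting.
    """
    choices = np.asarray(choices)
    rewards = np.asarray(rewards)
    alphas = np.asarray(alphas, dtype=float)
    n, n_trials = choices.shape
    q_a = np.zeros(n)
    q_b = np.zeros(n)
    signed = np.empty((n, n_trials))
    for t in range(n_trials):
        c = choices[:, t]
        d = q_a - q_b
        signed[:, t] = np.where(c == 0, d, -d)
        q_c = np.where(c == 0, q_a, q_b)
        q_new = q_c + alphas * (rewards[:, t] - q_c)
        q_a = np.where(c == 0, q_new, q_a)
        q_b = np.where(c == 1, q_new, q_b)
    return signed


def loglik_from_qdiff(signed_qdiff: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """Per-subject log-likelihood from cached signed Q-differences."""
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    x = betas[:, None] * signed_qdiff
    per_trial = -np.logaddexp(0.0, -x)  # log sigmoid(x)
    np.maximum(per_trial, math.log(PROB_FLOOR), out=per_trial)
    return per_trial.sum(axis=1)


def mle_grid(
    data: SubjectData,
    alpha_grid: Sequence[float],
    beta_grid: Sequence[float],
) -> tuple[AgentParams, float]:
    """Maximum-likelihood (alpha, beta) over a parameter grid.

    Exhaustive grid search; the likelihood surface is cheap because the
    value recursion is run once per alpha and reused across betas.
    """
    choices = data.choices_array()[None, :]
    rewards = data.rewards_array()[None, :]
    best_ll = -np.inf
    best = None
    for a in alpha_grid:
        signed = forward_signed_qdiff(choices, rewards, np.array([a]))
        lls = loglik_from_qdiff(np.repeat(signed, len(beta_grid), axis=0), np.asarray(beta_grid))
        k = int(np.argmax(lls))
        if lls[k] > best_ll:
            best_ll = float(lls[k])
            best = AgentParams(alpha=float(a), beta=float(beta_grid[k]))
    assert best is not None
    return best, best_ll
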