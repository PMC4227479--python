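"""Q-learning value updates, softmax choice rule, likelihood and simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynreward.rl import (
    AgentParams,
    QState,
    SubjectData,
    TrialRecord,
    choice_prob,
    forward_signed_qdiff,
    log_likelihood,
    loglik_from_qdiff,
    mle_grid,
    q_update,
    simulate_agent,
    simulate_many,
)
from dynreward.schedule import Block, TaskSchedule, make_schedule


# ---------------------------------------------------------------------------
# value update
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "q, reward, alpha, expected",
    [(0.0, 1, 0.5, 0.5), (0.2, 1, 1.0, 1.0), (0.7, 0, 0.1, 0.63)],
)
def test_q_update_examples(q, reward, alpha, expected):
    assert q_update(q, reward, alpha) == pytest.approx(expected)


def test_q_update_fixed_point_and_bounds_error():
    assert q_update(0.8, 0.8, 0.3) == pytest.approx(0.8)  # zero RPE is a fixed point
    with pytest.raises(ValueError):
        q_update(0.5, 1, 1.5)


@settings(deadline=None, derandomize=True)
@given(
    alpha=st.floats(0.0, 1.0),
    seed=st.integers(0, 10_000),
)
def test_q_values_stay_bounded(alpha, seed):
    """Binary rewards and alpha in [0,1] keep Q in [0,1] from a zero start."""
    rng = np.random.default_rng(seed)
    q = 0.0
    for _ in range(50):
        q = q_update(q, int(rng.random() < 0.5), alpha)
        assert 0.0 <= q <= 1.0


# ---------------------------------------------------------------------------
# softmax choice rule
# ---------------------------------------------------------------------------

def test_choice_prob_examples():
    assert choice_prob(QState(0.4, 0.4), 5.0) == 0.5          # symmetric values
    assert choice_prob((0.9, 0.1), 0.0) == 0.5                # beta=0 is random choice
    assert choice_prob((1.0, 0.0), math.log(3)) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        choice_prob((0.5, 0.5), -1.0)


@settings(deadline=None, derandomize=True)
@given(
    q_a=st.floats(0.0, 1.0),
    q_b=st.floats(0.0, 1.0),
    beta=st.floats(0.0, 50.0),
)
def test_choice_prob_normalization_and_symmetry(q_a, q_b, beta):
    p = choice_prob((q_a, q_b), beta)
    assert 0.0 < p < 1.0
    assert p + choice_prob((q_b, q_a), beta) == pytest.approx(1.0)


def test_choice_prob_monotone():
    diffs = np.linspace(-1, 1, 21)
    probs = [choice_prob((0.5 + d / 2, 0.5 - d / 2), 3.0) for d in diffs]
    assert all(a < b for a, b in zip(probs, probs[1:]))  # increasing in q_A - q_B
    betas = np.linspace(0, 20, 21)
    probs = [choice_prob((0.8, 0.2), b) for b in betas]
    assert all(a < b for a, b in zip(probs, probs[1:]))  # increasing in beta when q_A > q_B


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _replay_loglik(trials, alpha, beta):
    """Independent brute-force replay used as the likelihood oracle."""
    q = {"A": 0.0, "B": 0.0}
    ll = 0.0
    for t in trials:
        num = math.exp(beta * q[t.choice])
        den = math.exp(beta * q["A"]) + math.exp(beta * q["B"])
        ll += math.log(num / den)
        q[t.choice] += alpha * (t.reward - q[t.choice])
    return ll


def _make_subject(choices, rewards, label="custom"):
    trials = [
        TrialRecord(1, i + 1, c, r) for i, (c, r) in enumerate(zip(choices, rewards))
    ]
    return SubjectData("s1", "control", label, trials)


def test_log_likelihood_random_choice_baseline(seq1):
    data = simulate_agent(AgentParams(0.5, 3.0), seq1, np.random.default_rng(0))
    ll = log_likelihood(data, AgentParams(0.9, 0.0))
    assert ll == pytest.approx(480 * math.log(0.5))


def test_log_likelihood_single_trial_symmetric_start():
    data = _make_subject(["B"], [1])
    assert log_likelihood(data, AgentParams(0.3, 5.0)) == pytest.approx(math.log(0.5))


def test_log_likelihood_matches_bruteforce_replay():
    rng = np.random.default_rng(99)
    for _ in range(25):
        n = 10
        choices = ["A" if c else "B" for c in rng.integers(0, 2, n)]
        rewards = list(map(int, rng.integers(0, 2, n)))
        alpha, beta = rng.uniform(0, 1), rng.uniform(0, 8)
        data = _make_subject(choices, rewards)
        assert log_likelihood(data, AgentParams(alpha, beta)) == pytest.approx(
            _replay_loglik(data.trials, alpha, beta), rel=1e-10
        )


def test_vectorized_loglik_matches_scalar(seq1):
    data = simulate_agent(AgentParams(0.6, 4.0), seq1, np.random.default_rng(5))
    choices = data.choices_array()[None, :]
    rewards = data.rewards_array()[None, :]
    for alpha, beta in [(0.6, 4.0), (0.2, 1.0), (0.95, 9.0)]:
        signed = forward_signed_qdiff(choices, rewards, np.array([alpha]))
        vec = loglik_from_qdiff(signed, np.array([beta]))[0]
        assert vec == pytest.approx(log_likelihood(data, AgentParams(alpha, beta)), rel=1e-10)


def test_trial_count_mismatch_rejected(seq1):
    data = simulate_agent(AgentParams(0.5, 3.0), seq1, np.random.default_rng(1))
    data.trials.pop()
    with pytest.raises(ValueError, match="479 trials"):
        log_likelihood(data, AgentParams(0.5, 3.0))


def test_likelihood_self_consistency(seq1):
    """Data simulated at the true parameters is more likely under them."""
    n = 300
    rng = np.random.default_rng(21)
    u_c, u_r = rng.random((n, 480)), rng.random((n, 480))
    choices, rewards = simulate_many(np.full(n, 0.5), np.full(n, 4.0), seq1, u_c, u_r)
    signed = forward_signed_qdiff(choices, rewards, np.full(n, 0.5))
    ll_true = loglik_from_qdiff(signed, np.full(n, 4.0)).mean()
    ll_wrong = loglik_from_qdiff(signed, np.full(n, 0.5)).mean()
    assert ll_true > ll_wrong


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def test_simulate_agent_near_greedy_on_deterministic_schedule():
    sched = TaskSchedule((Block(1.0, 0.0, 100),), "custom")
    data = simulate_agent(AgentParams(1.0, 10.0), sched, np.random.default_rng(3))
    late = [t.choice for t in data.trials[5:]]
    assert np.mean([c == "A" for c in late]) >= 0.95


def test_simulate_random_policy_choice_fraction(seq1):
    n = 1000
    rng = np.random.default_rng(17)
    u_c, u_r = rng.random((n, 480)), rng.random((n, 480))
    choices, _ = simulate_many(np.full(n, 0.5), np.zeros(n), seq1, u_c, u_r)
    frac_a = (choices == 0).mean()
    se = 0.5 / math.sqrt(n * 480)
    assert abs(frac_a - 0.5) < 3 * se


def test_balanced_params_beat_fast_unperseverant_agent(seq1):
    scores = {}
    for label, (a, b) in {"balanced": (0.35, 7.0), "fast-random": (1.0, 0.5)}.items():
        rng = np.random.default_rng(8)  # same seeds for both agents
        u_c, u_r = rng.random((100, 480)), rng.random((100, 480))
        _, rewards = simulate_many(np.full(100, a), np.full(100, b), seq1, u_c, u_r)
        scores[label] = rewards.sum(axis=1).mean()
    assert scores["balanced"] > scores["fast-random"]


def test_simulate_agent_matches_vectorized_engine(seq1):
    params = AgentParams(0.4, 5.0)
    single = simulate_agent(params, seq1, np.random.default_rng(123))
    rng = np.random.default_rng(123)
    u_c, u_r = rng.random((1, 480)), rng.random((1, 480))
    choices, rewards = simulate_many(np.array([0.4]), np.array([5.0]), seq1, u_c, u_r)
    assert np.array_equal(single.choices_array(), choices[0])
    assert np.array_equal(single.rewards_array(), rewards[0])


def test_mle_grid_recovers_generating_parameters(seq1):
    """Grid-search ML on a long session recovers (alpha, beta) to grid resolution."""
    long_sched = TaskSchedule(seq1.blocks * 10, "custom")  # 4,800 trials
    data = simulate_agent(AgentParams(0.5, 4.0), long_sched, np.random.default_rng(29))
    alpha_grid = np.round(np.arange(0.05, 1.01, 0.05), 2)
    beta_grid = np.round(np.arange(0.5, 10.1, 0.5), 1)
    best, _ = mle_grid(data, alpha_grid, beta_grid)
    assert abs(best.alpha - 0.5) <= 0.10
    assert abs(best.beta - 4.0) <= 1.0
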