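"""Matching-law aggregation, filtering, regression and slope comparison."""

import numpy as np
import pytest

from dynreward.matching import (
    BlockAggregate,
    MatchingFit,
    aggregate_block,
    aggregate_subject,
    compare_sensitivity,
    filter_blocks,
    fit_matching,
)
from dynreward.rl import AgentParams, TrialRecord, simulate_agent, simulate_many
from dynreward.schedule import make_schedule


def _trials(pairs, block=1):
    return [TrialRecord(block, i + 1, c, r) for i, (c, r) in enumerate(pairs)]


# ---------------------------------------------------------------------------
# aggregation and filtering
# ---------------------------------------------------------------------------

def test_window_covers_fifty_trials_of_a_seventy_trial_block():
    trials = _trials([("A", 1)] * 70)
    agg = aggregate_block(trials)
    assert agg.c_A == 50 and agg.c_B == 0 and agg.r_A == 50 and agg.r_B == 0


def test_aggregate_matches_bruteforce_tally():
    rng = np.random.default_rng(31)
    pairs = [("A" if c else "B", int(r)) for c, r in zip(rng.integers(0, 2, 90), rng.integers(0, 2, 90))]
    trials = _trials(pairs)
    agg = aggregate_block(trials)
    window = pairs[20:70]  # trials 21-70, 1-based inclusive
    assert agg.c_A == sum(1 for c, _ in window if c == "A")
    assert agg.c_B == sum(1 for c, _ in window if c == "B")
    assert agg.r_A == sum(r for c, r in window if c == "A")
    assert agg.r_B == sum(r for c, r in window if c == "B")


def test_short_block_errors_unless_truncation_allowed():
    trials = _trials([("A", 0)] * 40)
    with pytest.raises(ValueError, match="fewer than window end"):
        aggregate_block(trials)
    agg = aggregate_block(trials, allow_short=True)
    assert agg.c_A == 20  # trials 21-40


def test_filter_drops_zero_reward_blocks():
    keep = BlockAggregate("s", 1, 10, 12, 5, 7)
    drop = BlockAggregate("s", 2, 40, 10, 12, 0)
    drop2 = BlockAggregate("s", 3, 10, 40, 0, 12)
    assert filter_blocks([keep, drop, drop2]) == [keep]


def test_filter_matches_enumeration_oracle():
    rng = np.random.default_rng(5)
    aggs = []
    for i in range(100):
        c_a, c_b = rng.integers(0, 30, 2)
        aggs.append(
            BlockAggregate("s", i, int(c_a), int(c_b),
                           int(rng.integers(0, c_a + 1)), int(rng.integers(0, c_b + 1)))
        )
    kept = filter_blocks(aggs)
    assert len(kept) == sum(1 for a in aggs if a.r_A > 0 and a.r_B > 0)
    assert kept == [a for a in aggs if a.r_A > 0 and a.r_B > 0]  # order preserved


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def _agg_from_ratios(ratios):
    """Build aggregates whose count ratios follow y = 0.37 x exactly."""
    aggs = []
    for i, r_ratio in enumerate(ratios):
        r_a, r_b = 2 ** r_ratio * 8, 8
        c_ratio = 0.37 * np.log2(r_a / r_b)
        c_b = 64
        c_a = c_b * 2 ** c_ratio
        aggs.append(BlockAggregate("s", i, int(round(c_a * 100)), c_b * 100,
                                   int(round(r_a * 10)), r_b * 10))
    return aggs


def test_noiseless_regression_recovers_slope():
    aggs = _agg_from_ratios([-2, -1, 0, 1, 2])
    fit = fit_matching(aggs)
    assert fit.sensitivity == pytest.approx(0.37, abs=1e-3)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-5)


def test_strict_matching_has_unit_slope_zero_bias():
    aggs = [
        BlockAggregate("s", i, c_a, c_b, c_a // 2, c_b // 2)
        for i, (c_a, c_b) in enumerate([(40, 10), (20, 20), (10, 40), (30, 16)])
    ]
    fit = fit_matching(aggs)
    assert fit.sensitivity == pytest.approx(1.0, abs=1e-10)
    assert fit.bias == pytest.approx(0.0, abs=1e-10)


def test_ols_matches_normal_equations():
    rng = np.random.default_rng(77)
    aggs = []
    for i in range(20):
        c_a, c_b = rng.integers(5, 45, 2)
        r_a = rng.integers(1, c_a + 1)
        r_b = rng.integers(1, c_b + 1)
        aggs.append(BlockAggregate("s", i, int(c_a), int(c_b), int(r_a), int(r_b)))
    fit = fit_matching(aggs)
    x = np.log2([a.r_A / a.r_B for a in aggs])
    y = np.log2([a.c_A / a.c_B for a in aggs])
    # closed-form simple OLS
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
    se = np.sqrt((resid**2).sum() / (len(x) - 2) / sxx)
    assert fit.sensitivity == pytest.approx(slope, rel=1e-10)
    assert fit.bias == pytest.approx(intercept, rel=1e-10)
    assert fit.r_squared == pytest.approx(r2, rel=1e-10)
    assert fit.se_sensitivity == pytest.approx(se, rel=1e-10)


def test_too_few_points_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        fit_matching([BlockAggregate("s", 1, 10, 10, 5, 5)] * 2)


def test_deck_relabel_invariance():
    rng = np.random.default_rng(13)
    aggs = [
        BlockAggregate("s", i, int(c_a), int(c_b), int(rng.integers(1, c_a + 1)), int(rng.integers(1, c_b + 1)))
        for i, (c_a, c_b) in enumerate(rng.integers(5, 45, (12, 2)))
    ]
    swapped = [BlockAggregate(a.subject_id, a.block_index, a.c_B, a.c_A, a.r_B, a.r_A) for a in aggs]
    f1, f2 = fit_matching(aggs), fit_matching(swapped)
    assert f1.sensitivity == pytest.approx(f2.sensitivity, rel=1e-10)
    assert f1.bias == pytest.approx(-f2.bias, rel=1e-10)
    assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-10)


# ---------------------------------------------------------------------------
# slope comparison
# ---------------------------------------------------------------------------

def test_identical_fits_give_zero_t():
    fit = MatchingFit(0.37, 0.1, 0.02, 0.8, 100)
    t, p = compare_sensitivity(fit, fit)
    assert t == 0.0 and p == pytest.approx(0.5)


def test_slope_comparison_hand_computation():
    f1 = MatchingFit(0.37, 0.0, 0.02, 0.8, 120)
    f2 = MatchingFit(0.31, 0.0, 0.03, 0.6, 110)
    t, p = compare_sensitivity(f1, f2)
    assert t == pytest.approx(0.06 / np.sqrt(0.0013), rel=1e-10)
    assert 0.01 < p < 0.1  # boundary-significant one-tailed difference


def test_slope_comparison_antisymmetric():
    f1 = MatchingFit(0.37, 0.0, 0.02, 0.8, 120)
    f2 = MatchingFit(0.31, 0.0, 0.03, 0.6, 110)
    t12, p12 = compare_sensitivity(f1, f2)
    t21, p21 = compare_sensitivity(f2, f1)
    assert t12 == pytest.approx(-t21)
    assert p12 + p21 == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# link to the generative model
# ---------------------------------------------------------------------------

def test_sensitivity_increases_with_perseveration(seq1):
    """Fitted s rises monotonically (rank) with the generating beta."""
    betas = [0.5, 1.5, 3.0, 5.0, 8.0]
    sens = []
    for k, beta in enumerate(betas):
        rng = np.random.default_rng(200 + k)
        n = 30
        u_c, u_r = rng.random((n, 480)), rng.random((n, 480))
        choices, rewards = simulate_many(np.full(n, 0.5), np.full(n, beta), seq1, u_c, u_r)
        aggs = []
        for i in range(n):
            data = __import__("dynreward").rl.SubjectData.from_arrays(
                f"s{i}", "g", seq1, choices[i], rewards[i]
            )
            aggs.extend(aggregate_subject(data))
        sens.append(fit_matching(filter_blocks(aggs)).sensitivity)
    from scipy.stats import spearmanr

    rho, _ = spearmanr(betas, sens)
    assert rho > 0
    assert all(s < 1 for s in sens)  # undermatching throughout


def test_paper_like_cohort_undermatches(small_cohort):
    for group, subs in small_cohort.by_group().items():
        aggs = [a for s in subs for a in aggregate_subject(s)]
        fit = fit_matching(filter_blocks(aggs))
        assert 0 < fit.sensitivity < 1
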