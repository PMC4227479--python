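"""End-to-end orchestration: load, validate, summarize, analyse, report.

The full pipeline mirrors the analysis order of a DRT study: behavioural
summaries (total scores, training-session deck preference, smoothed
choice time-courses), matching-law fits with group slope comparisons,
hierarchical Bayesian parameter estimation with posterior group
comparisons and Bayes factors, parameter-symptom correlations, and the
(alpha, beta) performance grid.  Every stochastic stage derives its seed
from the run seed, and the JSON report is byte-identical across reruns
with the same inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as drt_io
from .cohort import sample_cohort, default_study_specs
from .hb import (
    HierModelSpec,
    McmcSettings,
    correlate_params,
    fit_hierarchical,
    prob_diff_positive,
    reduced_settings,
    savage_dickey_bf,
    standardized_group_diff,
)
from .matching import aggregate_subject, compare_sensitivity, filter_blocks, fit_matching
from .rl import SubjectData
from .schedule import SCHEDULE_LABELS, make_schedule
from .grid import run_grid, locate_optimum

__all__ = [
    "RunConfig",
    "BehavioralSummary",
    "load_and_validate",
    "summarize_behavior",
    "run_full_pipeline",
]

logger = logging.getLogger("dynreward")

MOVING_AVERAGE_WINDOW = 10


class DataValidationError(ValueError):
    """Malformed input data, with the offending location in the message."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    When ``trials_path`` is None a default synthetic cohort is generated
    from the run seed.  ``mcmc`` defaults to the desk-scale protocol
    (3 chains x 4,000 iterations); pass a full
    :class:`~dynreward.hb.McmcSettings` for the long protocol.
    """

    trials_path: str | None = None
    covariates_path: str | None = None
    seed: int = 0
    outdir: str | None = None
    mcmc: McmcSettings | None = None
    model: HierModelSpec = field(default_factory=HierModelSpec)
    grid_reps: int = 100
    do_matching: bool = True
    do_hierarchical: bool = True
    do_grid: bool = False
    do_correlations: bool = True


@dataclass
class BehavioralSummary:
    """Group score statistics, training preference and smoothed curves."""

    score_mean: dict[str, float]
    score_sd: dict[str, float]
    anova_f: float
    anova_p: float
    training_majority: dict[str, int]      # subjects preferring the better deck >50%
    group_size: dict[str, int]
    smoothed_curves: dict[str, np.ndarray]  # subject_id -> moving-average P(choose A)


def _validate_frame(df: pd.DataFrame, path: str) -> None:
    missing = set(drt_io.TRIALS_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[~df["reward"].isin([0, 1])]
    if len(bad):
        raise DataValidationError(f"{path}: row {bad[0] + 2}: reward must be 0 or 1")
    bad = df.index[~df["choice"].isin(["A", "B"])]
    if len(bad):
        raise DataValidationError(f"{path}: row {bad[0] + 2}: choice must be 'A' or 'B'")
    bad = df.index[~df["schedule_label"].isin(SCHEDULE_LABELS)]
    if len(bad):
        raise DataValidationError(
            f"{path}: row {bad[0] + 2}: unknown schedule label "
            f"{df.loc[bad[0], 'schedule_label']!r}"
        )


def load_and_validate(
    trials_path: str | Path,
    covariates_path: str | Path | None = None,
) -> tuple[dict[str, list[SubjectData]], list[SubjectData]]:
    """Read and validate a trials CSV (and optional covariates CSV).

    Returns ``(testing_by_group, training_sessions)``.  Hard errors (with
    file and row locations) on schema violations, out-of-range rewards,
    unknown schedule labels, or trial counts that do not match the
    declared schedule.
    """
    path = str(trials_path)
    df = pd.read_csv(trials_path)
    _validate_frame(df, path)
    subjects = drt_io.frame_to_subjects(df)
    covs = drt_io.read_covariates(covariates_path) if covariates_path else {}
    testing: dict[str, list[SubjectData]] = {}
    training: list[SubjectData] = []
    for s in subjects:
        expected = make_schedule(s.schedule_label).n_trials
        if s.n_trials != expected:
            raise DataValidationError(
                f"{path}: subject {s.subject_id}: {s.n_trials} trials for schedule "
                f"{s.schedule_label!r}, expected {expected}"
            )
        if s.subject_id in covs:
            s.covariates.update(covs[s.subject_id])
        if s.schedule_label.startswith("training"):
            training.append(s)
        else:
            testing.setdefault(s.group, []).append(s)
    return testing, training


def moving_average_choice(data: SubjectData, window: int = MOVING_AVERAGE_WINDOW) -> np.ndarray:
    """Trailing moving average of the deck-A choice indicator."""
    ind = (data.choices_array() == 0).astype(float)
    return pd.Series(ind).rolling(window, min_periods=1).mean().to_numpy()


def summarize_behavior(
    testing_by_group: Mapping[str, Sequence[SubjectData]],
    training: Sequence[SubjectData] = (),
) -> BehavioralSummary:
    """Group-level score statistics, ANOVA, and training-deck preference."""
    if not testing_by_group:
        raise ValueError("no groups to summarize")
    score_mean: dict[str, float] = {}
    score_sd: dict[str, float] = {}
    group_size: dict[str, int] = {}
    curves: dict[str, np.ndarray] = {}
    groups_scores = []
    for label, subs in testing_by_group.items():
        scores = np.array([s.total_score for s in subs], dtype=float)
        score_mean[label] = float(scores.mean())
        score_sd[label] = float(scores.std(ddof=1)) if len(scores) > 1 else 0.0
        group_size[label] = len(subs)
        groups_scores.append(scores)
        for s in subs:
            curves[s.subject_id] = moving_average_choice(s)
    if len(groups_scores) >= 2:
        f, p = stats.f_oneway(*groups_scores)
    else:
        f, p = float("nan"), float("nan")
    majority: dict[str, int] = {label: 0 for label in testing_by_group}
    for t in training:
        sched = make_schedule(t.schedule_label)
        better = sched.blocks[0].advantageous_deck
        frac = np.mean([tr.choice == better for tr in t.trials])
        if t.group in majority and frac > 0.5:
            majority[t.group] += 1
    return BehavioralSummary(
        score_mean, score_sd, float(f), float(p), majority, group_size, curves
    )


_GROUP_ORDER = ("control", "low-psychosis", "high-psychosis")


def _ordered(groups: Mapping[str, list[SubjectData]]) -> dict[str, list[SubjectData]]:
    keys = [g for g in _GROUP_ORDER if g in groups] + sorted(set(groups) - set(_GROUP_ORDER))
    return {k: groups[k] for k in keys}


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every enabled analysis stage and return the JSON-ready report."""
    report: dict = {"seed": config.seed, "stages": []}

    if config.trials_path is not None:
        logger.info("stage=load trials=%s", config.trials_path)
        testing, training = load_and_validate(config.trials_path, config.covariates_path)
    else:
        logger.info("stage=synthesize seed=%d", config.seed)
        cohort = sample_cohort(default_study_specs(), np.random.default_rng(config.seed))
        testing = cohort.by_group()
        training = cohort.training_sessions
    testing = _ordered(testing)
    report["n_subjects"] = {g: len(s) for g, s in testing.items()}

    logger.info("stage=behavior")
    behavior = summarize_behavior(testing, training)
    report["stages"].append("behavior")
    report["behavior"] = {
        "score_mean": behavior.score_mean,
        "score_sd": behavior.score_sd,
        "anova_f": behavior.anova_f,
        "anova_p": behavior.anova_p,
        "training_majority": behavior.training_majority,
        "group_size": behavior.group_size,
    }

    if config.do_matching:
        logger.info("stage=matching")
        fits = {}
        n_excluded = {}
        for label, subs in testing.items():
            aggs = [a for s in subs for a in aggregate_subject(s)]
            kept = filter_blocks(aggs)
            n_excluded[label] = len(aggs) - len(kept)
            fits[label] = fit_matching(kept)
        report["stages"].append("matching")
        report["matching"] = {
            label: {
                "sensitivity": f.sensitivity,
                "bias": f.bias,
                "se_sensitivity": f.se_sensitivity,
                "r_squared": f.r_squared,
                "n_points": f.n_points,
                "n_blocks_excluded": n_excluded[label],
            }
            for label, f in fits.items()
        }
        if "control" in fits:
            comps = {}
            for other in fits:
                if other != "control":
                    t, p = compare_sensitivity(fits["control"], fits[other])
                    comps[f"control_vs_{other}"] = {"t": t, "p_one_tailed": p}
            report["matching"]["slope_comparisons"] = comps

    posterior = None
    if config.do_hierarchical:
        logger.info("stage=hierarchical-fit")
        settings = config.mcmc or reduced_settings(config.seed)
        posterior = fit_hierarchical(testing, config.model, settings)
        report["stages"].append("hierarchical")
        hb_rep: dict = {
            "n_retained": posterior.n_retained,
            "rhat": posterior.rhat,
            "converged": posterior.converged,
            "summaries": posterior.summaries(),
        }
        labels = list(posterior.groups)
        diffs: dict = {}
        bfs: dict = {}
        for i, g1 in enumerate(labels):
            for g2 in labels[i + 1 :]:
                p1, p2 = posterior.groups[g1], posterior.groups[g2]
                diffs[f"{g1}_gt_{g2}.alpha"] = prob_diff_positive(
                    p1.group_mean_alpha, p2.group_mean_alpha
                )
                diffs[f"{g1}_gt_{g2}.beta"] = prob_diff_positive(
                    p1.group_mean_beta, p2.group_mean_beta
                )
                for param in ("alpha", "beta"):
                    delta = standardized_group_diff(p1, p2, param)
                    bfs[f"{g1}_vs_{g2}.{param}"] = savage_dickey_bf(delta)
        hb_rep["prob_diff_positive"] = diffs
        hb_rep["bayes_factors"] = bfs
        report["hierarchical"] = hb_rep

    if config.do_correlations and posterior is not None:
        patient_groups = [g for g in testing if g != "control"]
        betas, alphas, panss, dose = [], [], [], []
        for g in patient_groups:
            gp = posterior.groups[g]
            bmeans = gp.subject_beta_means()
            ameans = gp.subject_alpha_means()
            for s in testing[g]:
                cov = s.covariates
                if "panss_p1p3" in cov and "dose" in cov:
                    betas.append(bmeans[s.subject_id])
                    alphas.append(ameans[s.subject_id])
                    panss.append(cov["panss_p1p3"])
                    dose.append(cov["dose"])
        if len(betas) >= 4:
            logger.info("stage=correlations n=%d", len(betas))
            rep_b = correlate_params(betas, panss, dose)
            rep_a = correlate_params(alphas, panss, dose)
            report["stages"].append("correlations")
            report["correlations"] = {
                "beta_vs_panss": {"partial_r": rep_b.partial_r, "p": rep_b.partial_p,
                                  "pearson_r": rep_b.pearson_r, "n": rep_b.n},
                "alpha_vs_panss": {"partial_r": rep_a.partial_r, "p": rep_a.partial_p,
                                   "pearson_r": rep_a.pearson_r, "n": rep_a.n},
            }

    if config.do_grid:
        logger.info("stage=grid reps=%d", config.grid_reps)
        grid = run_grid(n_reps=config.grid_reps, seed=config.seed)
        a_opt, b_opt, score = locate_optimum(grid)
        report["stages"].append("grid")
        report["grid"] = {
            "alpha_opt": a_opt,
            "beta_opt": b_opt,
            "score_opt": score,
            "sd_min": float(grid.sd_score.min()),
            "sd_max": float(grid.sd_score.max()),
            "n_reps": grid.n_reps,
            "schedule_label": grid.schedule_label,
        }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (outdir / "summary.txt").write_text(_human_summary(report))
        logger.info("stage=report outdir=%s", outdir)
    return report


def _human_summary(report: dict) -> str:
    lines = [f"DRT pipeline report (seed {report['seed']})", ""]
    beh = report.get("behavior", {})
    for g, m in beh.get("score_mean", {}).items():
        lines.append(f"  {g}: total score {m:.1f} +/- {beh['score_sd'][g]:.1f} (n={beh['group_size'][g]})")
    if "matching" in report:
        lines.append("")
        for g, f in report["matching"].items():
            if isinstance(f, dict) and "sensitivity" in f:
                lines.append(f"  matching s[{g}] = {f['sensitivity']:.3f} (R^2 {f['r_squared']:.2f})")
    if "hierarchical" in report:
        lines.append("")
        for name, s in report["hierarchical"]["summaries"].items():
            lines.append(
                f"  {name}: {s['mean']:.3f} (95% CI {s['ci_lower']:.3f}-{s['ci_upper']:.3f})"
            )
    if "grid" in report:
        g = report["grid"]
        lines.append("")
        lines.append(
            f"  grid optimum: alpha={g['alpha_opt']:.2f} beta={g['beta_opt']:.1f} score={g['score_opt']:.1f}"
        )
    return "\n".join(lines) + "\n"
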