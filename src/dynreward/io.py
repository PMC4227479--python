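"""Delimited-text serialization of trial data and covariates.

Schemas
-------
trials CSV
    ``subject_id, group, schedule_label, block, trial, choice, reward`` —
    one row per trial, ``choice`` in {A, B}, ``reward`` in {0, 1}.  A
    subject may contribute several sessions (e.g. a 40-trial training
    session and a 480-trial testing session) distinguished by
    ``schedule_label``.
covariates CSV
    ``subject_id, panss_p1p3, dose`` — one row per patient; controls are
    simply absent.
ground-truth CSV
    ``subject_id, group, alpha, beta`` — generating parameters of a
    synthetic cohort, retained for recovery tests.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .rl import AgentParams, SubjectData

TRIALS_COLUMNS = ["subject_id", "group", "schedule_label", "block", "trial", "choice", "reward"]
COVARIATES_COLUMNS = ["subject_id", "panss_p1p3", "dose"]


def subjects_to_frame(subjects: Iterable[SubjectData]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        for t in s.trials:
            rows.append((s.subject_id, s.group, s.schedule_label, t.block_index, t.trial_index, t.choice, t.reward))
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


def write_trials(subjects: Iterable[SubjectData], path: str | Path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False)


def frame_to_subjects(df: pd.DataFrame) -> list[SubjectData]:
    """Group a trials frame into SubjectData sessions (no validation)."""
    from .rl import TrialRecord

    out: list[SubjectData] = []
    for (sid, label), g in df.groupby(["subject_id", "schedule_label"], sort=False):
        g = g.sort_values("trial")
        trials = [
            TrialRecord(int(r.block), int(r.trial), str(r.choice), int(r.reward))
            for r in g.itertuples(index=False)
        ]
        out.append(SubjectData(str(sid), str(g["group"].iloc[0]), str(label), trials))
    return out


def read_trials(path: str | Path) -> list[SubjectData]:
    return frame_to_subjects(pd.read_csv(path))


def write_covariates(covariates: Mapping[str, Mapping[str, float]], path: str | Path) -> None:
    rows = [
        (sid, cov.get("panss_p1p3"), cov.get("dose"))
        for sid, cov in covariates.items()
        if cov
    ]
    pd.DataFrame(rows, columns=COVARIATES_COLUMNS).to_csv(path, index=False)


def read_covariates(path: str | Path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path)
    out: dict[str, dict[str, float]] = {}
    for r in df.itertuples(index=False):
        out[str(r.subject_id)] = {"panss_p1p3": float(r.panss_p1p3), "dose": float(r.dose)}
    return out


def write_ground_truth(true_params: Mapping[str, AgentParams], groups: Mapping[str, str], path: str | Path) -> None:
    rows = [(sid, groups[sid], p.alpha, p.beta) for sid, p in true_params.items()]
    pd.DataFrame(rows, columns=["subject_id", "group", "alpha", "beta"]).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> dict[str, AgentParams]:
    df = pd.read_csv(path)
    return {str(r.subject_id): AgentParams(float(r.alpha), float(r.beta)) for r in df.itertuples(index=False)}
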