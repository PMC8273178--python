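"""Plain-CSV schemas and structured-text fit reports.

Real or synthetic data enter the pipeline through two tidy tables:

``timecourses.csv``
    subject, area, condition, t_s, psc, n_blocks — one row per grid time
    of one block-averaged BOLD response.

``trials.csv``
    subject, session, chroma, test_contrast, order, response — one row
    per 2AFC trial.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .hrf import BlockTimeCourse, JointHRFFit, TimeGrid

TIMECOURSE_COLUMNS = ["subject", "area", "condition", "t_s", "psc", "n_blocks"]
TRIAL_COLUMNS = ["subject", "session", "chroma", "test_contrast", "order", "response"]


def write_timecourses(df: pd.DataFrame, path) -> None:
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"timecourses table missing columns: {sorted(missing)}")
    df[TIMECOURSE_COLUMNS].to_csv(path, index=False)


def read_timecourses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def timecourses_to_blocks(df: pd.DataFrame) -> dict:
    """Group a tidy time-course table into fit-ready inputs.

    Returns {(subject, area): {condition: BlockTimeCourse}}; each group
    must supply all 13 grid times exactly once.
    """
    out = {}
    for (subject, area, condition), grp in df.groupby(
            ["subject", "area", "condition"], sort=True):
        grp = grp.sort_values("t_s")
        grid = TimeGrid(tuple(grp["t_s"].to_numpy(float)))
        tc = BlockTimeCourse(
            condition=condition,
            responses=grp["psc"].to_numpy(float),
            n_blocks_averaged=int(grp["n_blocks"].iloc[0]),
            grid=grid,
        )
        out.setdefault((subject, area), {})[condition] = tc
    return out


def write_trials(df: pd.DataFrame, path) -> None:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials table missing columns: {sorted(missing)}")
    df.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["response"] = df["response"].astype(bool)
    return df


def fit_report(subject: str, area: str, fit: JointHRFFit) -> dict:
    """JSON-serialisable report of one joint HRF fit."""
    return {
        "subject": subject,
        "area": area,
        "temporal": {
            "T1": fit.temporal.T1, "T2": fit.temporal.T2,
            "alpha1": fit.temporal.alpha1, "alpha2": fit.temporal.alpha2,
        },
        "per_condition": {
            c: {"a1": p.a1, "a2": p.a2, "b": p.b, "d": p.d}
            for c, p in fit.per_condition.items()
        },
        "ev": fit.ev,
        "peaks": fit.peaks,
        "diagnostics": fit.diagnostics,
    }


def write_fit_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))


def peaks_frame(fits: dict) -> pd.DataFrame:
    """Tidy (subject, area, condition, peak, ev) frame from joint fits.

    `fits` maps (subject, area) -> JointHRFFit.
    """
    rows = []
    for (subject, area), fit in fits.items():
        for condition, peak in fit.peaks.items():
            rows.append({"subject": subject, "area": area,
                         "condition": condition, "peak": peak, "ev": fit.ev})
    return pd.DataFrame(rows)
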