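"""CSV/JSON artifact schemas shared by the pipeline stages.

All timestamps are integer milliseconds since the Unix epoch (UTC); dates are
ISO-8601; absent values are written as empty strings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    Cohort,
    DTMT_COLUMNS,
    KEY_COLUMNS,
    MOOD_COLUMNS,
    PTMT_COLUMNS,
    ROSTER_COLUMNS,
)
from .typing_features import WINDOW_COLUMNS

SUBJECTS_CSV = "subjects.csv"
KEYPRESSES_CSV = "keypresses.csv"
DTMT_CSV = "dtmt.csv"
MOOD_CSV = "mood.csv"
PTMT_CSV = "ptmt.csv"
WINDOWS_CSV = "windows.csv"
MODEL_TABLE_CSV = "model_table.csv"


def write_cohort(cohort: Cohort, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df, cols in (
        (SUBJECTS_CSV, cohort.roster, ROSTER_COLUMNS),
        (KEYPRESSES_CSV, cohort.keypresses, KEY_COLUMNS),
        (DTMT_CSV, cohort.dtmt, DTMT_COLUMNS),
        (MOOD_CSV, cohort.mood, MOOD_COLUMNS),
        (PTMT_CSV, cohort.ptmt, PTMT_COLUMNS),
    ):
        path = outdir / name
        df.reindex(columns=cols).to_csv(path, index=False, na_rep="")
        written.append(path)
    return written


def read_subjects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})


def read_keypresses(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "timestamp_ms": np.int64})


def read_dtmt(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "timestamp_ms": np.int64})


def read_mood(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["ymrs"] = pd.array(df["ymrs"], dtype="Int64") if "ymrs" in df else pd.NA
    return df


def read_ptmt(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})


def write_windows(windows: pd.DataFrame, path: str | Path) -> None:
    windows.reindex(columns=WINDOW_COLUMNS).to_csv(path, index=False, na_rep="")


def read_windows(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})


def write_model_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, na_rep="")


def read_model_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
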