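"""Merge typing features, mood ratings and test records into the model table.

The analysis-ready table has one row per retained test administration with

* response ``log_dtmt_time`` = ln(completion seconds),
* log-transformed wrong moves and within-period practice day,
* a study-period indicator and its interaction with log practice day
  (the regression-discontinuity term for the mid-study break),
* weekly depression (HDRS-17) and median typing speed split into a
  between-subject level (subject mean centred at the grand mean of subject
  means) and a within-subject level (deviation from own mean),
* mania (YMRS) split the same way on bipolar rows only,

and every fixed term z-scored over the final table so estimates are
comparable effect sizes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AssemblyOptions
from .errors import DataValidationError
from .typing_features import _dates_ms

logger = logging.getLogger(__name__)

MODEL_TABLE_COLUMNS = [
    "subject_id",
    "dtmt_timestamp_ms",  # row identifier (not a model term)
    "log_dtmt_time",
    "age_z",
    "log_wrong_moves_z",
    "time_of_day_z",
    "practice_z",
    "period_z",
    "practice_period_z",
    "diagnosis_z",
    "hdrs_grand_z",
    "hdrs_subject_z",
    "ikd_grand_z",
    "ikd_subject_z",
    "ymrs_grand_z",
    "ymrs_subject_z",
]


def backpropagate_mood(
    moods: pd.DataFrame, dtmts: pd.DataFrame, timezone: str = "UTC"
) -> tuple[pd.DataFrame, list]:
    """Assign each test the next recorded weekly rating of its subject.

    A rating dated ``d`` covers tests dated in ``(previous rating date, d]``;
    tests after the last rating inherit the last rating and tests before the
    first rating inherit the first. Subjects with tests but no ratings are
    excluded (returned separately) with a logged warning.

    Returns (tests with ``hdrs17``/``ymrs`` columns, excluded subject ids).
    """
    out = dtmts.copy()
    test_date = pd.to_datetime(
        _dates_ms(out["timestamp_ms"].to_numpy(np.int64), timezone), unit="ms"
    ).date
    out["_date"] = test_date
    hdrs = np.full(len(out), np.nan)
    ymrs = np.full(len(out), np.nan)
    excluded: list = []
    ratings_by_subject = {sid: g.sort_values("date") for sid, g in moods.groupby("subject_id")}
    for sid, g in out.groupby("subject_id"):
        r = ratings_by_subject.get(sid)
        if r is None or len(r) == 0:
            excluded.append(sid)
            continue
        rdates = np.array([pd.Timestamp(d).to_datetime64() for d in r["date"]])
        tdates = np.array([pd.Timestamp(d).to_datetime64() for d in g["_date"]])
        idx = np.searchsorted(rdates, tdates, side="left")
        idx = np.minimum(idx, len(rdates) - 1)  # after the last rating: keep the last
        hdrs[g.index.to_numpy()] = r["hdrs17"].to_numpy()[idx]
        ymrs[g.index.to_numpy()] = r["ymrs"].to_numpy(dtype=float)[idx]
    if excluded:
        logger.warning("subjects with tests but no mood ratings excluded: %s", excluded)
    out["hdrs17"] = hdrs
    out["ymrs"] = ymrs
    out = out[~out["subject_id"].isin(excluded)].drop(columns=["_date"]).reset_index(drop=True)
    return out, excluded


def two_level_center(values: pd.DataFrame, value_col: str = "x") -> tuple[pd.Series, pd.Series]:
    """Split a covariate into between- and within-subject components.

    Level 2 (between): subject mean minus the unweighted grand mean of subject
    means, one value per subject. Level 1 (within): each observation minus its
    own subject mean; sums to zero within every subject.

    ``values`` needs columns ``subject_id`` and ``value_col``.
    """
    if len(values) == 0:
        raise DataValidationError("two_level_center: empty input")
    subj_means = values.groupby("subject_id")[value_col].mean()
    grand = subj_means.mean()
    level2 = subj_means - grand
    level1 = values[value_col] - values["subject_id"].map(subj_means)
    return level2, level1


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DataValidationError(f"cannot z-score constant column {x.name!r}")
    return (x - x.mean()) / sd


def build_model_table(
    windows: pd.DataFrame,
    dtmts: pd.DataFrame,
    moods: pd.DataFrame,
    roster: pd.DataFrame,
    options: AssemblyOptions | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Build the analysis-ready model table.

    ``windows`` must carry ``median_ikd_s`` (from the typing-feature stage,
    already filtered); ``dtmts`` the raw test records; ``moods`` weekly
    ratings; ``roster`` one row per subject with ``age`` and ``diagnosis``.

    Returns (table, drop report). Raises when a test falls outside both study
    periods or when the inputs already look z-scored (idempotence guard).
    """
    options = options or AssemblyOptions()
    for df, name in ((windows, "windows"), (dtmts, "dtmt records")):
        zcols = [c for c in df.columns if c.endswith("_z")]
        if zcols:
            raise DataValidationError(
                f"{name} already contain z-scored columns {zcols}; "
                "build_model_table must not be re-applied to its own output"
            )

    report: dict = {"windows_in": len(windows)}
    merged = windows.merge(
        dtmts,
        left_on=["subject_id", "dtmt_timestamp_ms"],
        right_on=["subject_id", "timestamp_ms"],
        how="inner",
        validate="one_to_one",
    )
    no_ikd = merged["median_ikd_s"].isna()
    report["dropped_no_median_ikd"] = int(no_ikd.sum())
    merged = merged[~no_ikd].reset_index(drop=True)

    merged, excluded = backpropagate_mood(moods, merged, options.timezone)
    report["subjects_dropped_no_mood"] = excluded

    # study day and period classification
    date_ms = _dates_ms(merged["timestamp_ms"].to_numpy(np.int64), options.timezone)
    if options.study_start is not None:
        start_ms = int(pd.Timestamp(options.study_start, tz=options.timezone).value // 1_000_000)
    else:
        start_ms = int(date_ms.min()) if len(date_ms) else 0
    study_day = (date_ms - start_ms) // 86_400_000 + 1
    p1, p2 = options.period1, options.period2
    in_p1 = (study_day >= p1.start) & (study_day <= p1.end)
    in_p2 = (study_day >= p2.start) & (study_day <= p2.end)
    bad = ~(in_p1 | in_p2)
    if bad.any():
        i = int(np.argmax(bad))
        raise DataValidationError(
            f"test of subject {merged['subject_id'].iloc[i]} on study day "
            f"{int(study_day[i])} lies outside both study periods "
            f"({p1.start}-{p1.end}, {p2.start}-{p2.end})"
        )
    period = in_p2.astype(float)
    if options.practice_unit == "calendar_day":
        day_in_period = np.where(in_p1, study_day - p1.start, study_day - p2.start) + 1
    else:
        merged["_period"] = period
        day_in_period = (
            merged.sort_values("timestamp_ms")
            .groupby(["subject_id", "_period"])
            .cumcount()
            .sort_index()
            .to_numpy()
            + 1
        )
        merged = merged.drop(columns=["_period"])

    merged["_practice"] = np.log(day_in_period.astype(float))
    merged["_period"] = period
    merged["_interaction"] = merged["_practice"] * merged["_period"]
    merged["_tod"] = (merged["slot"] == "evening").astype(float)
    merged["_log_wm"] = np.log(merged["wrong_moves"].astype(float) + 1.0)

    roster_idx = roster.set_index("subject_id")
    merged["_age"] = merged["subject_id"].map(roster_idx["age"]).astype(float)
    merged["_diag"] = (
        merged["subject_id"].map(roster_idx["diagnosis"]).eq("bipolar").astype(float)
    )

    table = pd.DataFrame(
        {
            "subject_id": merged["subject_id"],
            "dtmt_timestamp_ms": merged["dtmt_timestamp_ms"].astype(np.int64),
            "log_dtmt_time": np.log(merged["completion_time_s"].astype(float)),
        }
    )

    # two-level centred covariates, then z-scoring over the final table
    for raw, grand_col, subj_col in (
        ("hdrs17", "hdrs_grand_z", "hdrs_subject_z"),
        ("median_ikd_s", "ikd_grand_z", "ikd_subject_z"),
    ):
        lv2, lv1 = two_level_center(
            merged[["subject_id", raw]].rename(columns={raw: "x"}), "x"
        )
        table[grand_col] = _zscore(merged["subject_id"].map(lv2))
        table[subj_col] = _zscore(lv1)

    table["age_z"] = _zscore(merged["_age"])
    table["log_wrong_moves_z"] = _zscore(merged["_log_wm"])
    table["practice_z"] = _zscore(merged["_practice"])
    if options.z_score_dummies:
        table["time_of_day_z"] = _zscore(merged["_tod"])
        table["period_z"] = _zscore(merged["_period"])
        table["diagnosis_z"] = _zscore(merged["_diag"])
    else:
        table["time_of_day_z"] = merged["_tod"]
        table["period_z"] = merged["_period"]
        table["diagnosis_z"] = merged["_diag"]
    # interaction of the coded (pre-z-score) terms, itself z-scored
    table["practice_period_z"] = _zscore(merged["_interaction"])

    bip = merged["_diag"] == 1.0
    table["ymrs_grand_z"] = np.nan
    table["ymrs_subject_z"] = np.nan
    if bip.any() and merged.loc[bip, "ymrs"].notna().all():
        sub = merged.loc[bip, ["subject_id", "ymrs"]].rename(columns={"ymrs": "x"})
        lv2, lv1 = two_level_center(sub, "x")
        g = merged.loc[bip, "subject_id"].map(lv2)
        try:
            table.loc[bip, "ymrs_grand_z"] = _zscore(g)
            table.loc[bip, "ymrs_subject_z"] = _zscore(lv1)
        except DataValidationError:
            logger.warning("YMRS constant within bipolar rows; YMRS terms left absent")

    table = table[MODEL_TABLE_COLUMNS].reset_index(drop=True)
    report["rows_out"] = len(table)
    logger.info(
        "model table: %d windows in, %d rows out (%d without median IKD, %s without mood)",
        report["windows_in"],
        report["rows_out"],
        report["dropped_no_median_ikd"],
        report["subjects_dropped_no_mood"],
    )
    return table, report
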