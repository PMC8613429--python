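"""Keypress-to-test window assignment and inter-key-delay features.

Each digital trail-making administration receives a half-open time window
``[start, end)`` built from its neighbours:

* two administrations at most 24 h apart share a boundary at the midpoint of
  their timestamps;
* an administration whose neighbour on one side is missing or more than 24 h
  away is clipped to its own calendar date on that side;
* on days with both a morning and an evening test recorded, time before the
  morning test and after the evening test is excluded (the morning window
  starts at the morning test, the evening window ends at the evening test).

The midpoint rule takes precedence over date clipping; the two-test-day clip
is applied last. Keypresses at a shared boundary belong to the later window.

Typing speed per window is the median inter-key delay (IKD) over transitions
shorter than 8 s; windows with fewer than 20 such transitions carry no median.

Everything here is vectorized over subjects (keypress streams run to millions
of events for large synthetic cohorts).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataValidationError

logger = logging.getLogger(__name__)

MS_PER_DAY = 86_400_000

#: transitions at or above this many seconds separate typing sessions and are
#: excluded from the median
SESSION_CUTOFF_S = 8.0
MIN_VALID_TRANSITIONS = 20

WINDOW_COLUMNS = [
    "subject_id",
    "dtmt_timestamp_ms",
    "window_start_ms",
    "window_end_ms",
    "n_keypresses",
    "n_valid_transitions",
    "median_ikd_s",
]


def _dates_ms(timestamps_ms: np.ndarray, timezone: str = "UTC") -> np.ndarray:
    """Start-of-calendar-date (in ``timezone``) of each epoch-ms timestamp, as epoch ms."""
    ts = pd.to_datetime(np.asarray(timestamps_ms, dtype=np.int64), unit="ms", utc=True)
    local = ts.tz_convert(timezone)
    floored = local.normalize().tz_convert("UTC")
    return (floored.asi8 // 1_000_000).astype(np.int64)


def _subject_codes(values: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """(integer codes, unique subject labels) for an id column of any dtype."""
    if isinstance(values.dtype, pd.CategoricalDtype):
        return values.cat.codes.to_numpy(np.int64), np.asarray(values.cat.categories)
    codes, uniques = pd.factorize(values.to_numpy())
    return codes.astype(np.int64), np.asarray(uniques)


def build_windows_all(dtmts: pd.DataFrame, timezone: str = "UTC") -> pd.DataFrame:
    """Window of every test, all subjects at once.

    ``dtmts`` needs columns ``subject_id``, ``timestamp_ms``, ``slot``, sorted
    by (subject, timestamp) with at most one record per (subject, date, slot).
    Returns one row per test: ``subject_id, dtmt_timestamp_ms,
    window_start_ms, window_end_ms``; windows of one subject are disjoint.
    """
    if len(dtmts) == 0:
        return pd.DataFrame(columns=WINDOW_COLUMNS[:4])
    codes, _ = _subject_codes(dtmts["subject_id"])
    n_runs = 1 + int(np.sum(codes[1:] != codes[:-1])) if len(codes) > 1 else 1
    if n_runs != len(np.unique(codes)):
        raise DataValidationError("test records must be grouped by subject")
    ts = dtmts["timestamp_ms"].to_numpy(np.int64)
    same_subj_prev = np.zeros(len(ts), dtype=bool)
    same_subj_prev[1:] = codes[1:] == codes[:-1]
    if np.any(same_subj_prev[1:] & (np.diff(ts) <= 0)):
        raise DataValidationError(
            "test records must be sorted by strictly increasing timestamp within subject"
        )

    date_ms = _dates_ms(ts, timezone)

    # runs of tests sharing (subject, calendar date)
    new_day = np.ones(len(ts), dtype=bool)
    new_day[1:] = ~same_subj_prev[1:] | (date_ms[1:] != date_ms[:-1])
    day_id = np.cumsum(new_day) - 1
    per_day = np.bincount(day_id)
    slots = dtmts["slot"].to_numpy()
    dup = (~new_day) & (slots == np.roll(slots, 1))
    if np.any(per_day > 2) or dup.any():
        raise DataValidationError("duplicate (date, slot) test record")

    prev_ts = np.roll(ts, 1)
    next_ts = np.roll(ts, -1)
    same_subj_next = np.zeros(len(ts), dtype=bool)
    same_subj_next[:-1] = same_subj_prev[1:]
    gap_prev = np.where(same_subj_prev, ts - prev_ts, 2 * MS_PER_DAY)
    gap_next = np.where(same_subj_next, next_ts - ts, 2 * MS_PER_DAY)

    left = np.where(gap_prev <= MS_PER_DAY, (ts + prev_ts) // 2, date_ms)
    right = np.where(gap_next <= MS_PER_DAY, (ts + next_ts) // 2, date_ms + MS_PER_DAY)

    # two-test-day clip: no time before the first or after the second test
    two = per_day[day_id] == 2
    first_of_day = new_day
    last_of_day = np.ones(len(ts), dtype=bool)
    last_of_day[:-1] = new_day[1:]
    left = np.where(two & first_of_day, ts, left)
    right = np.where(two & last_of_day, ts, right)

    out = pd.DataFrame(
        {
            "subject_id": dtmts["subject_id"].to_numpy(),
            "dtmt_timestamp_ms": ts,
            "window_start_ms": left,
            "window_end_ms": right,
        }
    )
    if (out["window_end_ms"] <= out["window_start_ms"]).any():
        raise DataValidationError("degenerate window (end <= start); check test timestamps")
    return out


def build_windows(dtmts_for_subject: pd.DataFrame, timezone: str = "UTC") -> pd.DataFrame:
    """Windows for the test records of a single subject (see :func:`build_windows_all`)."""
    if dtmts_for_subject["subject_id"].nunique() > 1:
        raise DataValidationError("build_windows expects records of a single subject")
    return build_windows_all(dtmts_for_subject, timezone)


def _keyed(codes: np.ndarray, ts: np.ndarray, base: int, span: int) -> np.ndarray:
    """Collapse (subject code, timestamp) onto one sortable int64 axis."""
    return codes * span + (ts - base)


def assign_keypresses(
    windows: pd.DataFrame, keys: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assign each keypress to at most one window of the same subject.

    Returns the windows with an ``n_keypresses`` column and an integer array
    aligned with ``keys`` rows giving the positional index of the owning
    window (-1 for keypresses outside every window; those are dropped
    downstream). Keys must be sorted by (subject, timestamp).
    """
    windows = windows.reset_index(drop=True)
    keys = keys.reset_index(drop=True)
    if len(windows) == 0 or len(keys) == 0:
        windows = windows.copy()
        windows["n_keypresses"] = np.zeros(len(windows), dtype=np.int64)
        return windows, np.full(len(keys), -1, dtype=np.int64)

    wsubj = pd.Index(pd.unique(windows["subject_id"]))
    kcodes_raw, kuniq = _subject_codes(keys["subject_id"])
    missing = set(kuniq) - set(wsubj)
    if missing:
        raise DataValidationError(
            f"keypresses reference subjects without any window: {sorted(missing)[:5]}"
        )
    # common code space
    kcodes = wsubj.get_indexer(kuniq)[kcodes_raw]
    wcodes = wsubj.get_indexer(windows["subject_id"])

    kts = keys["timestamp_ms"].to_numpy(np.int64)
    same = np.zeros(len(kts), dtype=bool)
    same[1:] = kcodes[1:] == kcodes[:-1]
    if np.any(same[1:] & (np.diff(kts) < 0)):
        raise DataValidationError("keypresses must be sorted by timestamp within subject")
    if np.any(np.diff(kcodes) < 0):
        order = np.lexsort((kts, kcodes))
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        win, assign_sorted = assign_keypresses(windows, keys.iloc[order].reset_index(drop=True))
        return win, assign_sorted[inv]

    starts = windows["window_start_ms"].to_numpy(np.int64)
    ends = windows["window_end_ms"].to_numpy(np.int64)
    lo = int(min(kts.min(), starts.min()))
    hi = int(max(kts.max(), ends.max()))
    span = hi - lo + 2
    wkey = _keyed(wcodes, starts, lo, span)
    kkey = _keyed(kcodes, kts, lo, span)
    order_w = np.argsort(wkey, kind="stable")
    idx = np.searchsorted(wkey[order_w], kkey, side="right") - 1
    cand = order_w[np.clip(idx, 0, None)]
    ok = (
        (idx >= 0)
        & (wcodes[cand] == kcodes)
        & (kts >= starts[cand])
        & (kts < ends[cand])
    )
    assignment = np.where(ok, cand, -1).astype(np.int64)

    windows = windows.copy()
    windows["n_keypresses"] = np.bincount(
        assignment[assignment >= 0], minlength=len(windows)
    ).astype(np.int64)
    return windows, assignment


def interkey_delays(keys_in_window) -> np.ndarray:
    """Delays (seconds) between consecutive keypresses; empty for <= 1 key."""
    if isinstance(keys_in_window, pd.DataFrame):
        ts = keys_in_window["timestamp_ms"].to_numpy(np.int64)
    else:
        ts = np.asarray(keys_in_window, dtype=np.int64)
    if len(ts) <= 1:
        return np.empty(0)
    if np.any(np.diff(ts) < 0):
        raise DataValidationError("keypresses must be sorted by timestamp")
    return np.diff(ts) / 1000.0


def median_ikd(
    delays,
    cutoff_s: float = SESSION_CUTOFF_S,
    min_transitions: int = MIN_VALID_TRANSITIONS,
) -> float | None:
    """Median inter-key delay over transitions shorter than ``cutoff_s``.

    Returns ``None`` when fewer than ``min_transitions`` transitions survive
    the cutoff (such windows are omitted from the analysis). The median of an
    even count is the mean of the two middle values.
    """
    d = np.asarray(delays, dtype=float)
    valid = d[d < cutoff_s]
    if valid.size < min_transitions:
        return None
    return float(np.median(valid))


def compute_window_features(
    windows: pd.DataFrame,
    keys: pd.DataFrame,
    cutoff_s: float = SESSION_CUTOFF_S,
    min_transitions: int = MIN_VALID_TRANSITIONS,
) -> pd.DataFrame:
    """Assign keypresses and compute per-window IKD features in one pass.

    Adds ``n_keypresses``, ``n_valid_transitions`` and ``median_ikd_s`` (NaN
    when absent) to ``windows``.
    """
    windows, assignment = assign_keypresses(windows, keys)
    n_valid = np.zeros(len(windows), dtype=np.int64)
    medians = np.full(len(windows), np.nan)

    if len(keys) > 1:
        kts = keys["timestamp_ms"].to_numpy(np.int64)
        # consecutive keys of the same window, in time order
        same = assignment[1:] == assignment[:-1]
        inside = assignment[1:] >= 0
        sel = same & inside
        wid = assignment[1:][sel]
        dv = (kts[1:] - kts[:-1])[sel] / 1000.0
        keep = dv < cutoff_s
        wid, dv = wid[keep], dv[keep]
        if len(wid):
            order = np.lexsort((dv, wid))
            ws, ds = wid[order], dv[order]
            uniq, start = np.unique(ws, return_index=True)
            cnt = np.diff(np.append(start, len(ws)))
            lo = start + (cnt - 1) // 2
            hi = start + cnt // 2
            med = 0.5 * (ds[lo] + ds[hi])
            n_valid[uniq] = cnt
            ok = cnt >= min_transitions
            medians[uniq[ok]] = med[ok]
    windows["n_valid_transitions"] = n_valid
    windows["median_ikd_s"] = medians
    return windows


def apply_inclusion_filters(
    windows: pd.DataFrame,
    min_keypresses: int = 20,
    min_tests: int = 6,
) -> tuple[pd.DataFrame, list, dict]:
    """Drop sparse windows, then subjects with too few surviving tests.

    A window survives when it holds at least ``min_keypresses`` keypresses
    *and* carries a median IKD (i.e. had at least 20 sub-cutoff transitions).
    Subjects then need at least ``min_tests`` surviving tests.

    Returns (kept windows, kept subject ids, drop report).
    """
    n_in = len(windows)
    has_median = windows["median_ikd_s"].notna()
    enough_keys = windows["n_keypresses"] >= min_keypresses
    kept = windows[has_median & enough_keys]
    report = {
        "windows_in": n_in,
        "dropped_keypress_filter": int((~enough_keys).sum()),
        "dropped_transition_filter": int((enough_keys & ~has_median).sum()),
    }
    per_subject = kept.groupby("subject_id", observed=True).size()
    kept_subjects = sorted(per_subject[per_subject >= min_tests].index)
    dropped_subjects = sorted(set(windows["subject_id"].unique()) - set(kept_subjects))
    kept = kept[kept["subject_id"].isin(kept_subjects)].reset_index(drop=True)
    report.update(
        {
            "dropped_subjects": dropped_subjects,
            "windows_out": len(kept),
            "subjects_out": len(kept_subjects),
        }
    )
    logger.info(
        "inclusion filters: %d -> %d windows, %d subjects dropped",
        n_in,
        len(kept),
        len(dropped_subjects),
    )
    return kept, kept_subjects, report
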