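"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the source study's design end to end: a roster of
controls and individuals with bipolar disorder, twice-daily digital
trail-making tests in two periods separated by a four-week break (with
realistic skipping), weekly HDRS-17/YMRS ratings as trait + AR(1) series,
and continuous keypress streams organized in typing sessions whose median
inter-key delay tracks a per-subject trait times a daily multiplier.

Completion times are generated by *inverting the analysis model*: the raw
streams are pushed through the very same windowing / filtering / assembly
pipeline the analysis uses, the default fixed coefficients (the full model's
published estimates) are applied to the resulting z-scored covariates, and
per-subject random effects plus lognormal residual noise are added on the log
scale. Parameter recovery by the pipeline is therefore a true inverse test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .assemble import build_model_table
from .config import (
    KEY_CATEGORY_PROBS,
    RANDOM_TERM_COLUMNS,
    AssemblyOptions,
    GeneratorConfig,
    MoodParams,
)
from .errors import ConfigurationError
from .typing_features import (
    apply_inclusion_filters,
    build_windows_all,
    compute_window_features,
)

logger = logging.getLogger(__name__)

MS_PER_DAY = 86_400_000

ROSTER_COLUMNS = ["subject_id", "age", "diagnosis", "gender"]
KEY_COLUMNS = ["subject_id", "timestamp_ms", "category"]
DTMT_COLUMNS = ["subject_id", "timestamp_ms", "completion_time_s", "wrong_moves", "variant_id", "slot"]
MOOD_COLUMNS = ["subject_id", "date", "hdrs17", "ymrs"]
PTMT_COLUMNS = ["subject_id", "occasion", "time_s"]

_SUBSTREAMS = ("roster", "schedule", "mood", "keys", "response", "ptmt")


@dataclass
class Cohort:
    """All generated streams plus per-subject latent truth (for diagnostics)."""

    roster: pd.DataFrame
    keypresses: pd.DataFrame
    dtmt: pd.DataFrame
    mood: pd.DataFrame
    ptmt: pd.DataFrame
    truth: Optional[pd.DataFrame] = None  # per-subject random effects / latent eta


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_SUBSTREAMS, children)}


def _study_start_ms(config: GeneratorConfig) -> int:
    return int(pd.Timestamp(config.study_start, tz="UTC").value // 1_000_000)


# ---------------------------------------------------------------------------
# roster, schedule, mood


def _roster(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_control + config.n_bipolar
    ids = [f"S{i + 1:03d}" for i in range(n)]
    diagnosis = ["control"] * config.n_control + ["bipolar"] * config.n_bipolar
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 21.0, 80.0).round(1)
    gender = np.where(rng.random(n) < config.prob_male, "male", "female")
    return pd.DataFrame(
        {"subject_id": ids, "age": age, "diagnosis": diagnosis, "gender": gender}
    )


def _schedule(
    config: GeneratorConfig, roster: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Scheduled administrations minus skips; completion time filled later."""
    days = np.array(list(config.period1.days) + list(config.period2.days))
    subjects = roster["subject_id"].to_numpy()
    n_subj, n_days = len(subjects), len(days)
    if n_subj == 0 or n_days == 0:
        return pd.DataFrame(columns=DTMT_COLUMNS)
    start_ms = _study_start_ms(config)

    sub_idx = np.repeat(np.arange(n_subj), n_days * 2)
    day = np.tile(np.repeat(days, 2), n_subj)
    slot = np.tile(np.array(["morning", "evening"]), n_subj * n_days)
    slot_hour = np.where(slot == "morning", config.slot_hours[0], config.slot_hours[1])
    jitter_min = rng.uniform(-config.slot_jitter_min, config.slot_jitter_min, size=len(day))
    ts = (
        start_ms
        + (day - 1) * MS_PER_DAY
        + (slot_hour * 3_600_000).astype(np.int64)
        + (jitter_min * 60_000).astype(np.int64)
    )
    keep = rng.random(len(day)) >= config.missingness

    rate = np.exp(
        rng.normal(np.log(max(config.wrong_moves_rate, 1e-12)), config.wrong_moves_rate_log_sd, n_subj)
    )
    wrong = rng.poisson(rate[sub_idx])
    variant = rng.integers(1, 13, size=len(day))

    df = pd.DataFrame(
        {
            "subject_id": subjects[sub_idx],
            "timestamp_ms": ts.astype(np.int64),
            "completion_time_s": np.nan,
            "wrong_moves": wrong,
            "variant_id": variant,
            "slot": slot,
        }
    )[keep]
    return df.sort_values(["subject_id", "timestamp_ms"], kind="stable").reset_index(drop=True)


def _mood_series(
    params: MoodParams, n_weeks: int, rng: np.random.Generator, hi: int
) -> np.ndarray:
    trait = max(rng.normal(params.trait_mean, params.trait_sd), 0.0)
    e = np.zeros(n_weeks)
    if params.ar_sd > 0:
        stat_sd = params.ar_sd / np.sqrt(max(1.0 - params.ar_rho**2, 1e-12))
        e[0] = rng.normal(0.0, stat_sd)
        innov = rng.normal(0.0, params.ar_sd, size=n_weeks - 1)
        for w in range(1, n_weeks):
            e[w] = params.ar_rho * e[w - 1] + innov[w - 1]
    return np.clip(np.round(trait + e), 0, hi).astype(int)


def _moods(
    config: GeneratorConfig, roster: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    week_days = list(range(1, config.period2.end + 1, 7))
    rows = []
    for _, subj in roster.iterrows():
        bipolar = subj["diagnosis"] == "bipolar"
        hdrs_params = config.hdrs_bipolar if bipolar else config.hdrs_control
        hdrs = _mood_series(hdrs_params, len(week_days), rng, hi=52)
        ymrs = (
            _mood_series(config.ymrs_bipolar, len(week_days), rng, hi=60)
            if bipolar
            else [pd.NA] * len(week_days)
        )
        for i, d in enumerate(week_days):
            rows.append(
                {
                    "subject_id": subj["subject_id"],
                    "date": config.study_start + pd.Timedelta(days=d - 1),
                    "hdrs17": int(hdrs[i]),
                    "ymrs": ymrs[i],
                }
            )
    df = pd.DataFrame(rows, columns=MOOD_COLUMNS)
    if len(df):
        df["date"] = pd.to_datetime(df["date"]).dt.date
        df["ymrs"] = df["ymrs"].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# keypress streams


def _session_keypresses(
    rng: np.random.Generator,
    start_s: np.ndarray,
    n_keys: np.ndarray,
    median_s: np.ndarray,
    sigma: float,
    cutoff_s: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized event times for many sessions at once.

    Returns (event times in seconds, session index per event, session
    durations). Within-session delays are lognormal with the given median,
    clipped strictly below the cutoff.
    """
    n_keys = np.asarray(n_keys, dtype=np.int64)
    start_s = np.asarray(start_s, dtype=float)
    S = len(start_s)
    trans = np.maximum(n_keys - 1, 0)
    total_trans = int(trans.sum())
    sess_of_trans = np.repeat(np.arange(S), trans)
    mu = np.log(np.asarray(median_s, dtype=float))[sess_of_trans]
    ikds = np.exp(rng.normal(mu, sigma)) if total_trans else np.empty(0)
    ikds = np.minimum(ikds, cutoff_s - 1e-3)

    cs = np.cumsum(ikds)
    first_idx = np.concatenate([[0], np.cumsum(trans)[:-1]]).astype(np.int64)
    base = np.zeros(S)
    nz = trans > 0
    if total_trans:
        base[nz] = cs[first_idx[nz]] - ikds[first_idx[nz]]
    offsets = cs - base[sess_of_trans] if total_trans else np.empty(0)

    total_keys = int(n_keys.sum())
    sess_of_key = np.repeat(np.arange(S), n_keys)
    first_key = np.zeros(total_keys, dtype=bool)
    if total_keys:
        first_key[np.concatenate([[0], np.cumsum(n_keys)[:-1]])[n_keys > 0]] = True
    off_full = np.zeros(total_keys)
    off_full[~first_key] = offsets
    times = start_s[sess_of_key] + off_full

    durations = np.zeros(S)
    if total_trans:
        last_idx = np.cumsum(trans) - 1
        durations[nz] = cs[last_idx[nz]] - base[nz]
    return times, sess_of_key, durations


def _space_sessions(
    start_s: np.ndarray, durations: np.ndarray, day_of: np.ndarray, min_gap_s: float
) -> np.ndarray:
    """Push session starts (already sorted within day) so between-session gaps
    within a day exceed ``min_gap_s``. Durations are held fixed."""
    start = start_s.copy()
    same_day = np.zeros(len(start), dtype=bool)
    if len(start) > 1:
        same_day[1:] = day_of[1:] == day_of[:-1]
    for _ in range(64):
        prev_end = np.empty_like(start)
        prev_end[1:] = start[:-1] + durations[:-1]
        required = prev_end + min_gap_s
        viol = same_day & (start < required)
        if not viol.any():
            break
        start = np.where(viol, required, start)
    return start


@dataclass
class KeypressDayParams:
    """One subject-day of typing for :func:`simulate_keypress_stream`."""

    subject_id: str
    day_start_ms: int
    trait_median_ikd_s: float
    daily_multiplier: float = 1.0
    n_sessions: Optional[int] = None
    session_starts_s: Optional[Sequence[float]] = None  # seconds from day start
    keys_per_session: Optional[Sequence[int]] = None


def simulate_keypress_stream(
    params: KeypressDayParams, seed: int, config: GeneratorConfig | None = None
) -> pd.DataFrame:
    """Generate one subject-day keypress stream.

    Events are grouped in typing sessions: within-session delays are lognormal
    with median trait x daily multiplier (all below the 8 s session cutoff);
    consecutive sessions are separated by gaps above the cutoff.
    """
    config = config or GeneratorConfig()
    ikd = config.ikd
    if params.trait_median_ikd_s <= 0:
        raise ConfigurationError(
            f"trait_median_ikd_s must be positive, got {params.trait_median_ikd_s}"
        )
    rng = np.random.default_rng(seed)
    if params.session_starts_s is not None:
        starts = np.asarray(params.session_starts_s, dtype=float)
        n_sessions = len(starts)
    else:
        n_sessions = (
            params.n_sessions
            if params.n_sessions is not None
            else int(rng.poisson(ikd.sessions_per_day))
        )
        starts = np.sort(
            rng.uniform(ikd.day_start_hour * 3600, ikd.day_end_hour * 3600, size=n_sessions)
        )
    if n_sessions == 0:
        return pd.DataFrame(columns=KEY_COLUMNS)
    if params.keys_per_session is not None:
        n_keys = np.asarray(params.keys_per_session, dtype=np.int64)
        if len(n_keys) != n_sessions:
            raise ConfigurationError("keys_per_session length must match the session count")
    else:
        n_keys = 1 + rng.poisson(ikd.keys_per_session, size=n_sessions)

    median = params.trait_median_ikd_s * params.daily_multiplier
    # provisional durations to space the sessions, then final event times
    times, sess_of_key, durations = _session_keypresses(
        rng, starts, n_keys, np.full(n_sessions, median), ikd.session_log_sd, ikd.session_cutoff_s
    )
    spaced = _space_sessions(
        starts, durations, np.zeros(n_sessions, dtype=np.int64), ikd.session_cutoff_s + 0.1
    )
    times = times + (spaced - starts)[sess_of_key]
    cats = rng.choice(
        list(KEY_CATEGORY_PROBS), size=len(times), p=list(KEY_CATEGORY_PROBS.values())
    )
    return pd.DataFrame(
        {
            "subject_id": params.subject_id,
            "timestamp_ms": (params.day_start_ms + np.round(times * 1000)).astype(np.int64),
            "category": cats,
        }
    )


def _keypresses(
    config: GeneratorConfig, roster: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Batched keypress streams for all subjects and all study days."""
    ikd = config.ikd
    subjects = roster["subject_id"].to_numpy()
    n_subj = len(subjects)
    n_days = config.period2.end
    if n_subj == 0 or n_days == 0:
        return pd.DataFrame(columns=KEY_COLUMNS)
    start_ms = _study_start_ms(config)

    trait = np.exp(rng.normal(np.log(ikd.trait_median_s), ikd.trait_log_sd, size=n_subj))
    daily_mult = np.exp(rng.normal(0.0, ikd.daily_log_sd, size=(n_subj, n_days)))
    n_sessions = rng.poisson(ikd.sessions_per_day, size=(n_subj, n_days))

    S = int(n_sessions.sum())
    if S == 0:
        return pd.DataFrame(columns=KEY_COLUMNS)
    flat_day = n_sessions.ravel()  # sessions per (subject, day) cell
    cell_of_sess = np.repeat(np.arange(n_subj * n_days), flat_day)
    subj_of_sess = cell_of_sess // n_days
    day_of_sess = cell_of_sess % n_days

    starts = rng.uniform(ikd.day_start_hour * 3600, ikd.day_end_hour * 3600, size=S)
    # sort within each cell so sessions are in time order
    order = np.lexsort((starts, cell_of_sess))
    starts, cell_of_sess = starts[order], cell_of_sess[order]
    subj_of_sess, day_of_sess = subj_of_sess[order], day_of_sess[order]

    n_keys = 1 + rng.poisson(ikd.keys_per_session, size=S)
    medians = trait[subj_of_sess] * daily_mult[subj_of_sess, day_of_sess]
    times, sess_of_key, durations = _session_keypresses(
        rng, starts, n_keys, medians, ikd.session_log_sd, ikd.session_cutoff_s
    )
    spaced = _space_sessions(starts, durations, cell_of_sess, ikd.session_cutoff_s + 0.1)
    times = times + (spaced - starts)[sess_of_key]

    abs_ms = (
        start_ms
        + day_of_sess[sess_of_key] * MS_PER_DAY
        + np.round(times * 1000).astype(np.int64)
    )
    cat_names = list(KEY_CATEGORY_PROBS)
    cat_codes = rng.choice(len(cat_names), size=len(abs_ms), p=list(KEY_CATEGORY_PROBS.values()))
    # construction is already (subject, day, session, key) ordered, but session
    # spacing can push a session past a later one on rare dense days
    subj_keys = subj_of_sess[sess_of_key]
    if np.any((np.diff(subj_keys) == 0) & (np.diff(abs_ms) < 0)):
        order = np.lexsort((abs_ms, subj_keys))
        subj_keys, abs_ms, cat_codes = subj_keys[order], abs_ms[order], cat_codes[order]
    return pd.DataFrame(
        {
            "subject_id": pd.Categorical.from_codes(subj_keys, categories=subjects),
            "timestamp_ms": abs_ms,
            "category": pd.Categorical.from_codes(cat_codes, categories=cat_names),
        }
    )


# ---------------------------------------------------------------------------
# response model


def simulate_dtmt_time(
    row_covariates: Mapping[str, float],
    subject_random_effects: Mapping[str, float],
    config: GeneratorConfig,
    eps: float | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Completion time (seconds) for one administration.

    ``exp(eta + eps)`` with ``eta = x.beta + z.b``: fixed coefficients from
    ``config.fixed_coeffs`` applied to the (already transformed / z-scored)
    covariates, plus the subject's random intercept and slopes, plus Gaussian
    residual noise on the log scale. Natural logs throughout.
    """
    beta = config.fixed_coeffs
    eta = float(beta.get("intercept", 0.0))
    try:
        for name, value in beta.items():
            if name == "intercept":
                continue
            eta += value * float(row_covariates[name])
        for term, col in RANDOM_TERM_COLUMNS.items():
            b = float(subject_random_effects.get(term, 0.0))
            if b != 0.0:
                eta += b * (1.0 if col is None else float(row_covariates[col]))
    except KeyError as exc:
        raise ConfigurationError(f"row covariates missing field {exc.args[0]!r}") from exc
    if eps is None:
        if config.residual_variance > 0:
            if rng is None:
                raise ConfigurationError(
                    "rng is required when residual_variance > 0 and eps is not given"
                )
            eps = float(rng.normal(0.0, np.sqrt(config.residual_variance)))
        else:
            eps = 0.0
    return float(np.exp(eta + eps))


def _draw_random_effects(
    config: GeneratorConfig, subjects: Sequence[str], rng: np.random.Generator
) -> pd.DataFrame:
    sds = np.sqrt([config.random_variances[t] for t in RANDOM_TERM_COLUMNS])
    b = rng.normal(0.0, 1.0, size=(len(subjects), len(sds))) * sds
    out = pd.DataFrame(b, columns=list(RANDOM_TERM_COLUMNS))
    out.insert(0, "subject_id", list(subjects))
    return out


def _fill_completion_times(
    config: GeneratorConfig,
    roster: pd.DataFrame,
    dtmt: pd.DataFrame,
    keys: pd.DataFrame,
    mood: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate every completion time; returns (dtmt, random effects, truth table)."""
    ranef = _draw_random_effects(config, roster["subject_id"], rng)
    dtmt = dtmt.copy()
    resid_sd = float(np.sqrt(config.residual_variance))
    # fallback for administrations that the analysis pipeline will not retain
    # (no valid typing window): intercept + random intercept + noise
    b0 = dtmt["subject_id"].map(ranef.set_index("subject_id")["intercept"]).to_numpy()
    eps_all = rng.normal(0.0, resid_sd, size=len(dtmt)) if resid_sd > 0 else np.zeros(len(dtmt))
    dtmt["completion_time_s"] = np.exp(
        config.fixed_coeffs.get("intercept", 0.0) + b0 + eps_all
    )

    table = pd.DataFrame()
    if len(dtmt):
        windows = build_windows_all(dtmt)
        feats = compute_window_features(windows, keys)
        kept, _, _ = apply_inclusion_filters(feats)
        if len(kept):
            opts = AssemblyOptions(
                period1=config.period1, period2=config.period2, study_start=config.study_start
            )
            placeholder = dtmt.copy()
            placeholder["completion_time_s"] = 1.0
            table, _ = build_model_table(kept, placeholder, mood, roster, opts)

    if len(table):
        beta = config.fixed_coeffs
        eta = np.full(len(table), float(beta.get("intercept", 0.0)))
        for name, value in beta.items():
            if name != "intercept":
                eta += value * table[name].to_numpy(float)
        ridx = ranef.set_index("subject_id")
        for term, col in RANDOM_TERM_COLUMNS.items():
            b = table["subject_id"].map(ridx[term]).to_numpy(float)
            eta += b * (1.0 if col is None else table[col].to_numpy(float))
        eps = rng.normal(0.0, resid_sd, size=len(table)) if resid_sd > 0 else np.zeros(len(table))
        sim = np.exp(eta + eps)
        key = pd.MultiIndex.from_frame(table[["subject_id", "dtmt_timestamp_ms"]])
        dkey = pd.MultiIndex.from_frame(dtmt[["subject_id", "timestamp_ms"]])
        pos = dkey.get_indexer(key)
        dtmt.loc[dtmt.index[pos], "completion_time_s"] = sim
        table = table.assign(eta=eta, eps=eps)
    return dtmt, ranef, table


def _ptmt(
    config: GeneratorConfig,
    roster: pd.DataFrame,
    ranef: pd.DataFrame,
    truth_table: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pencil-and-paper test scores sharing the subjects' latent level.

    Both occasions draw around the subject-level part of the model (age,
    diagnosis, trait depression, trait typing speed, trait error propensity,
    random intercept) with extra modality noise; no practice term, matching
    the flat first-to-last profile of the paper modality.
    """
    if len(roster) == 0:
        return pd.DataFrame(columns=PTMT_COLUMNS)
    beta = config.fixed_coeffs
    eta_s = pd.Series(float(beta.get("intercept", 0.0)), index=roster["subject_id"])
    if len(truth_table):
        subj_level = truth_table.groupby("subject_id")[
            ["age_z", "diagnosis_z", "hdrs_grand_z", "ikd_grand_z", "log_wrong_moves_z"]
        ].mean()
        for col in subj_level.columns:
            contrib = beta.get(col, 0.0) * subj_level[col]
            eta_s = eta_s.add(contrib.reindex(eta_s.index).fillna(0.0))
    eta_s = eta_s.add(ranef.set_index("subject_id")["intercept"].reindex(eta_s.index).fillna(0.0))
    rows = []
    noise = rng.normal(0.0, config.ptmt_modality_sd, size=(len(eta_s), 2))
    for i, (sid, eta) in enumerate(eta_s.items()):
        for j, occ in enumerate(("first", "last")):
            rows.append(
                {"subject_id": sid, "occasion": occ, "time_s": float(np.exp(eta + noise[i, j]))}
            )
    return pd.DataFrame(rows, columns=PTMT_COLUMNS)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full cohort; identical config (incl. seed) gives identical output."""
    rngs = _rngs(config.seed)
    roster = _roster(config, rngs["roster"])
    dtmt = _schedule(config, roster, rngs["schedule"])
    mood = _moods(config, roster, rngs["mood"])
    keys = _keypresses(config, roster, rngs["keys"])
    dtmt, ranef, truth = _fill_completion_times(config, roster, dtmt, keys, mood, rngs["response"])
    ptmt = _ptmt(config, roster, ranef, truth, rngs["ptmt"])
    logger.info(
        "generated cohort: %d subjects, %d tests, %d keypresses, %d ratings",
        len(roster),
        len(dtmt),
        len(keys),
        len(mood),
    )
    return Cohort(roster=roster, keypresses=keys, dtmt=dtmt, mood=mood, ptmt=ptmt, truth=truth)
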