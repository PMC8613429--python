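"""Cross- and within-modality consistency statistics.

Intraclass correlations use the two-way mixed-effects, consistency,
single-measurement form, ICC(3,1):

    ICC = (MS_rows - MS_error) / (MS_rows + (k - 1) MS_error),   k = 2,

with mean squares from the two-way (subjects x occasions) ANOVA decomposition
and an F-based confidence interval. The consistency form is invariant to a
constant offset between the two score sets but not to rescaling one of them.
Paired t-tests compare first and last administrations within each modality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

ICC_MODEL_LABEL = "ICC(3,1) two-way mixed, consistency, single measures"


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    model_label: str = ICC_MODEL_LABEL
    warning: str | None = None


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False


def icc_consistency(pairs: pd.DataFrame, alpha: float = 0.05) -> IccResult:
    """ICC(3,1) between ``score_a`` and ``score_b`` over complete pairs.

    Requires at least 3 complete pairs. Zero between-subject variance yields
    ICC 0 with a warning rather than an error.
    """
    data = pairs[["score_a", "score_b"]].dropna().to_numpy(float)
    n = data.shape[0]
    if n < 3:
        raise InsufficientDataError(f"ICC needs at least 3 complete pairs, got {n}")
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if ms_rows == 0.0:
        logger.warning("zero between-subject variance; ICC set to 0")
        return IccResult(icc=0.0, ci_low=0.0, ci_high=0.0, n_subjects=n, warning="zero between-subject variance")
    if ms_err == 0.0:
        # perfect consistency (possibly up to a constant offset)
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0, n_subjects=n)

    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = ms_rows / ms_err
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return IccResult(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_subjects=n,
    )


def paired_t_test(pairs: pd.DataFrame) -> TTestResult:
    """Two-sided paired t-test of ``score_a`` vs ``score_b``.

    Zero-variance differences with a nonzero mean are flagged (t infinite,
    p = 0) rather than raised.
    """
    data = pairs[["score_a", "score_b"]].dropna().to_numpy(float)
    n = data.shape[0]
    if n < 2:
        raise InsufficientDataError(f"paired t-test needs at least 2 complete pairs, got {n}")
    d = data[:, 0] - data[:, 1]
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0, degenerate=True)
        logger.warning("zero variance of paired differences with nonzero mean")
        return TTestResult(
            t=float(np.sign(mean)) * np.inf, df=n - 1, p=0.0, mean_diff=mean, degenerate=True
        )
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return TTestResult(t=float(t), df=n - 1, p=p, mean_diff=mean)


def _first_last(dtmts: pd.DataFrame) -> pd.DataFrame:
    """First and last completed test time per subject (by timestamp)."""
    g = dtmts.sort_values("timestamp_ms").groupby("subject_id")["completion_time_s"]
    out = pd.DataFrame({"first": g.first(), "last": g.last(), "count": g.size()})
    return out


def reliability_report(
    dtmts: pd.DataFrame, ptmt: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross- and within-modality comparison tables.

    Four ICC rows (first/first and last/last across modalities; first vs last
    within each modality) and two paired t-tests (first vs last within each
    modality). Subjects missing either score of a comparison are dropped from
    that row only.
    """
    d = _first_last(dtmts)
    p = ptmt.pivot_table(index="subject_id", columns="occasion", values="time_s", aggfunc="first")
    for col in ("first", "last"):
        if col not in p.columns:
            p[col] = np.nan
    # within-modality rows need two distinct administrations
    d_multi = d[d["count"] >= 2]

    def pairs(a: pd.Series, b: pd.Series) -> pd.DataFrame:
        joined = pd.concat({"score_a": a, "score_b": b}, axis=1).dropna()
        return joined

    comparisons = [
        ("first pTMT-B vs first dTMT-B", pairs(p["first"], d["first"])),
        ("last pTMT-B vs last dTMT-B", pairs(p["last"], d["last"])),
        ("first vs last pTMT-B", pairs(p["first"], p["last"])),
        ("first vs last dTMT-B", pairs(d_multi["first"], d_multi["last"])),
    ]
    icc_rows = []
    for label, pr in comparisons:
        res = icc_consistency(pr, alpha=alpha)
        icc_rows.append(
            {
                "comparison": label,
                "icc": res.icc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n": res.n_subjects,
                "model": res.model_label,
            }
        )
    t_rows = []
    for label, pr in comparisons[2:]:
        res = paired_t_test(pr)
        t_rows.append(
            {
                "comparison": label,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "mean_diff": res.mean_diff,
                "n": res.df + 1,
            }
        )
    return pd.DataFrame(icc_rows), pd.DataFrame(t_rows)
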