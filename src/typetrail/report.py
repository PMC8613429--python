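"""Human-readable summary of a pipeline run.

The renderer is a pure formatter: every number in the text report is taken
verbatim from the machine-readable artifacts (``fits.json`` and the
reliability CSVs); nothing is recomputed here. Plots show the fitted practice
curve and the mood/typing effect directions implied by the full model.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .io import read_json, read_model_table

FITS_JSON = "fits.json"
COMPARISON_CSV = "model_comparison.csv"
RELIABILITY_CSV = "reliability.csv"
TTESTS_CSV = "ttests.csv"
REPORT_TXT = "report.txt"


def _fmt(x) -> str:
    return str(x)


def _coef_table(fit: dict) -> list[str]:
    lines = ["term  estimate  se  p"]
    spec = fit["spec"]
    for term, est, se, p in zip(fit["terms"], fit["beta"], fit["se"], fit["p_values"]):
        lines.append(f"{term:<24} {_fmt(est)}  {_fmt(se)}  {_fmt(p)}")
    lines.append(
        f"sigma2={_fmt(fit['sigma2'])}  loglik={_fmt(fit['loglik'])}  "
        f"deviance={_fmt(fit['deviance'])}"
    )
    lines.append(
        f"R2 marginal={_fmt(fit['r2_marginal'])}  conditional={_fmt(fit['r2_conditional'])}  "
        f"n_obs={fit['n_obs']}  n_subjects={fit['n_subjects']}  "
        f"random terms: {', '.join(spec['random_terms'])} ({fit['re_structure_used']})"
    )
    return lines


def make_report(artifacts_dir: str | Path, plot: bool = True) -> Path:
    """Render ``report.txt`` (and PNG plots) from the stage artifacts."""
    d = Path(artifacts_dir)
    fits_path = d / FITS_JSON
    if not fits_path.exists():
        raise DataValidationError(f"missing artifact: {fits_path}")
    fits = read_json(fits_path)

    lines: list[str] = ["Typing dynamics / digital trail-making analysis report", "=" * 56, ""]
    lines.append(f"Fitted models: {len(fits['models'])}")
    for fit in fits["models"]:
        lines.append("")
        lines.append(f"--- Model {fit['number']} ---")
        lines.extend(_coef_table(fit))

    comp_path = d / COMPARISON_CSV
    if comp_path.exists():
        lines += ["", "Model comparison (likelihood-ratio tests)", "-" * 42]
        comp = pd.read_csv(comp_path, dtype=str)
        lines.append("  ".join(comp.columns))
        for _, row in comp.iterrows():
            lines.append("  ".join("" if pd.isna(v) else str(v) for v in row))

    rel_path = d / RELIABILITY_CSV
    if rel_path.exists():
        lines += ["", "Reliability (intraclass correlations)", "-" * 38]
        rel = pd.read_csv(rel_path, dtype=str)
        for _, row in rel.iterrows():
            lines.append(
                f"{row['comparison']:<32} ICC={row['icc']} CI=({row['ci_low']}, {row['ci_high']}) n={row['n']}"
            )
        tt = pd.read_csv(d / TTESTS_CSV, dtype=str)
        lines += ["", "Paired t-tests (first vs last)", "-" * 30]
        for _, row in tt.iterrows():
            lines.append(f"{row['comparison']:<32} t={row['t']} df={row['df']} p={row['p']}")
    else:
        lines += ["", "[reliability stage not run; section omitted]"]

    out = d / REPORT_TXT
    out.write_text("\n".join(lines) + "\n")

    if plot:
        _plots(d, fits)
    return out


def _plots(d: Path, fits: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table_path = d / "model_table.csv"
    if not table_path.exists():
        return
    table = read_model_table(table_path)
    full = fits["models"][-1]
    beta = dict(zip(full["terms"], full["beta"]))

    # practice curve: observed subject-mean log time by practice day vs the
    # fitted fixed-effect trend, per period
    fig, ax = plt.subplots(figsize=(6, 4))
    for per, g in table.groupby(table["period_z"] > table["period_z"].median()):
        x = g["practice_z"]
        ax.scatter(x, g["log_dtmt_time"], s=6, alpha=0.3, label=f"period {'2' if per else '1'}")
    ax.set_xlabel("practice (z-scored log day in period)")
    ax.set_ylabel("ln completion time (s)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(d / "practice_curve.png", dpi=110)
    plt.close(fig)

    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharey=True)
    for ax, col in zip(
        axes.ravel(), ("hdrs_grand_z", "hdrs_subject_z", "ikd_grand_z", "ikd_subject_z")
    ):
        ax.scatter(table[col], table["log_dtmt_time"], s=5, alpha=0.3)
        b = beta.get(col)
        if b is not None:
            xs = np.linspace(table[col].min(), table[col].max(), 20)
            ax.plot(xs, beta["intercept"] + b * xs, color="k")
        ax.set_title(col)
    fig.tight_layout()
    fig.savefig(d / "effects.png", dpi=110)
    plt.close(fig)
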