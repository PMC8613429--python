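"""Gaussian linear mixed models with maximum-likelihood fitting.

The model is, per subject i,

    y_i = X_i beta + Z_i b_i + e_i,   b_i ~ N(0, G),   e_i ~ N(0, sigma^2 I),

with an unstructured (or diagonal) random-effect covariance G shared across
subjects. Fitting maximizes the *profiled* ML deviance: for each candidate
relative covariance factor Lambda (G = sigma^2 Lambda Lambda'), beta and
sigma^2 have closed forms, so the optimizer only searches the Lambda
parameters (log-Cholesky: free off-diagonals, log diagonals). Per-subject
blocks are collapsed to cross-product sufficient statistics once, after which
every deviance evaluation costs O(subjects x q^3) via the Woodbury identity

    V_i^{-1} = I - Z_i Lambda M_i^{-1} Lambda' Z_i',
    M_i = I_q + Lambda' Z_i' Z_i Lambda,   log|V_i| = log|M_i|.

Inference: Wald z tests from the fixed-effect information, likelihood-ratio
tests between nested forward-fitted models, and variance-partition
(Nakagawa-style) marginal/conditional R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .errors import DataValidationError, NumericError, SingularDesignError

logger = logging.getLogger(__name__)

DEFAULT_RANDOM_TERMS = ["intercept", "practice_z", "period_z", "practice_period_z"]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class LmmSpec:
    """Declarative model specification over model-table columns."""

    response: str
    fixed_terms: list[str]
    random_terms: list[str] = field(default_factory=lambda: list(DEFAULT_RANDOM_TERMS))
    grouping: str = "subject_id"
    re_structure: str = "unstructured"  # or "diagonal"

    def __post_init__(self) -> None:
        if not self.fixed_terms:
            raise DataValidationError("fixed_terms must be non-empty (intercept is implicit)")
        if self.re_structure not in ("unstructured", "diagonal"):
            raise DataValidationError("re_structure must be 'unstructured' or 'diagonal'")

    @property
    def terms(self) -> list[str]:
        return ["intercept"] + list(self.fixed_terms)


@dataclass
class LmmFit:
    """Fitted model: estimates, covariances, likelihood and fit indices."""

    spec: LmmSpec
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    re_cov: np.ndarray
    sigma2: float
    loglik: float
    r2_marginal: float
    r2_conditional: float
    converged: bool
    n_obs: int
    n_subjects: int
    n_params: int
    theta: np.ndarray  # relative log-Cholesky parameters at the optimum
    re_structure_used: str = "unstructured"

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"] = {
            "response": self.spec.response,
            "fixed_terms": list(self.spec.fixed_terms),
            "random_terms": list(self.spec.random_terms),
            "grouping": self.spec.grouping,
            "re_structure": self.spec.re_structure,
        }
        for k in ("beta", "se", "p_values", "theta"):
            d[k] = [float(v) for v in d[k]]
        d["re_cov"] = [[float(v) for v in row] for row in self.re_cov]
        d["deviance"] = float(self.deviance)
        return d


@dataclass
class LrtResult:
    """Likelihood-ratio comparison of two nested ML fits."""

    chi_square: float
    df_change: int
    p_value: float


# ---------------------------------------------------------------------------
# design construction and sufficient statistics


def _design(spec: LmmSpec, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    missing = [c for c in spec.fixed_terms if c not in table.columns]
    missing += [c for c in spec.random_terms if c != "intercept" and c not in table.columns]
    if missing:
        raise DataValidationError(f"model table lacks columns {missing}")
    sub = table[
        [spec.response, spec.grouping]
        + [c for c in dict.fromkeys(spec.fixed_terms) ]
        + [c for c in spec.random_terms if c != "intercept" and c not in spec.fixed_terms]
    ]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise DataValidationError(f"missing values in required columns {bad}")
    n = len(table)
    ones = np.ones(n)
    X = np.column_stack([ones] + [table[c].to_numpy(float) for c in spec.fixed_terms])
    Z = np.column_stack(
        [ones if t == "intercept" else table[t].to_numpy(float) for t in spec.random_terms]
    )
    y = table[spec.response].to_numpy(float)
    groups = table[spec.grouping].to_numpy()
    return X, Z, y, groups


def _check_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] <= 1e-10 * s[0]:
        # pivoted QR points at the dependent columns
        from scipy.linalg import qr

        r = int(np.linalg.matrix_rank(X))
        _, _, p = qr(X, pivoting=True, mode="economic")
        collinear = [terms[i] for i in sorted(p[r:])]
        raise SingularDesignError(f"fixed-effect design is rank deficient; collinear: {collinear}")


@dataclass
class _SuffStats:
    XtX: np.ndarray  # (m, p, p)
    ZtZ: np.ndarray  # (m, q, q)
    ZtX: np.ndarray  # (m, q, p)
    Xty: np.ndarray  # (m, p)
    Zty: np.ndarray  # (m, q)
    yty: np.ndarray  # (m,)
    n_i: np.ndarray  # (m,)
    subjects: list
    n: int


def _suff_stats(X: np.ndarray, Z: np.ndarray, y: np.ndarray, groups: np.ndarray) -> _SuffStats:
    order = np.argsort(groups, kind="stable")
    Xs, Zs, ys, gs = X[order], Z[order], y[order], groups[order]
    uniq, starts = np.unique(gs, return_index=True)
    bounds = np.append(starts, len(gs))
    m, p, q = len(uniq), X.shape[1], Z.shape[1]
    ss = _SuffStats(
        XtX=np.empty((m, p, p)),
        ZtZ=np.empty((m, q, q)),
        ZtX=np.empty((m, q, p)),
        Xty=np.empty((m, p)),
        Zty=np.empty((m, q)),
        yty=np.empty(m),
        n_i=np.diff(bounds),
        subjects=list(uniq),
        n=len(y),
    )
    for k in range(m):
        sl = slice(bounds[k], bounds[k + 1])
        Xi, Zi, yi = Xs[sl], Zs[sl], ys[sl]
        ss.XtX[k] = Xi.T @ Xi
        ss.ZtZ[k] = Zi.T @ Zi
        ss.ZtX[k] = Zi.T @ Xi
        ss.Xty[k] = Xi.T @ yi
        ss.Zty[k] = Zi.T @ yi
        ss.yty[k] = yi @ yi
    return ss


# ---------------------------------------------------------------------------
# covariance parameterizations


def n_theta(q: int, structure: str) -> int:
    return q if structure == "diagonal" else q * (q + 1) // 2


def theta_to_lower(theta: np.ndarray, q: int, structure: str) -> np.ndarray:
    """Lower-triangular factor L from log-Cholesky parameters.

    Diagonal entries are exp(theta) (positivity), off-diagonals (unstructured
    only) enter untransformed, filled row by row below the diagonal.
    """
    theta = np.asarray(theta, float)
    if len(theta) != n_theta(q, structure):
        raise NumericError(
            f"theta has length {len(theta)}, expected {n_theta(q, structure)} "
            f"for q={q} ({structure})"
        )
    L = np.zeros((q, q))
    if structure == "diagonal":
        np.fill_diagonal(L, np.exp(theta))
        return L
    d = np.exp(np.clip(theta[:q], -40.0, 40.0))
    np.fill_diagonal(L, d)
    idx = q
    for i in range(1, q):
        for j in range(i):
            L[i, j] = theta[idx]
            idx += 1
    return L


def cov_to_theta(G: np.ndarray, structure: str) -> np.ndarray:
    """Inverse of :func:`theta_to_lower` followed by L L' (absolute scale)."""
    G = np.asarray(G, float)
    q = G.shape[0]
    if structure == "diagonal":
        return 0.5 * np.log(np.clip(np.diag(G), 1e-300, None))
    L = np.linalg.cholesky(G)
    theta = [np.log(L[i, i]) for i in range(q)]
    for i in range(1, q):
        for j in range(i):
            theta.append(L[i, j])
    return np.array(theta)


# ---------------------------------------------------------------------------
# likelihood


def lmm_loglik_cov(
    spec: LmmSpec,
    table: pd.DataFrame,
    re_cov: np.ndarray,
    beta: np.ndarray,
    sigma2: float,
) -> float:
    """Marginal Gaussian log-likelihood ln N(y; X beta, Z G Z' + sigma^2 I).

    Computed blockwise per subject via Cholesky factorization of each
    subject's marginal covariance.
    """
    if sigma2 <= 0:
        raise NumericError(f"sigma2 must be positive, got {sigma2}")
    X, Z, y, groups = _design(spec, table)
    G = np.asarray(re_cov, float)
    beta = np.asarray(beta, float)
    r = y - X @ beta
    ll = 0.0
    for sid in pd.unique(groups):
        sel = groups == sid
        Zi, ri = Z[sel], r[sel]
        Vi = Zi @ G @ Zi.T + sigma2 * np.eye(sel.sum())
        try:
            c, low = cho_factor(Vi, lower=True)
        except np.linalg.LinAlgError as exc:
            raise NumericError(
                f"implied covariance not positive definite for subject {sid}; "
                f"G={G.tolist()}, sigma2={sigma2}"
            ) from exc
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        quad = float(ri @ cho_solve((c, low), ri))
        ll += -0.5 * (sel.sum() * LOG2PI + logdet + quad)
    return float(ll)


def lmm_loglik(
    spec: LmmSpec,
    table: pd.DataFrame,
    theta: np.ndarray,
    beta: np.ndarray,
    sigma2: float,
) -> float:
    """Log-likelihood with G parameterized by absolute log-Cholesky ``theta``."""
    q = len(spec.random_terms)
    L = theta_to_lower(theta, q, spec.re_structure)
    return lmm_loglik_cov(spec, table, L @ L.T, beta, sigma2)


def _profiled_deviance(
    theta: np.ndarray, ss: _SuffStats, q: int, p: int, structure: str
) -> tuple[float, np.ndarray, float, np.ndarray, float]:
    """Profiled ML deviance at relative factor Lambda(theta).

    Returns (deviance, beta_hat, sigma2_hat, A, logdet) where A is the
    accumulated X' V^{-1} X on the relative (sigma^2-free) scale.
    """
    Lam = theta_to_lower(theta, q, structure)
    M = np.eye(q)[None, :, :] + Lam.T @ ss.ZtZ @ Lam  # (m, q, q)
    try:
        C = np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise NumericError(f"M not PD at theta={theta.tolist()}") from exc
    logdet = 2.0 * float(np.sum(np.log(np.einsum("kii->ki", C))))
    U = Lam.T @ ss.ZtX  # (m, q, p)
    v = (ss.Zty @ Lam)  # (m, q)  == Lam.T @ Zty
    SU = np.linalg.solve(M, U)
    Sv = np.linalg.solve(M, v[:, :, None])[:, :, 0]
    A = ss.XtX.sum(axis=0) - np.einsum("kqp,kqr->pr", U, SU)
    b = ss.Xty.sum(axis=0) - np.einsum("kqp,kq->p", U, Sv)
    c = float(ss.yty.sum() - np.einsum("kq,kq->", v, Sv))
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError("X' V^{-1} X singular during profiling") from exc
    rss = max(c - float(beta @ b), 1e-300)
    sigma2 = rss / ss.n
    dev = ss.n * (LOG2PI + np.log(sigma2)) + logdet + ss.n
    return float(dev), beta, float(sigma2), A, logdet


def fit_lmm(
    spec: LmmSpec,
    table: pd.DataFrame,
    restarts: int = 5,
    tol: float = 1e-8,
    seed: int = 0,
    maxiter: int = 500,
    extra_starts: Sequence[np.ndarray] | None = None,
) -> LmmFit:
    """Maximum-likelihood fit of ``spec`` on ``table``.

    The profiled deviance is minimized over the relative log-Cholesky
    parameters with bounded quasi-Newton (L-BFGS-B) from ``restarts`` jittered
    starting points; beta and sigma^2 come in closed form at the optimum.
    Wald standard errors derive from the fixed-effect information matrix.
    Falls back to a diagonal covariance when every unstructured start fails.
    """
    X, Z, y, groups = _design(spec, table)
    _check_rank(X, spec.terms)
    if len(pd.unique(groups)) < 2:
        raise DataValidationError("at least two subjects are required")
    ss = _suff_stats(X, Z, y, groups)
    q, p = Z.shape[1], X.shape[1]

    def _optimize(structure: str) -> tuple[optimize.OptimizeResult | None, np.ndarray | None]:
        k = n_theta(q, structure)
        bounds = [(-12.0, 6.0)] * q + [(-50.0, 50.0)] * (k - q)
        rng = np.random.default_rng(seed)
        base = np.zeros(k)
        base[:q] = np.log(0.5)
        starts = [base]
        if extra_starts is not None:
            starts += [np.asarray(s, float) for s in extra_starts if len(s) == k]
        while len(starts) < restarts + (1 if extra_starts else 0):
            starts.append(base + rng.normal(0.0, 0.7, size=k))
        best = None
        for theta0 in starts:
            try:
                res = optimize.minimize(
                    lambda th: _profiled_deviance(th, ss, q, p, structure)[0],
                    theta0,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
                )
            except NumericError:
                continue
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        return best, None

    structure = spec.re_structure
    best, _ = _optimize(structure)
    if best is None and structure == "unstructured":
        logger.warning("unstructured covariance optimization failed; falling back to diagonal")
        structure = "diagonal"
        best, _ = _optimize(structure)
    if best is None:
        raise NumericError("random-effect covariance optimization failed for all restarts")

    theta = best.x
    dev, beta, sigma2, A, _ = _profiled_deviance(theta, ss, q, p, structure)
    Lam = theta_to_lower(theta, q, structure)
    re_cov = sigma2 * (Lam @ Lam.T)
    cov_beta = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    p_values = 2.0 * stats.norm.sf(np.abs(z))
    loglik = -0.5 * dev
    converged = bool(best.success)
    if not converged:
        logger.warning("LMM optimizer did not report convergence: %s", best.message)

    fit = LmmFit(
        spec=spec,
        terms=spec.terms,
        beta=beta,
        se=se,
        p_values=p_values,
        re_cov=re_cov,
        sigma2=sigma2,
        loglik=loglik,
        r2_marginal=np.nan,
        r2_conditional=np.nan,
        converged=converged,
        n_obs=ss.n,
        n_subjects=len(ss.subjects),
        n_params=p + n_theta(q, structure) + 1,
        theta=theta,
        re_structure_used=structure,
    )
    fit.r2_marginal, fit.r2_conditional = r2_nakagawa(fit, table)
    return fit


def r2_nakagawa(fit: LmmFit, table: pd.DataFrame) -> tuple[float, float]:
    """Variance-partition marginal and conditional R^2.

    marginal = var(X beta) / (var(X beta) + mean diag(Z G Z') + sigma^2);
    conditional adds the random-effect variance to the numerator. The fixed
    variance is the population variance of the fitted fixed-effect predictor.
    """
    X, Z, _, _ = _design(fit.spec, table)
    var_f = float(np.var(X @ fit.beta))
    var_re = float(np.mean(np.einsum("ij,jk,ik->i", Z, fit.re_cov, Z)))
    denom = var_f + var_re + fit.sigma2
    if denom <= 0:
        raise NumericError("zero total variance; R^2 undefined")
    return var_f / denom, (var_f + var_re) / denom


def wald_fixed_effects(fit: LmmFit) -> pd.DataFrame:
    """Table of (term, estimate, se, p) with Wald z p-values."""
    return pd.DataFrame(
        {
            "term": fit.terms,
            "estimate": fit.beta,
            "se": fit.se,
            "p": fit.p_values,
        }
    )


def _is_nested(small: LmmSpec, large: LmmSpec) -> bool:
    return (
        set(small.fixed_terms) <= set(large.fixed_terms)
        and small.response == large.response
        and small.grouping == large.grouping
        and list(small.random_terms) == list(large.random_terms)
    )


def forward_fit(
    table: pd.DataFrame,
    model_sequence: Sequence[LmmSpec],
    **fit_options,
) -> tuple[list[LmmFit], list[LrtResult]]:
    """Fit a forward-nested model sequence and LRT each consecutive pair.

    Each spec must nest the previous one (fixed terms a superset, identical
    random structure). Chi-square is the deviance drop, df the number of added
    fixed terms.
    """
    for a, b in zip(model_sequence, model_sequence[1:]):
        if not _is_nested(a, b):
            raise DataValidationError(
                f"model with terms {b.fixed_terms} does not nest {a.fixed_terms}"
            )
    fits: list[LmmFit] = []
    for spec in model_sequence:
        # warm-start from the previous (nested) fit: its optimum is feasible
        # here, which keeps the deviance sequence monotone by construction
        warm = [fits[-1].theta] if fits else None
        fits.append(fit_lmm(spec, table, extra_starts=warm, **fit_options))
    lrts = []
    for small, large in zip(fits, fits[1:]):
        chi = max(small.deviance - large.deviance, 0.0)
        df = len(large.spec.fixed_terms) - len(small.spec.fixed_terms)
        p = float(stats.chi2.sf(chi, df)) if df > 0 else 1.0
        lrts.append(LrtResult(chi_square=float(chi), df_change=df, p_value=p))
    return fits, lrts


# ---------------------------------------------------------------------------
# the standard forward-fitted model sequence

PRACTICE_TERMS = [
    "age_z",
    "log_wrong_moves_z",
    "time_of_day_z",
    "practice_z",
    "period_z",
    "practice_period_z",
]
MOOD_TERMS = ["diagnosis_z", "hdrs_grand_z", "hdrs_subject_z"]
TYPING_TERMS = ["ikd_grand_z", "ikd_subject_z"]
HDRS_TERMS_WITHIN = ["hdrs_grand_z", "hdrs_subject_z"]
YMRS_TERMS = ["ymrs_grand_z", "ymrs_subject_z"]


def model_spec(number: int, re_structure: str = "unstructured") -> LmmSpec:
    """The forward-fitted hierarchy: 1 practice, 2 +mood/diagnosis, 3 +typing.

    Models 4 and 5 are the within-bipolar sequence (HDRS then +YMRS, no
    diagnosis term); fit them on the bipolar subset of the table.
    """
    if number == 1:
        fixed = list(PRACTICE_TERMS)
    elif number == 2:
        fixed = PRACTICE_TERMS + MOOD_TERMS
    elif number == 3:
        fixed = PRACTICE_TERMS + MOOD_TERMS + TYPING_TERMS
    elif number == 4:
        fixed = PRACTICE_TERMS + HDRS_TERMS_WITHIN
    elif number == 5:
        fixed = PRACTICE_TERMS + HDRS_TERMS_WITHIN + YMRS_TERMS
    else:
        raise DataValidationError(f"unknown model number {number}")
    return LmmSpec(
        response="log_dtmt_time",
        fixed_terms=fixed,
        re_structure=re_structure,
    )
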