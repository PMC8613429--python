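"""Mixed-model machinery against dense, closed-form and external oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from typetrail.errors import DataValidationError, NumericError, SingularDesignError
from typetrail.lmm import (
    LmmSpec,
    cov_to_theta,
    fit_lmm,
    forward_fit,
    lmm_loglik,
    lmm_loglik_cov,
    model_spec,
    r2_nakagawa,
    theta_to_lower,
    wald_fixed_effects,
)

from .oracles import compound_symmetry_loglik, dense_lmm_loglik


def _random_table(
    rng: np.random.Generator,
    n_subjects: int = 5,
    rows_per_subject: int = 8,
    q: int = 4,
    G: np.ndarray | None = None,
    sigma2: float = 0.3,
    beta: np.ndarray | None = None,
) -> tuple[pd.DataFrame, LmmSpec, np.ndarray, np.ndarray]:
    """Small dataset with known covariates x1, x2 and random design (1, x1, x2, x1*x2)."""
    p_fixed = ["x1", "x2"]
    random_terms = ["intercept", "x1", "x2", "x1x2"][:q]
    if beta is None:
        beta = np.array([1.0, 0.5, -0.3])
    rows = []
    for s in range(n_subjects):
        x1 = rng.normal(0, 1, rows_per_subject)
        x2 = rng.normal(0, 1, rows_per_subject)
        rows.append(
            pd.DataFrame(
                {"subject_id": f"S{s}", "x1": x1, "x2": x2, "x1x2": x1 * x2}
            )
        )
    table = pd.concat(rows, ignore_index=True)
    X = np.column_stack([np.ones(len(table)), table["x1"], table["x2"]])
    Z = np.column_stack(
        [np.ones(len(table))]
        + [table[t].to_numpy() for t in random_terms if t != "intercept"]
    )
    groups = table["subject_id"].to_numpy()
    if G is None:
        A = rng.normal(0, 0.4, (q, q))
        G = A @ A.T + 0.05 * np.eye(q)
    y = X @ beta
    if np.any(G):
        Lg = np.linalg.cholesky(G + 1e-12 * np.eye(q))
        for s in np.unique(groups):
            sel = groups == s
            y[sel] += Z[sel] @ (Lg @ rng.normal(0, 1, q))
    y += rng.normal(0, np.sqrt(sigma2), len(y))
    table["y"] = y
    spec = LmmSpec(response="y", fixed_terms=p_fixed, random_terms=random_terms)
    return table, spec, X, Z


class TestLoglik:
    @pytest.mark.parametrize("seed", range(20))
    def test_blockwise_matches_dense_mvn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = int(rng.integers(1, 5))
        table, spec, X, Z = _random_table(rng, n_subjects=5, rows_per_subject=int(rng.integers(4, 12)), q=q)
        A = rng.normal(0, 0.5, (q, q))
        G = A @ A.T + 0.1 * np.eye(q)
        beta = rng.normal(0, 1, 3)
        sigma2 = float(rng.uniform(0.1, 1.0))
        got = lmm_loglik_cov(spec, table, G, beta, sigma2)
        expected = dense_lmm_loglik(
            X, Z, table["y"].to_numpy(), table["subject_id"].to_numpy(), G, beta, sigma2
        )
        assert got == pytest.approx(expected, abs=1e-8)

    def test_theta_parameterization_roundtrip(self):
        rng = np.random.default_rng(3)
        A = rng.normal(0, 0.5, (3, 3))
        G = A @ A.T + 0.2 * np.eye(3)
        theta = cov_to_theta(G, "unstructured")
        L = theta_to_lower(theta, 3, "unstructured")
        np.testing.assert_allclose(L @ L.T, G, atol=1e-10)
        d = np.diag([0.5, 1.5, 2.0])
        theta_d = cov_to_theta(d, "diagonal")
        Ld = theta_to_lower(theta_d, 3, "diagonal")
        np.testing.assert_allclose(Ld @ Ld.T, d, atol=1e-12)

    def test_loglik_via_theta_equals_cov_form(self):
        rng = np.random.default_rng(4)
        table, spec, _, _ = _random_table(rng, q=2)
        G = np.array([[0.3, 0.05], [0.05, 0.2]])
        theta = cov_to_theta(G, "unstructured")
        beta = np.array([1.0, 0.5, -0.3])
        assert lmm_loglik(spec, table, theta, beta, 0.4) == pytest.approx(
            lmm_loglik_cov(spec, table, G, beta, 0.4), abs=1e-10
        )

    def test_zero_variance_reduces_to_iid_normal(self):
        rng = np.random.default_rng(5)
        table, spec, X, _ = _random_table(rng, q=4)
        beta = np.array([0.8, 0.2, 0.1])
        sigma2 = 0.5
        r = table["y"].to_numpy() - X @ beta
        iid = float(np.sum(-0.5 * (np.log(2 * np.pi * sigma2) + r**2 / sigma2)))
        got = lmm_loglik_cov(spec, table, np.zeros((4, 4)), beta, sigma2)
        assert got == pytest.approx(iid, abs=1e-9)

    def test_balanced_random_intercept_matches_compound_symmetry(self):
        rng = np.random.default_rng(6)
        groups = np.repeat([f"S{i}" for i in range(6)], 5)
        y = rng.normal(2.0, 1.0, 30)
        table = pd.DataFrame({"subject_id": groups, "y": y, "one": 1.0})
        spec = LmmSpec(response="y", fixed_terms=["one"], random_terms=["intercept"])
        # fixed_terms carries a constant column; drop implicit-intercept duplicate
        spec = LmmSpec(response="y", fixed_terms=["x0"], random_terms=["intercept"])
        table["x0"] = rng.normal(0, 1, 30)
        mu, b1, tau2, sigma2 = 1.9, 0.0, 0.4, 0.8
        beta = np.array([mu, b1])
        got = lmm_loglik_cov(spec, table, np.array([[tau2]]), beta, sigma2)
        expected = compound_symmetry_loglik(
            y - b1 * table["x0"].to_numpy(), groups, mu, tau2, sigma2
        )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_invalid_sigma2_rejected(self):
        rng = np.random.default_rng(7)
        table, spec, _, _ = _random_table(rng, q=1)
        with pytest.raises(NumericError, match="sigma2"):
            lmm_loglik_cov(spec, table, np.eye(1), np.zeros(3), 0.0)


class TestFit:
    def test_ols_limit_with_zero_random_variance(self):
        rng = np.random.default_rng(11)
        n = 200
        table = pd.DataFrame(
            {
                "subject_id": np.repeat([f"S{i}" for i in range(10)], n // 10),
                "x1": rng.normal(0, 1, n),
                "x2": rng.normal(0, 1, n),
            }
        )
        X = np.column_stack([np.ones(n), table["x1"], table["x2"]])
        beta_true = np.array([2.0, -0.5, 0.3])
        table["y"] = X @ beta_true + rng.normal(0, 0.4, n)  # no random effects
        spec = LmmSpec(response="y", fixed_terms=["x1", "x2"], random_terms=["intercept"])
        fit = fit_lmm(spec, table, restarts=3, seed=0)
        beta_ols = np.linalg.lstsq(X, table["y"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)

    def test_loglik_self_consistency(self):
        rng = np.random.default_rng(12)
        table, spec, _, _ = _random_table(rng, n_subjects=8, rows_per_subject=10, q=2)
        fit = fit_lmm(spec, table, restarts=2, seed=1)
        recomputed = lmm_loglik_cov(spec, table, fit.re_cov, fit.beta, fit.sigma2)
        assert recomputed == pytest.approx(fit.loglik, abs=1e-8)
        assert fit.deviance == -2.0 * fit.loglik

    def test_wald_se_matches_dense_information_oracle(self):
        rng = np.random.default_rng(13)
        table, spec, X, Z = _random_table(rng, n_subjects=8, rows_per_subject=10, q=2)
        fit = fit_lmm(spec, table, restarts=2, seed=1)
        groups = table["subject_id"].to_numpy()
        info = np.zeros((X.shape[1], X.shape[1]))
        for s in np.unique(groups):
            sel = groups == s
            V = Z[sel] @ fit.re_cov @ Z[sel].T + fit.sigma2 * np.eye(int(sel.sum()))
            info += X[sel].T @ np.linalg.solve(V, X[sel])
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        np.testing.assert_allclose(fit.se, se, rtol=1e-6)
        tab = wald_fixed_effects(fit)
        assert list(tab["term"]) == ["intercept", "x1", "x2"]
        from scipy import stats

        np.testing.assert_allclose(
            tab["p"], 2 * stats.norm.sf(np.abs(tab["estimate"] / tab["se"])), atol=1e-12
        )

    def test_estimate_zero_gives_p_one_and_196_se_gives_p05(self):
        from scipy import stats

        assert 2 * stats.norm.sf(0.0) == pytest.approx(1.0)
        assert 2 * stats.norm.sf(1.96) == pytest.approx(0.05, abs=5e-4)

    def test_singular_design_lists_collinear_columns(self):
        rng = np.random.default_rng(14)
        table, _, _, _ = _random_table(rng, q=1)
        table["x3"] = 2.0 * table["x1"]
        spec = LmmSpec(response="y", fixed_terms=["x1", "x2", "x3"], random_terms=["intercept"])
        with pytest.raises(SingularDesignError, match="x3|x1"):
            fit_lmm(spec, table, restarts=1, seed=0)

    def test_single_subject_rejected(self):
        rng = np.random.default_rng(15)
        table, spec, _, _ = _random_table(rng, n_subjects=1, q=1)
        with pytest.raises(DataValidationError, match="two subjects"):
            fit_lmm(spec, table, restarts=1, seed=0)

    def test_statsmodels_crosscheck_random_intercept_and_slope(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(16)
        table, spec, _, _ = _random_table(
            rng,
            n_subjects=12,
            rows_per_subject=12,
            q=2,
            G=np.array([[0.4, 0.1], [0.1, 0.25]]),
            sigma2=0.4,
        )
        fit = fit_lmm(spec, table, restarts=3, seed=2)
        X = np.column_stack([np.ones(len(table)), table["x1"], table["x2"]])
        Zre = np.column_stack([np.ones(len(table)), table["x1"]])
        md = sm.MixedLM(table["y"].to_numpy(), X, groups=table["subject_id"].to_numpy(), exog_re=Zre)
        smfit = md.fit(reml=False, method="lbfgs", maxiter=500)
        assert fit.loglik == pytest.approx(float(smfit.llf), abs=1e-3)


class TestR2:
    def test_zero_random_variance_marginal_equals_conditional(self):
        rng = np.random.default_rng(21)
        table, spec, _, _ = _random_table(rng, q=1, G=np.zeros((1, 1)), sigma2=0.3)
        fit = fit_lmm(spec, table, restarts=2, seed=0)
        # fitted random variance collapses to ~0; the two R2 values coincide
        assert fit.r2_marginal == pytest.approx(fit.r2_conditional, abs=1e-4)

    def test_zero_slopes_give_zero_marginal(self):
        rng = np.random.default_rng(22)
        table, spec, _, _ = _random_table(
            rng, q=1, G=np.array([[0.5]]), sigma2=0.4, beta=np.array([1.0, 0.0, 0.0])
        )
        fit = fit_lmm(spec, table, restarts=2, seed=0)
        assert fit.r2_marginal == pytest.approx(0.0, abs=0.02)

    def test_matches_literal_variance_partition_formula(self):
        rng = np.random.default_rng(23)
        table, spec, X, Z = _random_table(rng, n_subjects=8, rows_per_subject=10, q=2)
        fit = fit_lmm(spec, table, restarts=2, seed=3)
        var_f = np.var(X @ fit.beta)
        var_re = np.mean([z @ fit.re_cov @ z for z in Z])
        denom = var_f + var_re + fit.sigma2
        marginal, conditional = r2_nakagawa(fit, table)
        assert marginal == pytest.approx(var_f / denom, abs=1e-10)
        assert conditional == pytest.approx((var_f + var_re) / denom, abs=1e-10)
        assert 0.0 <= marginal <= conditional <= 1.0


class TestForwardFit:
    def test_identical_specs_give_zero_chi_square(self):
        rng = np.random.default_rng(31)
        table, spec, _, _ = _random_table(rng, n_subjects=6, rows_per_subject=8, q=1)
        fits, lrts = forward_fit(table, [spec, spec], restarts=2, seed=0)
        assert lrts[0].chi_square == pytest.approx(0.0, abs=1e-6)
        assert lrts[0].df_change == 0
        assert lrts[0].p_value == 1.0

    def test_non_nested_sequence_rejected(self):
        a = LmmSpec(response="y", fixed_terms=["x1"], random_terms=["intercept"])
        b = LmmSpec(response="y", fixed_terms=["x2"], random_terms=["intercept"])
        with pytest.raises(DataValidationError, match="nest"):
            forward_fit(pd.DataFrame({"subject_id": [], "y": [], "x1": [], "x2": []}), [a, b])

    @pytest.mark.parametrize("seed", range(5))
    def test_deviance_monotone_when_adding_fixed_terms(self, seed):
        rng = np.random.default_rng(40 + seed)
        table, _, _, _ = _random_table(rng, n_subjects=6, rows_per_subject=10, q=2)
        seq = [
            LmmSpec(response="y", fixed_terms=["x1"], random_terms=["intercept", "x1"]),
            LmmSpec(response="y", fixed_terms=["x1", "x2"], random_terms=["intercept", "x1"]),
            LmmSpec(
                response="y", fixed_terms=["x1", "x2", "x1x2"], random_terms=["intercept", "x1"]
            ),
        ]
        fits, lrts = forward_fit(table, seq, restarts=2, seed=0)
        devs = [f.deviance for f in fits]
        assert devs[0] >= devs[1] - 1e-8
        assert devs[1] >= devs[2] - 1e-8
        for lrt in lrts:
            assert lrt.chi_square >= 0.0
            assert 0.0 <= lrt.p_value <= 1.0

    def test_standard_model_sequence_structure(self):
        m1, m2, m3 = model_spec(1), model_spec(2), model_spec(3)
        assert len(m2.fixed_terms) - len(m1.fixed_terms) == 3
        assert len(m3.fixed_terms) - len(m2.fixed_terms) == 2
        assert set(m1.fixed_terms) < set(m2.fixed_terms) < set(m3.fixed_terms)
        m4, m5 = model_spec(4), model_spec(5)
        assert "diagnosis_z" not in m4.fixed_terms
        assert len(m5.fixed_terms) - len(m4.fixed_terms) == 2
        for m in (m1, m2, m3, m4, m5):
            assert m.random_terms == ["intercept", "practice_z", "period_z", "practice_period_z"]
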