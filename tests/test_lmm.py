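"""REML mixed models with ante-dependence covariance: oracles & selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import block_diag

from cprkit.lmm import (
    ConvergenceError,
    build_covariance,
    fit_lmm,
    gls_beta,
    n_cov_params,
    reml_loglik,
    select_covariance,
    simulate_longitudinal,
)
from cprkit.lmm import _prepare  # brute-force oracle needs the same layout


def dense_reml_loglik(data, kind, theta):
    """Independent dense-matrix evaluation of the restricted likelihood."""
    prob = _prepare(data, None)
    T = len(prob.times)
    S = build_covariance(kind, np.asarray(theta, float), T)
    Xs, ys, blocks = [], [], []
    for pat in prob.patterns:
        for s in range(pat["Y"].shape[1]):
            Xs.append(pat["X"])
            ys.append(pat["Y"][:, s])
            blocks.append(S[np.ix_(pat["obs"], pat["obs"])])
    V = block_diag(*blocks)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    Vi = np.linalg.inv(V)
    W = X.T @ Vi @ X
    beta = np.linalg.solve(W, X.T @ Vi @ y)
    r = y - X @ beta
    n, p = len(y), X.shape[1]
    return -0.5 * ((n - p) * np.log(2 * np.pi) + np.linalg.slogdet(V)[1]
                   + np.linalg.slogdet(W)[1] + r @ Vi @ r)


def ante1_theta(sig, rho):
    return np.concatenate([np.log(sig), np.arctanh(rho)])


class TestCovarianceStructures:
    def test_ante1_matches_product_formula(self):
        sig = np.array([1.0, 1.2, 1.5, 1.3])
        rho = np.array([0.6, -0.4, 0.3])
        S = build_covariance("ante1", ante1_theta(sig, rho), 4)
        for t in range(4):
            for s in range(4):
                lo, hi = min(t, s), max(t, s)
                expect = sig[t] * sig[s] * np.prod(rho[lo:hi])
                assert S[t, s] == pytest.approx(expect, rel=1e-12)

    @given(st.integers(2, 8), st.integers(0, 10_000))
    def test_structures_positive_definite(self, T, seed):
        rng = np.random.default_rng(seed)
        for kind in ("ante1", "cs", "ar1", "diag"):
            theta = rng.normal(0, 1.0, n_cov_params(kind, T))
            S = build_covariance(kind, theta, T)
            assert np.all(np.linalg.eigvalsh(S) > 0), kind
            np.testing.assert_allclose(S, S.T)


class TestFitting:
    def test_noiseless_data_recovers_cell_means(self):
        gm = np.array([[10, 11, 12, 13], [9, 9, 9, 9]], float)
        rows = []
        for g, lab in enumerate(["CCC", "30:2"]):
            for s in range(3):
                for t in range(4):
                    rows.append({"subject": f"{lab}{s}", "group": lab,
                                 "time": t + 1, "value": gm[g, t]})
        fit = fit_lmm(pd.DataFrame(rows), structure="diag")
        cm = fit.cell_means.pivot(index="group", columns="time", values="estimate")
        np.testing.assert_allclose(cm.loc["CCC"], gm[0], atol=1e-8)
        np.testing.assert_allclose(cm.loc["30:2"], gm[1], atol=1e-8)

    def test_ante1_with_zero_rho_equals_ols(self):
        rng = np.random.default_rng(4)
        T = 5
        S = build_covariance("ante1", ante1_theta(np.ones(T), np.zeros(T - 1)), T)
        data = simulate_longitudinal(4, T, np.zeros((2, T)), S, rng)
        theta0 = ante1_theta(np.ones(T), np.zeros(T - 1))
        beta = gls_beta(data, None, "ante1", theta0)
        prob = _prepare(data, None)
        X = np.vstack([pat["X"] for pat in prob.patterns
                       for _ in range(pat["Y"].shape[1])])
        y = np.concatenate([pat["Y"][:, s] for pat in prob.patterns
                            for s in range(pat["Y"].shape[1])])
        bols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta, bols, atol=1e-10)

    def test_restricted_loglik_matches_dense_oracle(self):
        """4 subjects x 3 times: fitted REML value equals an independent
        brute-force dense evaluation to 1e-8."""
        rng = np.random.default_rng(7)
        T = 3
        S = build_covariance(
            "ante1", ante1_theta(np.array([1.0, 1.4, 1.2]), np.array([0.5, 0.3])), T
        )
        data = simulate_longitudinal(2, T, np.array([[1, 2, 3], [0, 0, 0]], float),
                                     S, rng)
        fit = fit_lmm(data, structure="ante1")
        oracle = dense_reml_loglik(data, "ante1", fit.theta)
        assert fit.loglik == pytest.approx(oracle, abs=1e-8)
        # and at an arbitrary non-optimal point too
        theta_arb = ante1_theta(np.array([0.8, 1.0, 1.5]), np.array([0.2, -0.4]))
        assert reml_loglik(data, None, "ante1", theta_arb) == pytest.approx(
            dense_reml_loglik(data, "ante1", theta_arb), abs=1e-8
        )

    def test_missing_cells_handled_by_likelihood(self):
        rng = np.random.default_rng(11)
        T = 4
        S = build_covariance("ar1", np.array([0.0, np.arctanh(0.5)]), T)
        data = simulate_longitudinal(5, T, np.zeros((2, T)), S, rng)
        data = data.drop(index=[2, 9, 17]).reset_index(drop=True)
        fit = fit_lmm(data, structure="ante1")
        assert fit.n_obs == 2 * 5 * T - 3
        assert np.isfinite(fit.loglik)

    def test_duplicate_observation_rejected(self):
        df = pd.DataFrame({
            "subject": ["a", "a", "b", "b", "c", "c", "d", "d"],
            "group": ["CCC"] * 4 + ["30:2"] * 4,
            "time": [1, 1, 1, 2, 1, 2, 1, 2],
            "value": np.arange(8.0),
        })
        with pytest.raises(ValueError):
            fit_lmm(df, structure="diag")

    def test_determinism(self):
        rng = np.random.default_rng(21)
        T = 4
        S = build_covariance("cs", np.array([0.2, 0.5]), T)
        data = simulate_longitudinal(6, T, np.ones((2, T)), S, rng)
        f1 = fit_lmm(data, structure="ante1")
        f2 = fit_lmm(data, structure="ante1")
        np.testing.assert_array_equal(f1.theta, f2.theta)
        np.testing.assert_array_equal(f1.beta, f2.beta)
        assert f1.aic == f2.aic

    def test_aic_convention(self):
        rng = np.random.default_rng(31)
        T = 3
        S = np.eye(T)
        data = simulate_longitudinal(4, T, np.zeros((2, T)), S, rng)
        fit = fit_lmm(data, structure="ar1")
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 2)
        fit2 = fit_lmm(data, structure="ante1")
        assert fit2.aic == pytest.approx(-2 * fit2.loglik + 2 * (2 * T - 1))


class TestSelection:
    def test_single_candidate_trivially_ranked(self):
        rng = np.random.default_rng(41)
        data = simulate_longitudinal(4, 3, np.zeros((2, 3)), np.eye(3), rng)
        ranked = select_covariance(data, candidates=["cs"])
        assert list(ranked["structure"]) == ["cs"]

    def test_ante_dependent_data_prefers_ante1(self):
        """Heterogeneous sigmas with decaying adjacent correlations: AD(1)
        should reach minimal AIC in at least 80% of 50 replicates."""
        T = 5
        sig = np.array([1.0, 1.6, 2.4, 2.0, 1.2])
        rho = np.array([0.8, 0.65, 0.5, 0.35])
        S = build_covariance("ante1", ante1_theta(sig, rho), T)
        gm = np.zeros((2, T))
        wins = 0
        for r in range(50):
            data = simulate_longitudinal(8, T, gm, S, np.random.default_rng(5000 + r))
            ranked = select_covariance(data, df_method="residual")
            wins += ranked.iloc[0]["structure"] == "ante1"
        assert wins >= 40

    def test_iid_data_keeps_diag_competitive(self):
        T = 4
        S = np.eye(T)
        hits = 0
        n_rep = 20
        for r in range(n_rep):
            data = simulate_longitudinal(8, T, np.zeros((2, T)), S,
                                         np.random.default_rng(6000 + r))
            ranked = select_covariance(data, df_method="residual")
            best = ranked["aic"].min()
            diag_aic = ranked.set_index("structure").loc["diag", "aic"]
            hits += diag_aic <= best + 2.0
        assert hits >= n_rep // 2

    def test_nesting_sanity_bound(self):
        """On independence-generated data, ANTE1's AIC exceeds DIAG's minus
        twice the extra parameter count, on average."""
        T = 4
        extra = n_cov_params("ante1", T) - n_cov_params("diag", T)
        diffs = []
        for r in range(10):
            data = simulate_longitudinal(6, T, np.zeros((2, T)), np.eye(T),
                                         np.random.default_rng(7000 + r))
            fa = fit_lmm(data, structure="ante1", df_method="residual")
            fd = fit_lmm(data, structure="diag", df_method="residual")
            diffs.append(fa.aic - (fd.aic - 2 * extra))
        assert np.mean(diffs) >= 0
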