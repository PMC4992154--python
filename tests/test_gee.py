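"""GEE estimation against closed forms and established-implementation oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from islex.gee import (
    cloglog,
    cloglog_inverse,
    fit_gee,
    fit_mse,
    predict_probability,
    qicu,
)
from islex.preprocess import FINAL_MODEL_SPEC, DesignMatrix, ModelSpec, build_design
from islex.simulate import SimulationParams, simulate_dataset

from conftest import singleton_design

CLOGLOG_FAMILY = sm.families.Binomial(link=sm.families.links.CLogLog())


class TestLink:
    def test_closed_forms(self):
        assert cloglog(0.0) == pytest.approx(1 - np.exp(-1), abs=1e-12)
        assert cloglog(np.log(np.log(2))) == pytest.approx(0.5, abs=1e-12)

    @given(st.floats(-20, 3))
    def test_inverse_identity(self, eta):
        assert cloglog_inverse(cloglog(eta)) == pytest.approx(eta, abs=1e-9)

    def test_inverse_domain_errors(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                cloglog_inverse(bad)

    def test_stable_at_extremes(self):
        assert cloglog(-700) == 0.0 or cloglog(-700) > 0  # no underflow crash
        assert 0 < cloglog(-30) < 1e-12
        assert cloglog(30) <= 1.0


class TestFitGEE:
    def test_intercept_only_closed_form(self, paper_like_ds):
        """β₀ = ln(−ln(1−ȳ)) for intercept-only fits (independence weighting).

        With an exchangeable working correlation and unequal cluster sizes the
        estimating equations weight clusters unequally, so the closed form is
        exact under α = 0 or equal cluster sizes.
        """
        dm = build_design(paper_like_ds, ModelSpec(()))
        fit = fit_gee(dm, fix_alpha=0.0)
        ybar = dm.y.mean()
        assert fit.params["intercept"] == pytest.approx(
            np.log(-np.log(1 - ybar)), abs=1e-8
        )
        # equal cluster sizes: closed form holds for the full GEE
        n = 400
        rng = np.random.default_rng(1)
        y = (rng.random(n) < 0.25).astype(int)
        dm_eq = DesignMatrix(
            y=y,
            X=pd.DataFrame({"intercept": np.ones(n)}),
            cluster_index=np.repeat(np.arange(n // 4), 4),
            term_map={"intercept": "intercept"},
            spec=ModelSpec(()),
        )
        fit_eq = fit_gee(dm_eq)
        assert fit_eq.params["intercept"] == pytest.approx(
            np.log(-np.log(1 - y.mean())), abs=1e-8
        )

    def test_singleton_clusters_match_glm_oracle(self):
        dm = singleton_design(n=400, seed=0)
        fit = fit_gee(dm, fix_phi=1.0)
        gee = sm.GEE(
            dm.y,
            dm.X.to_numpy(),
            groups=np.arange(dm.n_obs),
            family=CLOGLOG_FAMILY,
            cov_struct=sm.cov_struct.Independence(),
        ).fit(scale=1.0)
        np.testing.assert_allclose(fit.params.to_numpy(), np.asarray(gee.params), atol=1e-6)
        np.testing.assert_allclose(
            fit.robust_se().to_numpy(), np.asarray(gee.bse), atol=1e-6
        )
        glm = sm.GLM(dm.y, dm.X.to_numpy(), family=CLOGLOG_FAMILY).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), np.asarray(glm.params), atol=1e-6)
        np.testing.assert_allclose(fit.naive_se().to_numpy(), np.asarray(glm.bse), atol=1e-6)

    def test_alpha_zero_matches_glm_on_clustered_data(self, paper_like_design):
        fit = fit_gee(paper_like_design, fix_alpha=0.0, fix_phi=1.0)
        glm = sm.GLM(
            paper_like_design.y, paper_like_design.X.to_numpy(), family=CLOGLOG_FAMILY
        ).fit(tol=1e-12)
        np.testing.assert_allclose(
            fit.params.to_numpy(), np.asarray(glm.params), atol=1e-6
        )

    def test_full_gee_matches_statsmodels_exchangeable(self, paper_like_design):
        """Independent implementation check: coefficients, α and robust SEs."""
        fit = fit_gee(paper_like_design)
        md = sm.GEE(
            paper_like_design.y,
            paper_like_design.X.to_numpy(),
            groups=paper_like_design.cluster_index,
            family=CLOGLOG_FAMILY,
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        res = md.fit(maxiter=200)
        np.testing.assert_allclose(fit.params.to_numpy(), np.asarray(res.params), atol=1e-8)
        assert fit.alpha == pytest.approx(float(md.cov_struct.dep_params), abs=1e-6)
        np.testing.assert_allclose(
            fit.robust_se().to_numpy(), np.asarray(res.bse), rtol=1e-8
        )

    def test_score_residual_vanishes_at_convergence(self, paper_like_fit):
        assert paper_like_fit.converged
        assert paper_like_fit.score_norm < 1e-6

    def test_closed_form_inverse_matches_dense(self, paper_like_fit, paper_like_design):
        """Exchangeable rank-1 inverse equals dense per-cluster inversion."""
        from islex.gee import _cluster_layout, _dmu_deta

        dm, fit = paper_like_design, paper_like_fit
        X = dm.X.to_numpy(float)
        beta = fit.params.to_numpy()
        eta = X @ beta
        mu = np.clip(cloglog(eta), 1e-12, 1 - 1e-12)
        g = _dmu_deta(eta)
        v = mu * (1 - mu)
        starts, sizes, _ = _cluster_layout(dm.cluster_index)
        B_dense = np.zeros((X.shape[1], X.shape[1]))
        for s, n_i in zip(starts, sizes):
            sl = slice(s, s + n_i)
            R = (1 - fit.alpha) * np.eye(n_i) + fit.alpha * np.ones((n_i, n_i))
            A = np.diag(np.sqrt(v[sl]))
            V = fit.phi * A @ R @ A
            D = g[sl, None] * X[sl]
            B_dense += D.T @ np.linalg.solve(V, D)
        np.testing.assert_allclose(
            np.linalg.inv(fit.naive_cov.to_numpy()), B_dense, rtol=1e-10, atol=1e-8
        )

    def test_robust_cov_symmetric_psd(self, paper_like_fit):
        S = paper_like_fit.robust_cov.to_numpy()
        assert np.max(np.abs(S - S.T)) < 1e-12
        assert np.min(np.linalg.eigvalsh(S)) > -1e-12

    def test_rank_deficiency_names_column(self, paper_like_design):
        X = paper_like_design.X.copy()
        X["rats_copy"] = X["rats"]
        dm = dataclasses.replace(paper_like_design, X=X)
        with pytest.raises(np.linalg.LinAlgError, match="rats"):
            fit_gee(dm)

    def test_parameter_recovery_strong_rat_effect(self):
        """True rat coefficient +2 recovered within 3 robust SEs at n≈20k."""
        from islex.simulate import fixture_params, make_fixture

        ds = make_fixture("strong_rat_effect")
        dm = build_design(ds, FINAL_MODEL_SPEC)
        fit = fit_gee(dm, warn=False)
        se = fit.robust_se()["rats"]
        assert abs(fit.params["rats"] - 2.0) < 3 * se

    def test_cluster_duplication_halves_variance(self):
        """Doubling every cluster roughly halves sandwich variances."""
        params = SimulationParams(n_islands=500, seed=21)
        ds = simulate_dataset(params)
        spec = ModelSpec(("ln_area", "rats", "human_presence"))
        dm = build_design(ds, spec)
        fit1 = fit_gee(dm, warn=False)
        # duplicate clusters with fresh ids
        X2 = pd.concat([dm.X, dm.X], ignore_index=True)
        y2 = np.r_[dm.y, dm.y]
        ci2 = np.r_[dm.cluster_index, np.char.add(dm.cluster_index.astype(str), "_b")]
        order = np.argsort(ci2, kind="mergesort")
        dm2 = DesignMatrix(
            y=y2[order],
            X=X2.iloc[order].reset_index(drop=True),
            cluster_index=ci2[order],
            term_map=dm.term_map,
            spec=spec,
        )
        fit2 = fit_gee(dm2, warn=False)
        ratio = np.diag(fit2.robust_cov) / np.diag(fit1.robust_cov)
        np.testing.assert_allclose(ratio, 0.5, rtol=0.10)


class TestCriteria:
    def test_qicu_hand_case(self):
        y = np.array([1.0, 0.0])
        mu = np.array([0.8, 0.2])
        ql = 2 * np.log(0.8)
        assert qicu(y, mu, 1) == pytest.approx(-2 * ql + 2, abs=1e-12)
        assert qicu(y, mu, 1) == pytest.approx(2.8925742052568927, abs=1e-9)

    def test_qicu_perfect_fit_limit(self):
        y = np.array([1.0, 0.0, 1.0])
        mu = np.array([1 - 1e-9, 1e-9, 1 - 1e-9])
        assert qicu(y, mu, 3) == pytest.approx(6.0, abs=1e-6)

    def test_qicu_noise_column_penalty(self):
        """Adding a pure-noise column raises QICu by ≈ +1 on average.

        The parameter penalty adds exactly 2, while fitting the irrelevant
        coefficient improves −2·QL by a χ²₁ deviate (mean 1), so the expected
        net change is +1: the criterion still penalizes the noise column in
        expectation.
        """
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(100):
            n = 800
            x = rng.normal(size=n)
            eta = -1.0 + 0.8 * x
            y = (rng.random(n) < cloglog(eta)).astype(int)
            X1 = pd.DataFrame({"intercept": np.ones(n), "x": x})
            X2 = X1.assign(noise=rng.normal(size=n))
            dm1 = DesignMatrix(y=y, X=X1, cluster_index=np.arange(n),
                               term_map={}, spec=ModelSpec(("x",)))
            dm2 = DesignMatrix(y=y, X=X2, cluster_index=np.arange(n),
                               term_map={}, spec=ModelSpec(("x",)))
            diffs.append(fit_gee(dm2, warn=False).qicu - fit_gee(dm1, warn=False).qicu)
        assert np.mean(diffs) == pytest.approx(1.0, abs=0.5)

    def test_mse_hand_cases(self):
        assert fit_mse(np.array([1, 0]), np.array([1.0, 0.0])) == 0.0
        assert fit_mse(np.array([1, 0]), np.array([0.5, 0.5])) == 0.25
        assert fit_mse(
            np.array([1, 0, 0, 1]), np.array([0.9, 0.1, 0.3, 0.7])
        ) == pytest.approx(0.05, abs=1e-12)


class TestPredict:
    def test_training_rows_reproduce_fitted(self, paper_like_fit, paper_like_design):
        pred = predict_probability(paper_like_fit, paper_like_design)
        np.testing.assert_allclose(pred, paper_like_fit.fitted, atol=1e-12)

    def test_all_zero_row_gives_intercept_risk(self, paper_like_fit, paper_like_design):
        X = paper_like_design.X.iloc[:1].copy()
        X.iloc[0] = 0.0
        X.iloc[0, 0] = 1.0
        pred = predict_probability(paper_like_fit, X)
        assert pred[0] == pytest.approx(
            float(cloglog(paper_like_fit.params["intercept"])), abs=1e-12
        )

    def test_monotone_in_positive_coefficient(self, paper_like_fit, paper_like_design):
        col = "mustelids_mongooses"
        assert paper_like_fit.params[col] > 0
        X0 = paper_like_design.X.copy()
        X0[col] = 0.0
        X1 = X0.copy()
        X1[col] = 1.0
        assert (
            predict_probability(paper_like_fit, X1)
            >= predict_probability(paper_like_fit, X0)
        ).all()

    def test_column_mismatch_rejected(self, paper_like_fit, paper_like_design):
        from islex.preprocess import SpecificationError

        with pytest.raises(SpecificationError):
            predict_probability(paper_like_fit, paper_like_design.X.iloc[:, :-1])
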