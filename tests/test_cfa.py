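"""ML confirmatory factor analysis: estimates, constraints, fit indices, scores."""

import numpy as np
import pytest

import cttkit as ck
from cttkit.cfa import _ParamMap, _fml_and_grad, model_df


def one_factor_spec(labels, constraint="congeneric"):
    return ck.FactorModelSpec({l: "f1" for l in labels}, constraint=constraint)


class TestFitCfa:
    def test_compound_symmetry_forces_equal_loadings(self):
        v, c = 1.2, 0.5
        C = np.full((3, 3), c)
        np.fill_diagonal(C, v)
        fit = ck.fit_cfa(ck.SampleMoments(C), one_factor_spec(["v1", "v2", "v3"]))
        np.testing.assert_allclose(fit.lam[:, 0], np.sqrt(c), atol=1e-6)
        np.testing.assert_allclose(fit.theta, v - c, atol=1e-6)

    def test_just_identified_fit_reproduces_closed_form(self, verbal_moments):
        fit = ck.fit_cfa(verbal_moments, one_factor_spec(verbal_moments.labels))
        lam, uniq = ck.spearman_three_indicator(verbal_moments.cov)
        assert fit.discrepancy < 1e-10
        np.testing.assert_allclose(fit.lam[:, 0], lam, atol=1e-8)
        np.testing.assert_allclose(fit.theta, uniq, atol=1e-8)
        np.testing.assert_allclose(
            ck.model_implied_cov(fit), verbal_moments.cov, atol=1e-7
        )

    def test_two_factor_recovery_from_large_sample(self, two_factor_population):
        pop = two_factor_population
        cfg = ck.GeneratorConfig(n=5000, lam=pop["lam"], theta=pop["theta"],
                                 phi=pop["phi"], seed=7,
                                 item_labels=pop["labels"])
        data = ck.simulate_items(cfg)
        moments = ck.SampleMoments.from_items(data.items)
        fit = ck.fit_cfa(
            ck.SampleMoments(moments.cov, labels=moments.labels, n=moments.n),
            ck.FactorModelSpec(pop["pattern"]),
        )
        est = np.concatenate([fit.lam[:3, 0], fit.lam[3:, 1]])
        true = np.concatenate([pop["lam"][:3, 0], pop["lam"][3:, 1]])
        assert np.max(np.abs(est - true)) < 0.05
        assert abs(fit.phi[0, 1] - 0.26) < 0.05

    def test_nesting_monotonicity_of_discrepancy(self, random_pd_cov):
        # parallel constraints nest inside tau-equivalent inside congeneric
        for seed in range(20):
            C = random_pd_cov(4, seed=seed, positive_cov=True)
            m = ck.SampleMoments(C)
            labels = m.labels
            f = {c: ck.fit_cfa(m, one_factor_spec(labels, c)).discrepancy
                 for c in ("parallel", "tau_equivalent", "congeneric")}
            assert f["parallel"] >= f["tau_equivalent"] - 1e-9
            assert f["tau_equivalent"] >= f["congeneric"] - 1e-9

    def test_congeneric_scale_equivariance(self, random_pd_cov):
        # rescaling item j by c maps lambda_j -> c lambda_j, theta_j -> c^2 theta_j
        C = random_pd_cov(4, seed=5, positive_cov=True)
        m = ck.SampleMoments(C)
        fit = ck.fit_cfa(m, one_factor_spec(m.labels))
        c = 2.5
        D = np.diag([c, 1, 1, 1])
        fit2 = ck.fit_cfa(ck.SampleMoments(D @ C @ D), one_factor_spec(m.labels))
        np.testing.assert_allclose(fit2.lam[0, 0], c * fit.lam[0, 0], atol=1e-5)
        np.testing.assert_allclose(fit2.theta[0], c ** 2 * fit.theta[0], atol=1e-5)
        np.testing.assert_allclose(fit2.lam[1:, 0], fit.lam[1:, 0], atol=1e-5)

    def test_heywood_case_is_flagged(self):
        C = np.array([[1.0, 0.85, 0.85], [0.85, 1.0, 0.6], [0.85, 0.6, 1.0]])
        m = ck.SampleMoments(C)
        fit = ck.fit_cfa(m, one_factor_spec(m.labels))
        assert any("Heywood" in w for w in fit.warnings)

    def test_non_pd_input_rejected(self):
        C = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ck.InputError):
            ck.SampleMoments(C)

    def test_analytic_gradient_matches_finite_differences(self, two_factor_population):
        pop = two_factor_population
        spec = ck.FactorModelSpec(pop["pattern"], constraint="tau_equivalent")
        cfg = ck.GeneratorConfig(n=300, lam=pop["lam"], theta=pop["theta"],
                                 phi=pop["phi"], seed=3, item_labels=pop["labels"])
        m = ck.SampleMoments.from_items(ck.simulate_items(cfg).items)
        pm = _ParamMap(spec, m.labels, with_means=True)
        rng = np.random.default_rng(0)
        x = rng.normal(scale=0.3, size=pm.n_free) + 0.5
        S = m.cov
        _, lndetS = np.linalg.slogdet(S)
        f0, g = _fml_and_grad(x, pm, S, lndetS, m.means)
        num = np.empty_like(g)
        h = 1e-6
        for i in range(x.size):
            e = np.zeros_like(x)
            e[i] = h
            fp, _ = _fml_and_grad(x + e, pm, S, lndetS, m.means)
            fm, _ = _fml_and_grad(x - e, pm, S, lndetS, m.means)
            num[i] = (fp - fm) / (2 * h)
        np.testing.assert_allclose(g, num, rtol=1e-4, atol=1e-6)


class TestSpearmanClosedForm:
    def test_equal_half_covariances_give_sqrt_half(self):
        C = np.full((3, 3), 0.5)
        np.fill_diagonal(C, 1.0)
        lam, uniq = ck.spearman_three_indicator(C)
        np.testing.assert_allclose(lam, np.sqrt(0.5))
        np.testing.assert_allclose(uniq, 0.5)

    def test_speed_loadings_close_to_published_estimates(self, speed_moments):
        lam, _ = ck.spearman_three_indicator(speed_moments.cov)
        # published estimates (.661, .801, .565) come from unrounded data
        np.testing.assert_allclose(lam, [0.661, 0.801, 0.565], atol=0.01)

    def test_reproduces_off_diagonals_exactly(self, random_pd_cov):
        for seed in range(5):
            C = random_pd_cov(3, seed=seed, positive_cov=True)
            lam, uniq = ck.spearman_three_indicator(C)
            implied = np.outer(lam, lam) + np.diag(uniq)
            np.testing.assert_allclose(implied, C, atol=1e-10)

    def test_negative_covariance_not_applicable(self):
        C = np.array([[1.0, -0.5, 0.4], [-0.5, 1.0, 0.3], [0.4, 0.3, 1.0]])
        with pytest.raises(ck.NotApplicableError):
            ck.spearman_three_indicator(C)


class TestFitIndices:
    def test_saturated_model_reports_perfect_fit(self, verbal_moments):
        m = ck.SampleMoments(verbal_moments.cov, labels=verbal_moments.labels,
                             n=301)
        fit = ck.fit_cfa(m, one_factor_spec(m.labels))
        fx = ck.fit_indices(fit, m)
        assert (fx.chisq, fx.df, fx.rmsea) == (0.0, 0, 0.0)
        assert fx.cfi == 1.0 and fx.tli == 1.0

    @pytest.mark.parametrize("constraint,expected_df", [
        ("congeneric", 9), ("tau_equivalent", 14), ("parallel", 19),
    ])
    def test_df_taxonomy_single_factor_six_indicators(
        self, constraint, expected_df, two_factor_population, random_pd_cov
    ):
        C = random_pd_cov(6, seed=2, positive_cov=True)
        m = ck.SampleMoments(C, n=301)
        fit = ck.fit_cfa(m, one_factor_spec(m.labels, constraint))
        assert model_df(fit) == expected_df

    def test_chisq_calibrated_under_true_model(self, two_factor_population):
        # chi-square should average its df when the model holds
        pop = two_factor_population
        spec = ck.FactorModelSpec(pop["pattern"])
        chis = []
        for rep in range(200):
            cfg = ck.GeneratorConfig(n=500, lam=pop["lam"], theta=pop["theta"],
                                     phi=pop["phi"], seed=10_000 + rep,
                                     item_labels=pop["labels"])
            m = ck.SampleMoments.from_items(ck.simulate_items(cfg).items)
            m = ck.SampleMoments(m.cov, labels=m.labels, n=m.n)
            fit = ck.fit_cfa(m, spec, n_restarts=3)
            chis.append(ck.fit_indices(fit, m).chisq)
        chis = np.asarray(chis)
        df = 8  # 21 statistics - (6 loadings + 6 uniques + 1 factor corr)
        se = chis.std(ddof=1) / np.sqrt(len(chis))
        assert abs(chis.mean() - df) < 3 * se

    def test_rmsea_interval_brackets_point_estimate(self, random_pd_cov):
        C = random_pd_cov(6, seed=4, positive_cov=True)
        # perturb to induce misfit
        C = C + 0.05 * np.diag(np.ones(6))
        C[0, 5] = C[5, 0] = C[0, 5] + 0.15
        m = ck.SampleMoments(C, n=200)
        fit = ck.fit_cfa(m, one_factor_spec(m.labels))
        fx = ck.fit_indices(fit, m)
        lo, hi = fx.rmsea_ci90
        assert 0 <= lo <= fx.rmsea <= hi


class TestFactorScores:
    def test_error_free_single_indicator_limit(self):
        # lambda = 1, theta -> 0: scores equal centered item values
        rng = np.random.default_rng(12)
        f = rng.normal(size=400)
        x = np.column_stack([f, f, f]) + rng.normal(scale=1e-4, size=(400, 3))
        items = ck.ItemMatrix(x, ["a", "b", "c"])
        m = ck.SampleMoments.from_items(items)
        fit = ck.fit_cfa(m, one_factor_spec(m.labels))
        scores, W = ck.factor_scores_regression(fit, m, items)
        resid = scores[:, 0] - (x[:, 0] - x[:, 0].mean()) / x[:, 0].std(ddof=1) * \
            np.sqrt(float(fit.lam[0, 0] ** 2))
        assert abs(np.corrcoef(scores[:, 0], f)[0, 1]) > 0.9999
        assert abs(scores[:, 0].mean()) < 1e-12
        assert resid.std() < 0.05

    def test_scores_have_mean_zero_and_expose_weights(self, two_factor_population):
        pop = two_factor_population
        cfg = ck.GeneratorConfig(n=600, lam=pop["lam"], theta=pop["theta"],
                                 phi=pop["phi"], seed=21, item_labels=pop["labels"])
        data = ck.simulate_items(cfg)
        m = ck.SampleMoments.from_items(data.items)
        fit = ck.fit_cfa(m, ck.FactorModelSpec(pop["pattern"]))
        scores, W = ck.factor_scores_regression(fit, m, data.items)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-12)
        assert W.shape == (2, 6)
        # holdout scoring with calibration weights is a plain linear map
        np.testing.assert_allclose(
            scores, (data.items.values - m.means) @ W.T, atol=1e-12
        )

    def test_score_determinacy_matches_formula_in_simulation(self):
        # squared correlation of estimated with true scores ~ lambda' C^-1 lambda
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        theta = 1.0 - lam ** 2
        cfg = ck.GeneratorConfig(n=20000, lam=lam, theta=theta, seed=31)
        data = ck.simulate_items(cfg)
        m = ck.SampleMoments.from_items(data.items)
        fit = ck.fit_cfa(m, one_factor_spec(m.labels))
        scores, _ = ck.factor_scores_regression(fit, m, data.items)
        r2 = np.corrcoef(scores[:, 0], data.factors[:, 0])[0, 1] ** 2
        C = np.outer(lam, lam) + np.diag(theta)
        rho2 = float(lam @ np.linalg.inv(C) @ lam)
        assert abs(r2 - rho2) < 0.02


class TestModelImpliedCov:
    def test_zero_loadings_imply_diagonal(self):
        fit = ck.FittedFactorModel(
            lam=np.zeros((3, 1)), theta=np.array([1.0, 2.0, 3.0]),
            phi=np.eye(1), nu=None, discrepancy=0.0, converged=True,
            n_iterations=0, n_free=0)
        np.testing.assert_allclose(ck.model_implied_cov(fit), np.diag([1, 2, 3.0]))

    def test_published_two_factor_estimates_imply_verbal_covariances(
        self, two_factor_population, verbal_moments
    ):
        # the published 2-decimal loadings reproduce the verbal covariances
        # up to their rounding (worst pair off by ~0.013)
        pop = two_factor_population
        fit = ck.FittedFactorModel(
            lam=pop["lam"], theta=pop["theta"], phi=pop["phi"], nu=None,
            discrepancy=0.0, converged=True, n_iterations=0, n_free=0)
        implied = ck.model_implied_cov(fit)[:3, :3]
        off = ~np.eye(3, dtype=bool)
        assert np.max(np.abs(implied[off] - verbal_moments.cov[off])) < 0.02

    def test_implied_matrix_is_psd_for_nonnegative_theta(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            lam = rng.normal(size=(5, 2))
            theta = rng.uniform(0, 1, size=5)
            phi = np.eye(2)
            phi[0, 1] = phi[1, 0] = rng.uniform(-0.8, 0.8)
            fit = ck.FittedFactorModel(
                lam=lam, theta=theta, phi=phi, nu=None, discrepancy=0.0,
                converged=True, n_iterations=0, n_free=0)
            assert np.linalg.eigvalsh(ck.model_implied_cov(fit)).min() > -1e-10
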