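"""Inference-engine correctness: Matérn covariance closed forms, Laplace
fits against an independent IRLS oracle, mixture marginals against sampling,
WAIC against hand-computed values, GP-conditioned prediction identities."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit

from snakerisk.model import (
    MaternHyperparams,
    SpatialLogisticGP,
    build_covariance,
    matern_cov,
    mixture_marginal_summary,
    odds_from_logit,
    waic_from_loglik,
)


def vague(include_spatial=False, **kw):
    kw.setdefault("beta_precision", 1e-8)
    kw.setdefault("random_state", 0)
    return SpatialLogisticGP(include_spatial=include_spatial, **kw)


class TestMaternCov:
    def test_at_zero_distance_equals_variance(self):
        assert matern_cov(0.0, MaternHyperparams(1.0, 10.0)) == 1.0
        assert matern_cov(0.0, MaternHyperparams(2.0, 10.0)) == 4.0

    def test_at_range_matches_independent_bessel(self):
        """At d = rho the correlation is sqrt(8) K1(sqrt 8), with K1 evaluated
        by an independent integral representation."""
        k1, _ = quad(
            lambda t: np.exp(-np.sqrt(8) * np.cosh(t)) * np.cosh(t), 0, 30, limit=200
        )
        expected = np.sqrt(8) * k1
        got = matern_cov(25.0, MaternHyperparams(1.0, 25.0))
        assert got == pytest.approx(expected, abs=1e-10)
        assert got == pytest.approx(0.139, abs=1e-3)

    def test_strictly_decreasing(self, rng):
        hyper = MaternHyperparams(1.3, 12.0)
        d = np.sort(rng.uniform(0.01, 100, 1000))
        vals = matern_cov(d, hyper)
        assert (np.diff(vals) < 0).all()

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            matern_cov(-1.0, MaternHyperparams(1.0, 10.0))

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            MaternHyperparams(-1.0, 10.0)
        with pytest.raises(ValueError):
            MaternHyperparams(1.0, 0.0)


class TestBuildCovariance:
    def test_identical_points_give_sigma2_plus_jitter(self):
        hyper = MaternHyperparams(1.5, 10.0)
        with pytest.warns(UserWarning, match="jitter"):
            cov = build_covariance([(0, 0), (0, 0)], hyper)
        assert cov[0, 1] == pytest.approx(2.25)
        assert cov[0, 0] == pytest.approx(2.25 * (1 + 1e-8))

    def test_positive_definite(self, rng):
        locs = rng.uniform(0, 100, (50, 2))
        cov = build_covariance(locs, MaternHyperparams(1.0, 20.0))
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_entries_match_elementwise_matern(self, rng):
        from scipy.spatial.distance import cdist

        locs = rng.uniform(0, 50, (10, 2))
        hyper = MaternHyperparams(0.8, 15.0)
        cov = build_covariance(locs, hyper, jitter=0.0)
        expected = matern_cov(cdist(locs, locs), hyper)
        np.testing.assert_allclose(cov, expected)

    def test_dense_limit_enforced(self, rng):
        locs = rng.uniform(0, 10, (30, 2))
        with pytest.raises(ValueError, match="dense"):
            build_covariance(locs, MaternHyperparams(1.0, 5.0), dense_limit=10)


class TestLaplaceFit:
    def test_intercept_only_matches_log_odds(self):
        """12 successes in 100 trials, vague prior: mode ~ log(12/88)."""
        y = np.r_[np.ones(12), np.zeros(88)]
        est = vague().fit(np.zeros((100, 0)), y)
        assert est.intercept_ == pytest.approx(np.log(12 / 88), abs=1e-2)

    def test_tiny_sigma_matches_plain_logistic_regression(self, rng):
        """sigma -> 0 spatial fit reproduces the IRLS solution."""
        import statsmodels.api as sm

        n = 300
        X = rng.standard_normal((n, 2))
        eta = -1.0 + X @ [0.8, -0.5]
        y = (rng.uniform(size=n) < expit(eta)).astype(float)
        coords = rng.uniform(0, 100, (n, 2))
        est = vague(
            include_spatial=True, sigma_bounds=(1e-6, 1e-6), rho_bounds=(10.0, 10.0),
            grid_size=1,
        ).fit(X, y, coords=coords)
        glm = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            np.r_[est.intercept_, est.coef_], glm.params, atol=1e-4
        )

    def test_all_zero_outcomes_regularized(self):
        y = np.zeros(100)
        est = SpatialLogisticGP(include_spatial=False, random_state=0).fit(
            np.zeros((100, 0)), y
        )
        assert est.intercept_ < -4
        assert np.isfinite(est.intercept_)

    def test_rank_deficient_design_rejected(self, rng):
        X = np.ones((50, 2))
        y = rng.integers(0, 2, 50).astype(float)
        with pytest.raises(ValueError, match="rank"):
            SpatialLogisticGP(include_spatial=False).fit(X, y)

    def test_nonbinary_outcomes_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            SpatialLogisticGP(include_spatial=False).fit(np.zeros((3, 0)), [0, 1, 2])

    def test_unscaled_design_tag_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0]})
        X.attrs["scaled"] = False
        with pytest.raises(ValueError, match="unscaled|scale"):
            SpatialLogisticGP(include_spatial=False).fit(X, [0, 1, 0, 1])

    def test_irls_equivalence_many_random_datasets(self, rng):
        """Non-spatial engine vs statsmodels IRLS on 20 random datasets."""
        import statsmodels.api as sm

        for _ in range(20):
            n = 200
            X = rng.standard_normal((n, 3))
            beta = rng.uniform(-1, 1, 3)
            y = (rng.uniform(size=n) < expit(0.3 + X @ beta)).astype(float)
            est = vague().fit(X, y)
            glm = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
            np.testing.assert_allclose(
                np.r_[est.intercept_, est.coef_], glm.params, atol=1e-4
            )

    def test_hyperparameter_continuity(self, small_survey):
        """1% perturbation of (sigma, rho) changes coefficient means < 5%."""
        sv = small_survey
        X = sv.design[["ndvi", "dist_water", "food_storage"]]
        y = sv.households["outcome_human"].to_numpy()

        def fit_at(sigma, rho):
            return SpatialLogisticGP(
                sigma_bounds=(sigma, sigma), rho_bounds=(rho, rho), grid_size=1,
                random_state=0,
            ).fit(X, y, coords=sv.coords, groups=sv.households["cluster_id"])

        base = fit_at(1.0, 30.0).summary_["mean"]
        pert = fit_at(1.01, 30.3).summary_["mean"]
        rel = np.abs(pert - base) / np.maximum(np.abs(base), 0.05)
        assert (rel < 0.05).all()


class TestHyperparameterGrid:
    def test_single_node_weight_is_one(self, small_survey):
        sv = small_survey
        est = SpatialLogisticGP(
            grid_size=1, sigma_bounds=(1.0, 1.0), rho_bounds=(30.0, 30.0), random_state=0
        ).fit(
            sv.design[["ndvi"]], sv.households["outcome_human"].to_numpy(),
            coords=sv.coords, groups=sv.households["cluster_id"],
        )
        assert est.weights_.shape == (1,)
        assert est.weights_[0] == 1.0

    def test_weights_normalized(self, small_survey):
        sv = small_survey
        est = SpatialLogisticGP(grid_size=3, random_state=0).fit(
            sv.design[["ndvi", "dist_water"]],
            sv.households["outcome_human"].to_numpy(),
            coords=sv.coords, groups=sv.households["cluster_id"],
        )
        assert est.weights_.sum() == pytest.approx(1.0, abs=1e-12)
        assert (est.weights_ >= 0).all()


class TestMarginals:
    def test_single_gaussian_ci(self):
        s = mixture_marginal_summary([1.0], [2.0], [0.25])
        assert s["mean"] == pytest.approx(2.0)
        assert s["ci_lower"] == pytest.approx(2.0 - 1.6449 * 0.5, abs=1e-4)
        assert s["ci_upper"] == pytest.approx(2.0 + 1.6449 * 0.5, abs=1e-4)

    def test_equal_mixture_mean(self):
        s = mixture_marginal_summary([0.5, 0.5], [0.0, 2.0], [1.0, 1.0])
        assert s["mean"] == pytest.approx(1.0)

    def test_quantiles_match_sampling_oracle(self, rng):
        """Random mixtures vs 1e6-draw empirical quantiles (3 SEs)."""
        for _ in range(5):
            k = int(rng.integers(2, 5))
            w = rng.dirichlet(np.ones(k))
            mu = rng.uniform(-3, 3, k)
            sd = rng.uniform(0.2, 2.0, k)
            s = mixture_marginal_summary(w, mu, sd**2)
            n = 1_000_000
            comp = rng.choice(k, n, p=w)
            draws = rng.normal(mu[comp], sd[comp])
            for q, key in ((0.05, "ci_lower"), (0.95, "ci_upper")):
                emp = np.quantile(draws, q)
                dens = np.sum(w * np.exp(-0.5 * ((emp - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi)))
                se = np.sqrt(q * (1 - q) / n) / dens
                assert abs(s[key] - emp) < 3 * se


class TestOdds:
    @pytest.mark.parametrize(
        "logit,expected",
        [(0.32, 1.38), (-1.43, 0.24), (0.0, 1.0), (0.82, 2.27), (-0.77, 0.46), (-2.12, 0.12)],
    )
    def test_round_trip_to_two_decimals(self, logit, expected):
        assert round(odds_from_logit(logit), 2) == pytest.approx(expected)

    def test_interval_transform(self):
        lo, hi = odds_from_logit(np.array([-0.5, 0.5]))
        assert lo == pytest.approx(np.exp(-0.5))
        assert hi == pytest.approx(np.exp(0.5))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            odds_from_logit(np.inf)


class TestWaic:
    def test_degenerate_one_sample_posterior(self):
        ll = np.log(np.array([[0.2, 0.7]]))
        waic, p_waic, lppd = waic_from_loglik(ll)
        assert p_waic == 0.0
        assert waic == pytest.approx(-2 * (np.log(0.2) + np.log(0.7)))
        del lppd

    def test_three_sample_toy_hand_computed(self):
        """Explicit 3-sample posterior on 2 observations against the direct
        formula computed by hand."""
        p = np.array([[0.1, 0.8], [0.2, 0.6], [0.15, 0.7]])
        ll = np.log(p)
        lppd_hand = np.log(p[:, 0].mean()) + np.log(p[:, 1].mean())
        p_hand = ll[:, 0].var(ddof=1) + ll[:, 1].var(ddof=1)
        waic, p_waic, lppd = waic_from_loglik(ll)
        assert lppd == pytest.approx(lppd_hand, abs=1e-12)
        assert p_waic == pytest.approx(p_hand, abs=1e-12)
        assert waic == pytest.approx(-2 * (lppd_hand - p_hand), abs=1e-12)

    def test_observation_order_invariance(self, rng):
        ll = np.log(rng.uniform(0.05, 0.95, (10, 6)))
        perm = rng.permutation(6)
        assert waic_from_loglik(ll)[0] == pytest.approx(
            waic_from_loglik(ll[:, perm])[0], abs=1e-12
        )

    def test_too_few_samples_rejected(self, small_survey):
        sv = small_survey
        est = SpatialLogisticGP(include_spatial=False, n_waic_samples=1, random_state=0)
        with pytest.raises(ValueError, match="2 posterior samples"):
            est.fit(sv.design[["ndvi"]], sv.households["outcome_human"].to_numpy())


class TestPrediction:
    def test_symmetric_null_predicts_half(self):
        """Balanced outcomes, no covariates, negligible field: mean risk 0.5."""
        n = 2000
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 100, (n, 2))
        est = vague(
            include_spatial=True, sigma_bounds=(1e-6, 1e-6), rho_bounds=(20.0, 20.0),
            grid_size=1,
        ).fit(np.zeros((n, 0)), y, coords=coords, groups=np.repeat(np.arange(20), 100))
        mean, sd = est.predict_risk(np.zeros((5, 0)), coords=rng.uniform(0, 100, (5, 2)))
        np.testing.assert_allclose(mean, 0.5, atol=1e-3)

    def test_far_point_reverts_to_prior(self, small_survey):
        """A prediction point many ranges away from all data has latent
        marginal ~ N(0, sigma^2)."""
        sv = small_survey
        est = SpatialLogisticGP(
            sigma_bounds=(0.9, 0.9), rho_bounds=(20.0, 20.0), grid_size=1, random_state=0
        ).fit(
            sv.design[["ndvi"]], sv.households["outcome_human"].to_numpy(),
            coords=sv.coords, groups=sv.households["cluster_id"],
        )
        far = np.array([[5000.0, 5000.0]])
        mean, sd = est.predict_latent(far)
        assert mean[0] == pytest.approx(0.0, abs=1e-3)
        assert sd[0] == pytest.approx(0.9, abs=1e-3)

    def test_observed_site_matches_posterior_mode(self, small_survey):
        """Predicting u at a latent site returns that site's posterior mode
        (single hyperparameter node)."""
        sv = small_survey
        est = SpatialLogisticGP(
            sigma_bounds=(1.0, 1.0), rho_bounds=(30.0, 30.0), grid_size=1, random_state=0
        ).fit(
            sv.design[["ndvi"]], sv.households["outcome_human"].to_numpy(),
            coords=sv.coords, groups=sv.households["cluster_id"],
        )
        p = len(est.coef_names_)
        site = est.latent_sites_[3][None, :]
        mean, _ = est.predict_latent(site)
        assert mean[0] == pytest.approx(est.nodes_[0].mode[p + 3], abs=1e-6)

    def test_mean_risk_in_unit_interval(self, small_survey):
        sv = small_survey
        est = SpatialLogisticGP(grid_size=3, random_state=0).fit(
            sv.design[["ndvi", "dist_water"]],
            sv.households["outcome_human"].to_numpy(),
            coords=sv.coords, groups=sv.households["cluster_id"],
        )
        rng = np.random.default_rng(1)
        Xn = pd.DataFrame({"ndvi": rng.uniform(0, 1, 20), "dist_water": rng.uniform(0, 5, 20)})
        mean, sd = est.predict_risk(Xn, coords=rng.uniform(0, 100, (20, 2)))
        assert ((mean > 0) & (mean < 1)).all()
        assert (sd >= 0).all()

    def test_wrong_covariate_set_rejected(self, small_survey):
        sv = small_survey
        est = SpatialLogisticGP(include_spatial=False, random_state=0).fit(
            sv.design[["ndvi"]], sv.households["outcome_human"].to_numpy()
        )
        with pytest.raises(ValueError, match="match|columns"):
            est.predict_risk(pd.DataFrame({"bio6": [0.5]}))


class TestPersistence:
    def test_save_load_round_trip(self, small_survey, tmp_path):
        sv = small_survey
        est = SpatialLogisticGP(grid_size=3, random_state=0).fit(
            sv.design[["ndvi", "dist_water"]],
            sv.households["outcome_human"].to_numpy(),
            coords=sv.coords, groups=sv.households["cluster_id"],
        )
        est.save(tmp_path / "m.npz")
        back = SpatialLogisticGP.load(tmp_path / "m.npz")
        pd.testing.assert_frame_equal(
            back.summary_.astype(float), est.summary_.astype(float)
        )
        rng = np.random.default_rng(2)
        Xn = pd.DataFrame({"ndvi": [0.4], "dist_water": [1.0]})
        c = rng.uniform(0, 100, (1, 2))
        m1, s1 = est.predict_risk(Xn, coords=c, random_state=9)
        m2, s2 = back.predict_risk(Xn, coords=c, random_state=9)
        np.testing.assert_allclose(m1, m2)
        np.testing.assert_allclose(s1, s2)
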