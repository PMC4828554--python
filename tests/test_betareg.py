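import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st
from scipy import integrate, stats

from bsfareg.betareg import (
    BetaRegData,
    BetaRegPriors,
    beta_logpdf,
    fit_ml,
    inv_logit,
    logit,
    loglik,
    run_beta_mcmc,
)
from bsfareg.sfa import McmcSettings
from bsfareg.synthetic import TrueBetaRegParams, simulate_beta_outcomes


def _data_from_xy(X, y):
    n = len(y)
    return BetaRegData(
        units=np.array([f"u{i}" for i in range(n)], dtype=object),
        y=np.asarray(y, dtype=float),
        X=np.asarray(X, dtype=float),
    )


class TestLink:
    def test_logit_half_is_zero(self):
        assert logit(0.5) == 0.0

    def test_inv_logit_zero_is_half(self):
        assert inv_logit(0.0) == 0.5

    def test_roundtrip_minus_twenty(self):
        assert abs(logit(inv_logit(-20.0)) + 20.0) < 1e-9

    @given(eta=st.floats(min_value=-30.0, max_value=10.0))
    @hyp_settings(max_examples=100, deadline=None)
    def test_roundtrip_property(self, eta):
        assert abs(logit(inv_logit(eta)) - eta) <= 1e-9 * max(1.0, abs(eta))

    def test_inv_logit_extreme_arguments_stay_finite(self):
        assert inv_logit(700.0) == 1.0  # saturates without overflow
        assert 0.0 < inv_logit(-700.0) < 1e-300

    @pytest.mark.parametrize("mu", [0.0, 1.0, -0.5, 1.5])
    def test_logit_rejects_boundary(self, mu):
        with pytest.raises(ValueError):
            logit(mu)


class TestBetaLogpdf:
    def test_uniform_case(self):
        # mu = 0.5, phi = 2 is Beta(1, 1)
        assert abs(beta_logpdf(0.3, 0.5, 2.0)) < 1e-12

    def test_beta22_closed_form(self):
        # Beta(2, 2) density at 0.25 is 6 * 0.25 * 0.75 = 1.125
        assert beta_logpdf(0.25, 0.5, 4.0) == pytest.approx(math.log(1.125), abs=1e-12)

    @pytest.mark.parametrize("mu", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("phi", [0.5, 5.0, 50.0])
    def test_normalization_by_quadrature(self, mu, phi):
        val, err = integrate.quad(lambda t: math.exp(beta_logpdf(t, mu, phi)), 0.0, 1.0, limit=200)
        assert abs(val - 1.0) < 1e-6

    @given(
        y=st.floats(min_value=0.01, max_value=0.99),
        mu=st.floats(min_value=0.05, max_value=0.95),
        phi=st.floats(min_value=0.1, max_value=200.0),
    )
    @hyp_settings(max_examples=200, deadline=None)
    def test_matches_scipy_parameterization(self, y, mu, phi):
        expected = stats.beta.logpdf(y, mu * phi, (1.0 - mu) * phi)
        assert beta_logpdf(y, mu, phi) == pytest.approx(expected, rel=1e-10, abs=1e-10)

    @pytest.mark.parametrize("y", [0.0, 1.0])
    def test_boundary_rejected(self, y):
        with pytest.raises(ValueError):
            beta_logpdf(y, 0.5, 2.0)

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            beta_logpdf(0.5, 0.5, 0.0)


class TestLoglik:
    def test_single_observation_reduces_to_logpdf(self):
        data = _data_from_xy(np.array([[1.0, 0.5]]), np.array([0.4]))
        beta = np.array([0.2, -0.3])
        mu = inv_logit(0.2 - 0.15)
        assert loglik(data, beta, 3.0) == pytest.approx(beta_logpdf(0.4, mu, 3.0), abs=1e-12)

    def test_duplicated_observation_doubles_contribution(self, rng):
        X = np.column_stack([np.ones(4), rng.standard_normal(4)])
        y = rng.uniform(0.2, 0.8, 4)
        beta = np.array([0.1, 0.2])
        base = loglik(_data_from_xy(X, y), beta, 5.0)
        X2 = np.vstack([X, X[-1:]])
        y2 = np.append(y, y[-1])
        dup = loglik(_data_from_xy(X2, y2), beta, 5.0)
        single = beta_logpdf(y[-1], inv_logit(X[-1] @ beta), 5.0)
        assert dup - base == pytest.approx(single, abs=1e-10)

    def test_agrees_with_independent_scipy_coding(self, rng):
        n = 10
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.uniform(0.1, 0.9, n)
        beta = np.array([-0.2, 0.4])
        phi = 7.0
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        expected = float(np.sum(stats.beta.logpdf(y, mu * phi, (1.0 - mu) * phi)))
        assert loglik(_data_from_xy(X, y), beta, phi) == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        data = _data_from_xy(np.column_stack([np.ones(5), rng.standard_normal(5)]), rng.uniform(0.2, 0.8, 5))
        with pytest.raises(ValueError):
            loglik(data, np.array([0.1]), 1.0)


class TestFitMl:
    def test_symmetric_pairs_give_zero_coefficients(self, rng):
        # pairing every y with 1 - y at the same covariate makes beta = 0 the MLE
        x = np.repeat(rng.standard_normal(30), 2)
        y_half = rng.uniform(0.55, 0.9, 30)
        y = np.empty(60)
        y[0::2] = y_half
        y[1::2] = 1.0 - y_half
        data = _data_from_xy(np.column_stack([np.ones(60), x]), y)
        fit = fit_ml(data)
        assert abs(fit.beta[0]) < 1e-6
        assert abs(fit.beta[1]) < 1e-6

    def test_recovery_on_synthetic_data(self, rng):
        n = 2000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        data = simulate_beta_outcomes(X, TrueBetaRegParams(beta=(-0.1, 0.15), phi=40.0, seed=31))
        fit = fit_ml(data)
        assert abs(fit.beta[0] + 0.1) < 3 * fit.se_beta[0]
        assert abs(fit.beta[1] - 0.15) < 3 * fit.se_beta[1]
        assert abs(fit.phi - 40.0) < 3 * fit.se_phi
        assert fit.grad_norm < 1e-6
        assert (fit.se_beta > 0).all() and fit.se_phi > 0

    def test_fit_beats_generating_parameters(self, rng):
        n = 300
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        data = simulate_beta_outcomes(X, TrueBetaRegParams(beta=(0.3, -0.2), phi=15.0, seed=32))
        fit = fit_ml(data)
        assert fit.loglik >= loglik(data, np.array([0.3, -0.2]), 15.0)

    def test_matches_statsmodels(self, rng):
        sm_beta = pytest.importorskip("statsmodels.othermod.betareg")
        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        data = simulate_beta_outcomes(X, TrueBetaRegParams(beta=(0.2, 0.3), phi=25.0, seed=33))
        fit = fit_ml(data)
        res = sm_beta.BetaModel(data.y, data.X, exog_precision=np.ones((n, 1))).fit(disp=False)
        np.testing.assert_allclose(fit.beta, res.params[:-1], atol=1e-4)
        assert fit.phi == pytest.approx(math.exp(res.params[-1]), rel=1e-3)

    def test_too_few_observations_rejected(self, rng):
        data = _data_from_xy(np.column_stack([np.ones(3), rng.standard_normal(3)]), rng.uniform(0.3, 0.7, 3))
        with pytest.raises(ValueError):
            fit_ml(data)


class TestRunBetaMcmc:
    def test_paper_scale_retention_arithmetic(self):
        assert McmcSettings(n_iter=48000, n_burn=9500, thin=1, seed=0).n_retained == 38500

    def test_retained_count_small_run(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        data = simulate_beta_outcomes(X, TrueBetaRegParams(beta=(0.2, 0.1), phi=20.0, seed=41))
        draws = run_beta_mcmc(data, BetaRegPriors(), McmcSettings(900, 300, 2, 42))
        assert draws.n_draws == 300
        assert (draws.phi_draws > 0).all()
        assert 0.0 <= draws.accept_rate_beta <= 1.0

    def test_seed_determinism(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        data = simulate_beta_outcomes(X, TrueBetaRegParams(beta=(0.1, 0.2), phi=30.0, seed=43))
        s = McmcSettings(800, 300, 1, 44)
        a = run_beta_mcmc(data, BetaRegPriors(), s)
        b = run_beta_mcmc(data, BetaRegPriors(), s)
        assert np.array_equal(a.beta_draws, b.beta_draws)
        assert np.array_equal(a.phi_draws, b.phi_draws)

    def test_diffuse_prior_agrees_with_ml(self, rng):
        n = 800
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        data = simulate_beta_outcomes(X, TrueBetaRegParams(beta=(-0.1, 0.15), phi=40.0, seed=45))
        fit = fit_ml(data)
        draws = run_beta_mcmc(data, BetaRegPriors(beta_prior_sd=1e4), McmcSettings(6000, 2000, 1, 46))
        post_mean = draws.beta_draws.mean(axis=0)
        post_sd = draws.beta_draws.std(axis=0, ddof=1)
        assert np.all(np.abs(post_mean - fit.beta) < 3 * post_sd)
        assert abs(draws.phi_draws.mean() - fit.phi) < 3 * draws.phi_draws.std(ddof=1)

    def test_acceptance_rates_in_adapted_band(self, rng):
        n = 300
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        data = simulate_beta_outcomes(X, TrueBetaRegParams(beta=(0.0, 0.3), phi=25.0, seed=47))
        draws = run_beta_mcmc(data, BetaRegPriors(), McmcSettings(5000, 2000, 1, 48))
        assert 0.1 < draws.accept_rate_beta < 0.6
        assert 0.15 < draws.accept_rate_phi < 0.7

    def test_grid_oracle_intercept_only(self):
        from bsfareg.diagnostics import mc_error
        from helpers import betareg_grid_posterior

        y = np.array([0.3, 0.6])
        data = _data_from_xy(np.ones((2, 1)), y)
        priors = BetaRegPriors(beta_prior_sd=2.0, phi_prior_shape=2.0, phi_prior_rate=0.5)
        (mb, sb), (mf, sf), edge = betareg_grid_posterior(
            y, priors,
            beta_grid=np.linspace(-6, 6, 241),
            log_phi_grid=np.linspace(math.log(1e-3), math.log(200), 241),
        )
        assert edge < 1e-6
        draws = run_beta_mcmc(data, priors, McmcSettings(20000, 4000, 1, 11))
        b = draws.beta_draws[:, 0]
        f = draws.phi_draws
        assert abs(b.mean() - mb) < 3 * mc_error(b) + 0.01
        assert abs(f.mean() - mf) < 3 * mc_error(f) + 0.05
        assert abs(b.std(ddof=1) - sb) / sb < 0.1
        assert abs(f.std(ddof=1) - sf) / sf < 0.15

    def test_coverage_of_credible_intervals(self):
        # ~95% of 95% intervals over 100 seeded replications should cover truth
        beta_true = np.array([0.3, 0.2])
        hits = 0
        total = 0
        for rep in range(100):
            gen = np.random.default_rng(900 + rep)
            X = np.column_stack([np.ones(40), gen.standard_normal(40)])
            data = simulate_beta_outcomes(X, TrueBetaRegParams(beta=(0.3, 0.2), phi=30.0, seed=900 + rep))
            draws = run_beta_mcmc(data, BetaRegPriors(), McmcSettings(2200, 700, 1, 7000 + rep))
            for j in range(2):
                lo, hi = np.quantile(draws.beta_draws[:, j], [0.025, 0.975])
                hits += lo <= beta_true[j] <= hi
                total += 1
        rate = hits / total
        assert 0.88 <= rate <= 1.0
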