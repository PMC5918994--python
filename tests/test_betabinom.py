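"""Distribution core and maximum-likelihood regression engine."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import betabinom as scipy_bb
from scipy.stats import binom

import snvppv as sp


class TestMomentsAndBridge:
    def test_binomial_limit_moments(self):
        assert sp.bb_moments(sp.BBParams(0.5, 0.0, 10)) == (5.0, 2.5)

    def test_overdispersed_moments(self):
        mean, var = sp.bb_moments(sp.BBParams(0.5, 1.0, 10))
        assert (mean, var) == (5.0, 13.75)

    def test_variance_approaches_maximal_overdispersion(self):
        n, mu = 50, 0.3
        _, var = sp.bb_moments(sp.BBParams(mu, 1e9, n))
        assert var == pytest.approx(n**2 * mu * (1 - mu), rel=1e-6)

    @pytest.mark.parametrize("mu,sigma,expected", [(0.5, 0.5, (1, 1)), (0.5, 1.0, (0.5, 0.5))])
    def test_shape_bridge(self, mu, sigma, expected):
        assert sp.ab_from_musigma(mu, sigma) == pytest.approx(expected)

    def test_bridge_rejects_binomial_limit(self):
        with pytest.raises(ValueError):
            sp.ab_from_musigma(0.5, 0.0)

    @given(
        st.floats(0.01, 0.99),
        st.floats(1e-4, 50.0),
        st.integers(1, 10_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_variance_forms_agree_and_bridge_roundtrips(self, mu, sigma, n):
        """The (mu, sigma) variance equals the (alpha, beta) form exactly."""
        a, b = sp.ab_from_musigma(mu, sigma)
        mu2, sigma2 = sp.musigma_from_ab(a, b)
        assert mu2 == pytest.approx(mu, rel=1e-12)
        assert sigma2 == pytest.approx(sigma, rel=1e-12)
        _, var = sp.bb_moments(sp.BBParams(mu, sigma, n))
        var_ab = n * a * b * (a + b + n) / ((a + b) ** 2 * (a + b + 1))
        assert var == pytest.approx(var_ab, rel=1e-10)


class TestLogPmf:
    def test_normalizes(self):
        p = sp.BBParams(0.3, 0.7, 12)
        assert np.exp(sp.bb_logpmf(np.arange(13), p)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_reference(self):
        p = sp.BBParams(0.42, 1.3, 25)
        a, b = sp.ab_from_musigma(0.42, 1.3)
        ys = np.arange(26)
        np.testing.assert_allclose(
            sp.bb_logpmf(ys, p), scipy_bb.logpmf(ys, 25, a, b), rtol=1e-10
        )

    def test_binomial_limit(self):
        got = sp.bb_logpmf(6, sp.BBParams(0.3, 1e-8, 20))
        assert got == pytest.approx(binom.logpmf(6, 20, 0.3), abs=1e-6)

    def test_large_n_tiny_sigma_stable(self):
        got = sp.bb_logpmf(30_000, sp.BBParams(0.3, 1e-13, 100_000))
        assert got == pytest.approx(binom.logpmf(30_000, 100_000, 0.3), abs=1e-8)

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError):
            sp.bb_logpmf(21, sp.BBParams(0.3, 0.5, 20))

    def test_sampler_matches_moments(self):
        params = sp.BBParams(0.7, 0.4, 40)
        draws = sp.bb_rvs(params, 100_000, np.random.default_rng(1))
        mean, var = sp.bb_moments(params)
        assert draws.mean() == pytest.approx(mean, rel=0.01)
        assert draws.var() == pytest.approx(var, rel=0.05)

    def test_cdf_matches_scipy(self):
        p = sp.BBParams(0.6, 0.9, 30)
        a, b = sp.ab_from_musigma(0.6, 0.9)
        for y in (0, 7, 15, 29, 30):
            assert sp.bb_cdf(y, p) == pytest.approx(scipy_bb.cdf(y, 30, a, b), abs=1e-10)


class TestLinks:
    def test_logit_mean_link(self):
        assert sp.link_mu(0.0) == 0.5
        assert sp.link_mu(2.0) == pytest.approx(np.exp(2) / (1 + np.exp(2)))

    def test_log_dispersion_link(self):
        assert sp.link_sigma(0.0, "log") == 1.0

    def test_boxcox_dispersion_link(self):
        assert sp.link_sigma(4.0, "boxcox", boxcox_lambda=0.5) == pytest.approx(16.0)

    def test_boxcox_approaches_log_link(self):
        """(1 + lam*zeta)^(1/lam) -> exp(zeta): at matched linear predictors
        small-lambda Box-Cox reproduces log-link sigma values."""
        zeta = 0.7
        for lam in (1e-4, 1e-6):
            assert sp.link_sigma(1 + lam * zeta, "boxcox", boxcox_lambda=lam) == pytest.approx(
                np.exp(zeta), rel=1e-3
            )

    def test_boxcox_requires_positive_predictor(self):
        with pytest.raises(ValueError):
            sp.link_sigma(-1.0, "boxcox", boxcox_lambda=0.5)


class TestFit:
    def test_recovers_known_coefficients(self, default_table):
        """Estimates land within 3 Wald SE of the generating truth."""
        cfg = sp.default_config(seed=42)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = sp.fit(default_table, cfg.spec)
        assert m.converged
        est = np.concatenate([m.beta_coef, m.gamma_coef])
        se = np.concatenate([m.se_beta, m.se_gamma])
        z = np.abs(est - np.concatenate([cfg.beta, cfg.gamma])) / se
        assert np.all(np.isfinite(se))
        assert np.mean(z <= 3) >= 0.94

    def test_titv_coefficient_magnitude(self, m116_model):
        """The Ti/Tv mean coefficient recovers its generating value ~5.15."""
        idx = m116_model.x_names.index("titv")
        est, se = m116_model.beta_coef[idx], m116_model.se_beta[idx]
        assert est == pytest.approx(5.15, abs=3 * se)

    def test_aic_identity_and_term_order_invariance(self, default_table):
        spec = sp.named_spec("m11_1")
        perm = sp.ModelSpec(
            mean_terms=spec.mean_terms[:1] + spec.mean_terms[1:][::-1],
            dispersion_terms=spec.dispersion_terms,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = sp.fit(default_table, spec)
            m2 = sp.fit(default_table, perm)
        assert m1.aic == pytest.approx(-2 * m1.loglik + 2 * (spec.p + spec.q))
        assert m1.aic == pytest.approx(m2.aic, abs=1e-3)

    def test_binomial_data_gives_near_zero_sigma_and_smaller_model_wins(self):
        """On Binomial data, sigma-hat ~ 0 and AIC prefers (p,1) over (p,2)."""
        rng = np.random.default_rng(5)
        cfg = sp.default_config(
            seed=5,
            spec=sp.ModelSpec(tuple(sp.term(t) for t in ["1", "titv"])),
            beta=(2.0, 1.5),
            gamma=(-12.0,),  # sigma ~ 6e-6: indistinguishable from Binomial
            n_obs=300,
            n_range=(500, 2000),
        )
        tab = sp.simulate_training_table(cfg)
        spec1 = sp.ModelSpec(tuple(sp.term(t) for t in ["1", "titv"]))
        spec2 = sp.ModelSpec(
            tuple(sp.term(t) for t in ["1", "titv"]),
            tuple(sp.term(t) for t in ["1", "titv"]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = sp.fit(tab, spec1)
            m2 = sp.fit(tab, spec2)
        assert np.exp(m1.gamma_coef[0]) < 1e-4
        assert m1.aic < m2.aic

    def test_loglik_is_local_maximum(self, default_table, m116_model):
        from snvppv.betabinom import _nll_grad
        from snvppv.design import build_design

        dm = build_design(default_table, m116_model.spec)
        y = default_table["y"].to_numpy(float)
        n = default_table["n"].to_numpy(float)
        theta = np.concatenate([m116_model.beta_coef, m116_model.gamma_coef])
        f0, _ = _nll_grad(theta, y, n, dm.X, dm.Z, "log", None)
        rng = np.random.default_rng(0)
        scales = np.maximum(np.abs(theta), 1e-3)
        for _ in range(20):
            pert = theta + rng.normal(scale=0.02) * scales * rng.normal(size=len(theta))
            f1, _ = _nll_grad(pert, y, n, dm.X, dm.Z, "log", None)
            assert f1 >= f0 - 1e-6

    def test_rank_deficiency_names_terms(self, default_table):
        tab = default_table.copy()
        tab["dp_lt5"] = 0.25  # constant column: collinear with the intercept
        with pytest.raises(sp.ConvergenceError, match="collinear"):
            sp.fit(tab, sp.named_spec("m11_1"))

    def test_too_few_observations_rejected(self, default_table):
        with pytest.raises(ValueError, match="observations"):
            sp.fit(default_table.head(10), sp.named_spec("m11_6"))


class TestAkaikeWeight:
    def test_printed_aic_pair(self):
        w = sp.akaike_weight([7219.47, 7230.74])
        assert w[0] == pytest.approx(0.9964, abs=2e-4)
        assert w[1] == pytest.approx(0.0036, abs=2e-4)

    def test_equal_aics_split_evenly(self):
        np.testing.assert_allclose(sp.akaike_weight([100.0, 100.0]), [0.5, 0.5])

    @given(st.lists(st.floats(0, 5000), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_weights_sum_to_one(self, aics):
        assert sp.akaike_weight(aics).sum() == pytest.approx(1.0)
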