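"""Density, normalizer and sampler checks against independent oracles.

Oracles: scipy's own hyp1f1/quadrature (different code paths from the
log-space series implemented here), closed forms for the 3-D vMF
normalizer, and Monte-Carlo / 1-D reduced quadrature on the sphere.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.special import gammaln, hyp1f1, ive

from methclust.distributions import (
    BetaShape,
    GammaShapeRate,
    VmfParams,
    WatsonParams,
    beta_logpdf,
    gamma_logpdf,
    log_kummer_1f1,
    vmf_log_normalizer,
    vmf_logpdf,
    watson_logpdf,
    sample_vmf,
    sample_watson,
    sample_uniform_sphere,
)


class TestBetaGamma:
    def test_uniform_beta_is_flat(self):
        assert beta_logpdf(0.3, BetaShape(1, 1)) == pytest.approx(0.0)

    def test_symmetric_beta_value(self):
        # ln(Gamma(10)/(Gamma(5)^2) * 0.5^8), frozen from a log-gamma evaluation
        assert beta_logpdf(0.5, BetaShape(5, 5)) == pytest.approx(0.9005424, abs=1e-6)

    @given(x=st.floats(0.01, 0.99), u=st.floats(0.1, 50), v=st.floats(0.1, 50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_reflection_symmetry(self, x, u, v):
        assert beta_logpdf(x, BetaShape(u, v)) == pytest.approx(
            beta_logpdf(1.0 - x, BetaShape(v, u)), rel=1e-9, abs=1e-9
        )

    def test_beta_domain_errors(self):
        with pytest.raises(ValueError):
            beta_logpdf(0.0, BetaShape(2, 2))
        with pytest.raises(ValueError):
            BetaShape(-1, 2)

    def test_gamma_exponential_case(self):
        assert gamma_logpdf(1.0, GammaShapeRate(1, 1)) == pytest.approx(-1.0)

    def test_gamma_value(self):
        # k ln(theta) - lnGamma(k) + (k-1) ln x - theta x at (2, 3, 1.5), frozen
        assert gamma_logpdf(2.0, GammaShapeRate(3, 1.5)) == pytest.approx(-1.090457, abs=1e-6)

    def test_gamma_normalizes(self):
        par = GammaShapeRate(2, 1)
        val, _ = integrate.quad(lambda x: np.exp(gamma_logpdf(x, par)), 1e-12, 50)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_gamma_domain_error(self):
        with pytest.raises(ValueError):
            gamma_logpdf(-1.0, GammaShapeRate(1, 1))


class TestKummer:
    def test_zero_argument(self):
        assert log_kummer_1f1(0.5, 1.5, 0.0) == 0.0

    def test_r_equals_p_collapses_to_exp(self):
        assert log_kummer_1f1(2.0, 2.0, 3.0) == pytest.approx(3.0, abs=1e-12)

    @pytest.mark.parametrize("r,p,k", [
        (0.5, 1.5, 10), (0.5, 1.5, -10), (0.5, 2.0, 400), (0.5, 1.5, 500),
        (0.5, 2.5, -500), (1.5, 2.5, 40), (0.5, 1.0, 4),
    ])
    def test_matches_scipy(self, r, p, k):
        assert log_kummer_1f1(r, p, k) == pytest.approx(np.log(hyp1f1(r, p, k)), rel=1e-10)

    def test_kummer_transformation(self):
        lhs = log_kummer_1f1(0.5, 1.5, 10.0)
        rhs = 10.0 + log_kummer_1f1(1.0, 1.5, -10.0)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            log_kummer_1f1(0.5, -1.0, 3.0)


class TestVmf:
    def test_uniform_limit_is_reciprocal_sphere_area(self):
        assert vmf_log_normalizer(3, 0.0) == pytest.approx(np.log(1 / (4 * np.pi)))

    def test_closed_form_K3(self):
        # c_3(lam) = lam / (4 pi sinh(lam))
        for lam in (0.5, 1.0, 5.0):
            expect = np.log(lam / (4 * np.pi * np.sinh(lam)))
            assert vmf_log_normalizer(3, lam) == pytest.approx(expect, rel=1e-10)

    def test_no_overflow_at_400(self):
        assert np.isfinite(vmf_log_normalizer(3, 400.0))
        assert np.isfinite(vmf_log_normalizer(14, 1000.0))

    @pytest.mark.parametrize("K", [3, 4, 5])
    @pytest.mark.parametrize("lam", [0.0, 4.0, 40.0, 400.0])
    def test_density_integrates_to_one(self, K, lam, sphere_integral):
        logc = vmf_log_normalizer(K, lam)
        total = sphere_integral(lambda t: logc + lam * t, K)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_logpdf_difference_at_antipodes(self):
        mu = np.array([0.0, 0.0, 1.0])
        par = VmfParams(mu, 7.0)
        assert vmf_logpdf(mu, par) - vmf_logpdf(-mu, par) == pytest.approx(14.0)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            vmf_logpdf(np.array([1.0, 1.0, 1.0]), VmfParams(np.eye(3)[0], 1.0))


class TestWatson:
    @pytest.mark.parametrize("p", [3, 4])
    @pytest.mark.parametrize("kappa", [-400.0, -40.0, -4.0, 0.0, 4.0, 40.0, 400.0])
    def test_density_integrates_to_one(self, p, kappa, sphere_integral):
        from methclust.distributions import watson_log_normalizer

        logc = watson_log_normalizer(p, kappa)
        total = sphere_integral(lambda t: logc + kappa * t**2, p)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_uniform_at_zero_concentration(self):
        par = WatsonParams(np.array([0.0, 0.0, 1.0]), 0.0)
        x = sample_uniform_sphere(3, 5, np.random.default_rng(0))
        np.testing.assert_allclose(watson_logpdf(x, par), np.log(1 / (4 * np.pi)))

    def test_axial_symmetry_bitwise(self):
        rng = np.random.default_rng(1)
        x = sample_uniform_sphere(4, 100, rng)
        par = WatsonParams(np.eye(4)[1], 23.0)
        assert np.array_equal(watson_logpdf(x, par), watson_logpdf(-x, par))

    def test_finite_across_extreme_parameters(self):
        for kappa in (-500.0, -40.0, 40.0, 500.0):
            par = WatsonParams(np.eye(3)[0], kappa)
            assert np.isfinite(watson_logpdf(np.eye(3)[2], par))


class TestSamplers:
    def test_vmf_samples_unit_norm(self):
        x = sample_vmf(VmfParams(np.eye(3)[2], 40.0), 500, seed=0)
        np.testing.assert_allclose(np.linalg.norm(x, axis=1), 1.0, atol=1e-10)

    def test_vmf_high_concentration_mean_direction(self):
        mu = np.array([0.0, 0.0, 1.0])
        x = sample_vmf(VmfParams(mu, 400.0), 10_000, seed=1)
        mean_dir = x.mean(axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        angle = np.degrees(np.arccos(np.clip(mean_dir @ mu, -1, 1)))
        assert angle < 1.0

    @pytest.mark.parametrize("K,lam", [(3, 40.0), (5, 40.0)])
    def test_vmf_mean_projection_matches_bessel_ratio(self, K, lam):
        mu = np.eye(K)[0]
        x = sample_vmf(VmfParams(mu, lam), 20_000, seed=2)
        expect = ive(K / 2.0, lam) / ive(K / 2.0 - 1.0, lam)
        assert (x @ mu).mean() == pytest.approx(expect, abs=0.01)

    def test_vmf_reproducible(self):
        a = sample_vmf(VmfParams(np.eye(3)[0], 10.0), 50, seed=5)
        b = sample_vmf(VmfParams(np.eye(3)[0], 10.0), 50, seed=5)
        assert np.array_equal(a, b)

    def test_watson_samples_unit_norm_and_concentrated(self):
        mu = np.array([0.0, 0.0, 1.0])
        x = sample_watson(WatsonParams(mu, 40.0), 10_000, seed=3)
        np.testing.assert_allclose(np.linalg.norm(x, axis=1), 1.0, atol=1e-10)
        assert ((x @ mu) ** 2).mean() > 0.9

    def test_watson_girdle_concentrates_off_axis(self):
        mu = np.array([0.0, 0.0, 1.0])
        x = sample_watson(WatsonParams(mu, -40.0), 5_000, seed=4)
        assert ((x @ mu) ** 2).mean() < 0.05

    def test_watson_squared_projection_distribution(self):
        # KS test of s = (mu.x)^2 against its analytic CDF at kappa=4, p=3
        from scipy.stats import kstest

        kappa, p = 4.0, 3
        mu = np.eye(p)[0]
        x = sample_watson(WatsonParams(mu, kappa), 10_000, seed=6)
        s_obs = (x @ mu) ** 2

        grid = np.linspace(0, 1, 2001)
        with np.errstate(divide="ignore"):
            pdf = grid ** (-0.5) * (1 - grid) ** ((p - 3) / 2.0) * np.exp(kappa * grid)
        pdf[0] = 0.0
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]

        stat, pval = kstest(s_obs, lambda q: np.interp(q, grid, cdf))
        assert pval > 0.01
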