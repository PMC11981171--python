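"""Density, sampler and compound-oracle checks for the mixing distributions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from nblcrash.distributions import (
    GEParams,
    LindleyParams,
    ParameterDomainError,
    ge_mean,
    ge_pdf,
    ge_sample,
    lindley_mean,
    lindley_pdf,
    lindley_sample,
    lindley_var,
    nb_logpmf,
    nb_pmf,
    nbge_pmf_oracle,
    nbl_pmf_oracle,
)

positive = st.floats(min_value=0.05, max_value=20.0, allow_nan=False)


class TestLindley:
    @pytest.mark.parametrize("tau, theta, expected", [
        (0.0, 2.0, 4.0 / 3.0),
        (0.0, 1.0, 0.5),
    ])
    def test_pdf_closed_form_values(self, tau, theta, expected):
        assert lindley_pdf(tau, LindleyParams(theta)) == pytest.approx(expected)

    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0, 5.0])
    def test_pdf_normalizes(self, theta):
        total, err = integrate.quad(lambda t: lindley_pdf(t, theta), 0, 50)
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0, 5.0])
    def test_sampler_mean_matches_closed_form(self, theta):
        n = 200_000
        draws = lindley_sample(LindleyParams(theta), n, seed=42)
        se = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - lindley_mean(theta)) < 3 * se

    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0, 5.0])
    def test_mixture_sampler_vs_inverse_cdf(self, theta):
        """KS distance between mixture draws and numeric-inverse-CDF draws."""
        n = 100_000
        mix = lindley_sample(theta, n, seed=7)
        # independent oracle: invert the numeric CDF built from the pdf
        grid = np.linspace(0, 60.0 / theta, 40_000)
        cdf = np.concatenate([[0.0], integrate.cumulative_trapezoid(
            lindley_pdf(grid, theta), grid)])
        cdf /= cdf[-1]
        u = np.random.default_rng(8).random(n)
        inv = np.interp(u, cdf, grid)
        ks = stats.ks_2samp(mix, inv).statistic
        assert ks < 0.01

    def test_sampler_deterministic(self):
        a = lindley_sample(1.5, 100, seed=3)
        b = lindley_sample(1.5, 100, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_empirical_density_matches_pdf(self):
        """Binned empirical density tracks the exact bin-averaged pdf."""
        theta = 2.0
        width = 0.2
        draws = lindley_sample(theta, 1_000_000, seed=5)
        edges = np.arange(0.0, 6.0 + 1e-9, width)
        hist, _ = np.histogram(draws, bins=edges)
        empirical = hist / draws.size / width
        # closed-form Lindley CDF: 1 - (1 + theta*t/(theta+1)) exp(-theta t)
        cdf = 1.0 - (1.0 + theta * edges / (theta + 1.0)) * np.exp(-theta * edges)
        expected = np.diff(cdf) / width
        sup = np.max(np.abs(empirical - expected))
        assert sup < 0.01

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan])
    def test_invalid_theta_rejected(self, bad):
        with pytest.raises(ParameterDomainError):
            lindley_pdf(1.0, bad)

    def test_negative_tau_rejected(self):
        with pytest.raises(ParameterDomainError):
            lindley_pdf(-0.1, 1.0)


class TestGeneralizedExponential:
    def test_shape_one_is_exponential_pointwise(self):
        lam = np.linspace(0, 20, 200)
        for omega in (0.5, 1.0, 2.0):
            np.testing.assert_allclose(
                ge_pdf(lam, GEParams(omega, 1.0)),
                omega * np.exp(-omega * lam), atol=1e-12)

    def test_density_at_zero_shape_one(self):
        assert ge_pdf(0.0, GEParams(2.0, 1.0)) == pytest.approx(2.0)

    @pytest.mark.parametrize("omega", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("v", [0.5, 1.0, 3.0])
    def test_pdf_normalizes(self, omega, v):
        total, _ = integrate.quad(lambda t: ge_pdf(t, (omega, v)), 0, 100 / omega,
                                  limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_sampler_mean_exponential_case(self):
        draws = ge_sample(GEParams(1.0, 1.0), 200_000, seed=11)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.0) < 3 * se

    def test_sampler_mean_matches_quadrature(self):
        omega, v = 2.0, 3.0
        mean_quad, _ = integrate.quad(lambda t: t * ge_pdf(t, (omega, v)), 0, 50)
        draws = ge_sample((omega, v), 200_000, seed=12)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - mean_quad) < 3 * se
        assert ge_mean(omega, v) == pytest.approx(mean_quad, abs=1e-8)

    def test_sampler_deterministic(self):
        np.testing.assert_array_equal(ge_sample((2.0, 3.0), 50, seed=1),
                                      ge_sample((2.0, 3.0), 50, seed=1))

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterDomainError):
            ge_pdf(1.0, (0.0, 1.0))
        with pytest.raises(ParameterDomainError):
            ge_sample((1.0, -2.0), 10, seed=0)


class TestNBKernel:
    def test_simple_value(self):
        assert nb_pmf(0, (1.0, 1.0)) == pytest.approx(0.5)

    def test_matches_scipy_nbinom(self):
        """Independent cross-check against scipy's NB parameterization."""
        y = np.arange(0, 60)
        for eta, alpha in [(5.0, 0.5), (0.3, 2.0), (12.0, 0.1)]:
            r = 1.0 / alpha
            expected = stats.nbinom.logpmf(y, r, r / (r + eta))
            np.testing.assert_allclose(nb_logpmf(y, eta, alpha), expected, rtol=1e-10)

    def test_mass_sums_to_one(self):
        y = np.arange(0, 2001)
        assert nb_pmf(y, (5.0, 0.5)).sum() == pytest.approx(1.0, abs=1e-10)

    def test_mean_equals_eta(self):
        y = np.arange(0, 4001)
        mean = float((y * nb_pmf(y, (3.0, 2.0))).sum())
        assert mean == pytest.approx(3.0, abs=1e-8)

    def test_negative_count_rejected(self):
        with pytest.raises(ParameterDomainError):
            nb_pmf(-1, (1.0, 1.0))

    @given(eta=positive, alpha=positive, y=st.integers(min_value=0, max_value=200))
    def test_logpmf_is_log_of_probability(self, eta, alpha, y):
        lp = float(nb_logpmf(y, eta, alpha))
        assert lp <= 1e-12 and np.isfinite(lp)


class TestCompoundOracles:
    def test_nbl_total_mass(self):
        total = sum(nbl_pmf_oracle(y, 2.0, 1.0, 1.0) for y in range(0, 400))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nbl_mean_law_of_total_expectation(self):
        lam, theta = 2.0, 1.0
        mean = sum(y * nbl_pmf_oracle(y, lam, theta, 1.0) for y in range(0, 600))
        assert mean == pytest.approx(lam * lindley_mean(theta), abs=1e-5)

    def test_nbl_monte_carlo_cross_check(self):
        lam, theta, alpha = 2.0, 1.0, 1.0
        tau = lindley_sample(theta, 1_000_000, seed=21)
        vals = nb_pmf(0, (tau * lam, alpha))
        mc, se = vals.mean(), vals.std() / np.sqrt(vals.size)
        assert abs(mc - nbl_pmf_oracle(0, lam, theta, alpha)) < 3 * se

    def test_nbge_total_mass(self):
        total = sum(nbge_pmf_oracle(y, 2.0, (1.0, 1.0), 1.0) for y in range(0, 500))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nbge_monte_carlo_cross_check(self):
        """v=1 reduces to the NB-Exponential mixture; MC sampler agrees."""
        lam, omega, alpha = 2.0, 1.0, 1.0
        Lam = ge_sample((omega, 1.0), 500_000, seed=22)
        for y in (0, 3):
            vals = nb_pmf(y, (lam * Lam, alpha))
            mc, se = vals.mean(), vals.std() / np.sqrt(vals.size)
            assert abs(mc - nbge_pmf_oracle(y, lam, (omega, 1.0), alpha)) < 3 * se

    def test_nbge_zero_mass_tends_to_one_for_vanishing_mean(self):
        assert nbge_pmf_oracle(0, 1e-9, (1.0, 1.0), 1.0) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("alpha", [0.5, 1.0])
    def test_excess_zero_mass_beats_plain_nb(self, theta, alpha):
        """At matched mean 0.75, the Lindley mixture carries more zero mass."""
        target_mean = 0.75
        lam = target_mean / lindley_mean(theta)
        assert nbl_pmf_oracle(0, lam, theta, alpha) >= float(nb_pmf(0, (target_mean, alpha)))


class TestMoments:
    def test_lindley_variance_closed_form_matches_quadrature(self):
        theta = 1.7
        m2, _ = integrate.quad(lambda t: t * t * lindley_pdf(t, theta), 0, 80)
        assert lindley_var(theta) == pytest.approx(m2 - lindley_mean(theta) ** 2, abs=1e-9)
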