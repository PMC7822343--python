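"""Closed-form distribution functions against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import logbilal as lb
from logbilal.distribution import UnitSample, hrf_shape_diagnostic

from conftest import oracle_cdf, oracle_pdf, oracle_quantile, sample_bilal_parent

THETA_GRID = np.geomspace(0.05, 50.0, 9)
Y_GRID = np.linspace(0.01, 0.99, 25)


class TestClosedForms:
    def test_pdf_at_theta_one_is_beta22(self):
        y = np.linspace(1e-6, 1 - 1e-6, 501)
        np.testing.assert_allclose(lb.pdf(y, 1.0), 6.0 * y * (1.0 - y), rtol=1e-13)

    def test_pdf_value_half(self):
        assert lb.pdf(0.5, 1.0) == pytest.approx(1.5, rel=1e-14)

    @pytest.mark.parametrize("theta", [0.3, 1.0, 1.7, 4.7063])
    def test_pdf_normalizes(self, theta):
        total, err = integrate.quad(lambda y: lb.pdf(y, theta), 0.0, 1.0)
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("theta", THETA_GRID)
    def test_pdf_normalizes_extreme_shapes(self, theta):
        total, _ = integrate.quad(
            lambda y: lb.pdf(y, theta), 0.0, 1.0, points=[1e-6, 1 - 1e-6], limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("theta", [0.3, 1.7, 4.7063])
    def test_pdf_cdf_quantile_match_beta_power_oracle(self, theta):
        np.testing.assert_allclose(lb.pdf(Y_GRID, theta), oracle_pdf(Y_GRID, theta), rtol=1e-10)
        np.testing.assert_allclose(lb.cdf(Y_GRID, theta), oracle_cdf(Y_GRID, theta), rtol=1e-10)
        u = np.linspace(0.02, 0.98, 21)
        np.testing.assert_allclose(
            lb.quantile(u, theta), oracle_quantile(u, theta), rtol=1e-9
        )

    def test_pdf_is_derivative_of_cdf(self):
        y, theta, h = 0.1, 4.7063, 1e-6
        fd = (lb.cdf(y + h, theta) - lb.cdf(y - h, theta)) / (2 * h)
        assert lb.pdf(y, theta) == pytest.approx(fd, abs=1e-6)

    def test_cdf_against_quadrature(self):
        val, _ = integrate.quad(lambda y: lb.pdf(y, 1.7), 0.0, 0.3)
        assert lb.cdf(0.3, 1.7) == pytest.approx(val, abs=1e-8)

    def test_cdf_boundaries(self):
        for theta in THETA_GRID:
            assert lb.cdf(0.0, theta) == 0.0
            assert lb.cdf(1.0, theta) == 1.0

    def test_logpdf_matches_log_of_pdf(self):
        np.testing.assert_allclose(
            lb.logpdf(Y_GRID, 1.7), np.log(lb.pdf(Y_GRID, 1.7)), rtol=1e-12
        )

    def test_hrf_identity(self):
        y = np.linspace(0.05, 0.95, 19)
        for theta in (0.3, 1.0, 4.0):
            np.testing.assert_allclose(
                lb.hrf(y, theta) * lb.sf(y, theta), lb.pdf(y, theta), rtol=1e-12
            )

    def test_hrf_shape_diagnostic_regimes(self):
        # small theta concentrates mass near 1 -> monotone increasing hazard;
        # large theta pushes mass to 0 and produces a bathtub
        assert hrf_shape_diagnostic(0.3) == "increasing"
        assert hrf_shape_diagnostic(5.0) == "bathtub"

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            lb.pdf(0.0, 1.0)
        with pytest.raises(ValueError):
            lb.pdf(0.5, -1.0)
        with pytest.raises(ValueError):
            lb.quantile(1.0, 1.0)
        with pytest.raises(ValueError):
            lb.cdf(1.5, 1.0)


class TestQuantile:
    def test_median_at_theta_one(self):
        assert lb.quantile(0.5, 1.0) == pytest.approx(0.5, abs=1e-14)

    @pytest.mark.parametrize("theta", THETA_GRID)
    def test_inversion(self, theta):
        u = np.concatenate([[1e-6, 1 - 1e-6], np.linspace(0.01, 0.99, 33)])
        np.testing.assert_allclose(lb.cdf(lb.quantile(u, theta), theta), u, atol=1e-10)

    def test_quantile_agrees_with_bisection(self):
        u, theta = 0.25, 1.7
        from scipy.optimize import brentq

        root = brentq(lambda y: lb.cdf(y, theta) - u, 1e-12, 1 - 1e-12, xtol=1e-14)
        assert lb.quantile(u, theta) == pytest.approx(root, abs=1e-10)

    def test_limits(self):
        assert lb.quantile(1e-12, 1.7) < 1e-6
        assert lb.quantile(1 - 1e-12, 1.7) > 1 - 1e-3

    @settings(derandomize=True, max_examples=50)
    @given(
        u1=st.floats(1e-6, 1 - 1e-6),
        u2=st.floats(1e-6, 1 - 1e-6),
        theta=st.floats(0.05, 50.0),
    )
    def test_strictly_increasing_in_u(self, u1, u2, theta):
        if u1 == u2:
            return
        lo, hi = sorted((u1, u2))
        assert lb.quantile(lo, theta) < lb.quantile(hi, theta)


class TestMoments:
    def test_first_moments_at_theta_one(self):
        assert lb.raw_moment(1, 1.0) == pytest.approx(0.5)
        assert lb.raw_moment(2, 1.0) == pytest.approx(0.3)
        assert lb.variance(1.0) == pytest.approx(0.05)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    @pytest.mark.parametrize("theta", [0.3, 1.7, 4.7063])
    def test_raw_moments_match_quadrature(self, k, theta):
        val, _ = integrate.quad(lambda y: y**k * lb.pdf(y, theta), 0.0, 1.0)
        assert lb.raw_moment(k, theta) == pytest.approx(val, abs=1e-8)

    def test_variance_closed_form_is_moment_difference(self):
        for theta in THETA_GRID:
            direct = lb.raw_moment(2, theta) - lb.raw_moment(1, theta) ** 2
            np.testing.assert_allclose(lb.variance(theta), direct, rtol=1e-12)

    def test_mean_decreases_in_theta(self):
        grid = np.geomspace(0.05, 50.0, 40)
        assert np.all(np.diff(lb.mean(grid)) < 0)

    def test_variance_is_unimodal_in_theta(self):
        # the variance rises from 0, peaks near theta ~ 1.55, then falls;
        # it is monotone decreasing only beyond the mode
        grid = np.geomspace(0.05, 50.0, 200)
        v = lb.variance(grid)
        peak = int(np.argmax(v))
        assert 1.0 < grid[peak] < 2.0
        assert np.all(np.diff(v[: peak + 1]) > 0)
        assert np.all(np.diff(v[peak:]) < 0)

    def test_incomplete_moment_examples(self):
        assert lb.incomplete_moment(1, 1.0, 1.7) == pytest.approx(lb.raw_moment(1, 1.7))
        assert lb.incomplete_moment(1, 0.5, 1.0) == pytest.approx(0.15625, rel=1e-12)

    @pytest.mark.parametrize("r,t,theta", [(2, 0.3, 1.7), (1, 0.8, 0.5), (3, 0.6, 4.0)])
    def test_incomplete_moment_matches_truncated_quadrature(self, r, t, theta):
        val, _ = integrate.quad(lambda y: y**r * lb.pdf(y, theta), 0.0, t)
        assert lb.incomplete_moment(r, t, theta) == pytest.approx(val, abs=1e-8)

    def test_incomplete_moment_monotone_in_t(self):
        t = np.linspace(0.05, 1.0, 30)
        assert np.all(np.diff(lb.incomplete_moment(1, t, 1.7)) >= 0)


class TestMeanReparametrization:
    def test_mu_half_maps_to_theta_one(self):
        assert lb.theta_from_mu(0.5) == pytest.approx(1.0, rel=1e-14)

    @pytest.mark.parametrize("mu", [0.01, 0.5, 0.99])
    def test_roundtrip(self, mu):
        assert lb.mu_from_theta(lb.theta_from_mu(mu)) == pytest.approx(mu, rel=1e-12)

    def test_mu_at_fitted_shape(self):
        theta = 4.7063
        assert lb.mu_from_theta(theta) == pytest.approx(6.0 / (6.7063 * 7.7063), rel=1e-12)
        quad_mean, _ = integrate.quad(lambda y: y * lb.pdf(y, theta), 0.0, 1.0)
        assert lb.mu_from_theta(theta) == pytest.approx(quad_mean, abs=1e-8)


class TestExponentialFamily:
    @pytest.mark.parametrize("theta", [1.0, 1.7])
    def test_recomposition_equals_pdf(self, theta):
        comp = lb.expfam_components(theta)
        y = np.linspace(0.005, 0.995, 100)
        recomposed = np.exp(comp["Q"] * comp["T"](y) + comp["D"] + comp["S"](y))
        np.testing.assert_allclose(recomposed, lb.pdf(y, theta), rtol=1e-12)
        assert np.exp(comp["Q"] * comp["T"](0.5) + comp["D"] + comp["S"](0.5)) == pytest.approx(
            lb.pdf(0.5, theta)
        )

    def test_sufficient_statistic_drives_likelihood(self, rng):
        # two samples with equal sum(log y) and equal sum(log(1-y^(1/theta)))
        # terms differ only through those sums; check T is sum of logs
        y = lb.sample(40, 1.7, seed=5).values
        comp = lb.expfam_components(1.7)
        assert np.sum(comp["T"](y)) == pytest.approx(np.sum(np.log(y)), rel=1e-14)


class TestSampling:
    def test_same_seed_identical(self):
        a = lb.sample(1000, 1.7, seed=42).values
        b = lb.sample(1000, 1.7, seed=42).values
        np.testing.assert_array_equal(a, b)

    def test_mean_at_theta_one(self):
        y = lb.sample(1_000_000, 1.0, seed=11).values
        sd = y.std()
        assert abs(y.mean() - 0.5) < 3 * sd / 1000.0

    def test_ks_self_consistency(self):
        y = lb.sample(100_000, 1.7, seed=13).values
        d = stats.kstest(y, lambda v: lb.cdf(v, 1.7)).statistic
        assert d < 1.63 / np.sqrt(y.size)  # 1% critical value

    def test_exp_of_bilal_parent_matches_cdf(self, rng):
        # X = median of three exponentials is the Bilal parent; exp(-X)
        # must follow the log-Bilal law
        theta = 1.7
        x = sample_bilal_parent(100_000, theta, rng)
        y = np.exp(-x)
        d = stats.kstest(y, lambda v: lb.cdf(v, theta)).statistic
        assert d < 1.63 / np.sqrt(y.size)


class TestUnitSample:
    def test_rejects_boundaries(self):
        with pytest.raises(ValueError, match="rejected"):
            UnitSample([0.2, 1.0, 0.4])
        with pytest.raises(ValueError):
            UnitSample([0.0])
        with pytest.raises(ValueError):
            UnitSample([])

    def test_counts(self):
        s = UnitSample([0.2, 0.4])
        assert s.n == len(s) == 2
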