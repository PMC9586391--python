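"""Core distribution functions: exact values, identities, stability, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

from olinh.distribution import (
    InhParams,
    ObservationSet,
    OlinhParams,
    inh_cdf,
    inh_pdf,
    olg_cdf,
    olinh_cdf,
    olinh_hazard,
    olinh_logpdf,
    olinh_logsf,
    olinh_orf,
    olinh_pdf,
    olinh_quantile,
    olinh_rvs,
    olinh_sf,
)

XGRID = np.logspace(-2, 2, 50)


class TestValidation:
    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan])
    def test_inh_params_reject_nonpositive(self, bad):
        with pytest.raises(ValueError):
            InhParams(bad, 1.0)
        with pytest.raises(ValueError):
            InhParams(1.0, bad)

    def test_olinh_params_reject_nonpositive(self):
        with pytest.raises(ValueError):
            OlinhParams(1.0, -2.0, 1.0, 1.0)

    def test_olinh_params_compose_baseline(self):
        w = OlinhParams(1.0, 2.0, 3.0, 4.0)
        assert w.baseline == InhParams(3.0, 4.0)

    @pytest.mark.parametrize("values", [[], [1.0, -2.0], [0.0], [np.nan], [np.inf]])
    def test_observation_set_rejects(self, values):
        with pytest.raises(ValueError):
            ObservationSet(values)

    def test_pdf_domain_error(self, w_std):
        with pytest.raises(ValueError):
            olinh_pdf(-1.0, w_std)
        with pytest.raises(ValueError):
            olinh_pdf(0.0, w_std)


class TestInhBaseline:
    def test_point_value(self):
        # G(1; 1, 1) = exp(1 - 2) = e^-1, and the pdf coincides there
        p = InhParams(1.0, 1.0)
        assert inh_cdf(1.0, p) == pytest.approx(np.exp(-1), rel=1e-12)
        assert inh_pdf(1.0, p) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_limits(self):
        p = InhParams(2.0, 0.7)
        assert inh_cdf(0.0, p) == 0.0
        assert inh_cdf(np.inf, p) == 1.0

    def test_pdf_is_cdf_derivative(self):
        p = InhParams(1.5, 0.8)
        h = 1e-5
        num = (inh_cdf(2 + h, p) - inh_cdf(2 - h, p)) / (2 * h)
        assert inh_pdf(2.0, p) == pytest.approx(num, rel=1e-6)

    def test_pdf_normalises(self):
        p = InhParams(1.5, 1.5)
        total, _ = integrate.quad(lambda x: inh_pdf(x, p), 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)


class TestOlgTransform:
    def test_identity_at_unit_shapes(self):
        g = np.linspace(0, 0.99, 25)
        assert np.allclose(olg_cdf(g, 1.0, 1.0), g, atol=1e-14)

    def test_anchors(self):
        assert olg_cdf(0.0, 3.0, 2.0) == 0.0
        assert olg_cdf(0.5, 2.0, 1.0) == pytest.approx(0.75, rel=1e-12)
        assert olg_cdf(1.0, 2.0, 1.0) == 1.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            olg_cdf(1.2, 1.0, 1.0)


class TestOlinhIdentities:
    def test_family_reduction_to_inh(self):
        """alpha = beta = 1 collapses the transform exactly."""
        w = OlinhParams(1.0, 1.0, 1.5, 1.5)
        base = InhParams(1.5, 1.5)
        assert np.allclose(olinh_cdf(XGRID, w), inh_cdf(XGRID, base), atol=1e-12)
        assert np.allclose(olinh_pdf(XGRID, w),
                           [inh_pdf(x, base) for x in XGRID], rtol=1e-12)

    @pytest.mark.parametrize("w", [
        OlinhParams(1.25, 1.5, 1.5, 1.5),
        OlinhParams(0.5, 2.0, 1.0, 3.0),
        OlinhParams(2.0, 0.5, 1.0, 1.0),
        OlinhParams(5.0, 1.0, 0.5, 2.0),
        OlinhParams(9.0385, 1.8521, 716.7624, 0.2115),
    ])
    def test_pdf_normalises(self, w):
        med = olinh_quantile(0.5, w)
        lo, _ = integrate.quad(lambda x: olinh_pdf(x, w), 0, med, limit=200)
        hi, _ = integrate.quad(lambda x: olinh_pdf(x, w), med, np.inf, limit=200)
        assert lo + hi == pytest.approx(1.0, abs=1e-6)

    def test_pdf_is_cdf_derivative(self, w_std):
        h = 1e-5
        num = (olinh_cdf(5 + h, w_std) - olinh_cdf(5 - h, w_std)) / (2 * h)
        assert olinh_pdf(5.0, w_std) == pytest.approx(num, rel=1e-6)

    def test_logpdf_consistent_and_stable(self, w_std):
        assert np.exp(olinh_logpdf(1.0, w_std)) == pytest.approx(
            olinh_pdf(1.0, w_std), rel=1e-12)
        # right tail: baseline CDF -> 1, naive form cancels
        assert np.isfinite(olinh_logpdf(1e6, w_std))
        # left tail: exponent ~ -1.8e6, naive exp underflows
        assert np.isfinite(olinh_logpdf(1e-4, w_std))
        # check the right-tail value against the power-law asymptote
        # f(x) ~ alpha * beta^alpha * (theta*delta)^alpha * x^(-alpha-1)
        a, b, d, t = w_std.alpha, w_std.beta, w_std.delta, w_std.theta
        asym = np.log(a) + a * np.log(b * t * d) - (a + 1) * np.log(1e6)
        assert olinh_logpdf(1e6, w_std) == pytest.approx(asym, rel=1e-3)

    def test_sf_complementarity_and_hazard(self):
        w = OlinhParams(0.5, 2.0, 1.0, 3.0)
        grid = np.linspace(0.05, 20, 50)
        assert olinh_sf(0.5, w) + olinh_cdf(0.5, w) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(olinh_hazard(grid, w),
                           olinh_pdf(grid, w) / olinh_sf(grid, w), rtol=1e-10)

    def test_cumulative_hazard_identity(self, w_std):
        total, _ = integrate.quad(lambda t: olinh_hazard(t, w_std), 1e-12, 2.0,
                                  limit=200)
        assert total == pytest.approx(-olinh_logsf(2.0, w_std), rel=1e-7)

    def test_orf_identities(self):
        w = OlinhParams(2.0, 0.5, 1.0, 1.0)
        grid = np.linspace(0.05, 20, 50)
        assert np.allclose(olinh_orf(grid, w),
                           olinh_cdf(grid, w) / olinh_sf(grid, w), rtol=1e-10)
        assert olinh_orf(1e-8, w) < 1e-6
        med = olinh_quantile(0.5, w)
        assert olinh_orf(med, w) == pytest.approx(1.0, rel=1e-9)

    def test_tail_law(self, w_std):
        """sf(x) * x^alpha -> beta^alpha (theta*delta)^alpha."""
        a = w_std.alpha
        limit = (w_std.beta * w_std.theta * w_std.delta) ** a
        x = np.array([1e4, 1e5, 1e6])
        ratio = olinh_sf(x, w_std) * x ** a / limit
        assert np.all(np.abs(ratio - 1) < 0.01)
        # and the convergence is monotone toward 1
        assert np.all(np.diff(np.abs(ratio - 1)) < 0)


class TestQuantile:
    def test_round_trip(self, w_std):
        q = np.array([0.01, 0.25, 0.5, 0.75, 0.99])
        assert np.allclose(olinh_cdf(olinh_quantile(q, w_std), w_std), q,
                           atol=1e-9)

    def test_round_trip_wide(self, w_std):
        q = np.linspace(0.001, 0.999, 200)
        assert np.allclose(olinh_cdf(olinh_quantile(q, w_std), w_std), q,
                           atol=1e-9)

    def test_reduces_to_inh_quantile(self):
        w = OlinhParams(1.0, 1.0, 2.0, 0.7)
        for q in (0.1, 0.5, 0.9):
            closed = w.delta / ((1 - np.log(q)) ** (1 / w.theta) - 1)
            assert olinh_quantile(q, w) == pytest.approx(closed, rel=1e-12)
            root = optimize.brentq(
                lambda x: inh_cdf(x, InhParams(2.0, 0.7)) - q, 1e-8, 1e8,
                xtol=1e-12, rtol=1e-14)
            assert closed == pytest.approx(root, rel=1e-8)

    def test_median_matches_bisection(self):
        w = OlinhParams(2.0, 1.0, 1.0, 1.0)
        root = optimize.brentq(lambda x: olinh_cdf(x, w) - 0.5, 1e-8, 1e8,
                               xtol=1e-14, rtol=1e-15)
        assert olinh_quantile(0.5, w) == pytest.approx(root, rel=1e-8)

    def test_monotone_in_q(self, w_std):
        q = np.linspace(0.001, 0.999, 400)
        assert np.all(np.diff(olinh_quantile(q, w_std)) > 0)

    def test_domain_error(self, w_std):
        for q in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                olinh_quantile(q, w_std)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(a=st.floats(0.3, 5), b=st.floats(0.3, 5), d=st.floats(0.3, 5),
           t=st.floats(0.3, 5), q=st.floats(0.005, 0.995))
    def test_round_trip_property(self, a, b, d, t, q):
        w = OlinhParams(a, b, d, t)
        assert olinh_cdf(olinh_quantile(q, w), w) == pytest.approx(q, abs=1e-9)


class TestSampling:
    def test_determinism(self, w_std):
        s1 = olinh_rvs(100, w_std, seed=42)
        s2 = olinh_rvs(100, w_std, seed=42)
        assert np.array_equal(s1.values, s2.values)

    def test_positive_and_sized(self, w_std):
        s = olinh_rvs(10, w_std, seed=0)
        assert s.n == 10 and np.all(s.values > 0)
        with pytest.raises(ValueError):
            olinh_rvs(0, w_std, seed=0)

    def test_empirical_cdf_matches(self, w_std):
        n = 10 ** 5
        s = olinh_rvs(n, w_std, seed=7)
        F = olinh_cdf(2.0, w_std)
        emp = np.mean(s.values <= 2.0)
        assert abs(emp - F) < 3 * np.sqrt(F * (1 - F) / n)

    def test_quantile_fraction(self, w_std):
        n = 10 ** 4
        s = olinh_rvs(n, w_std, seed=11)
        q25 = olinh_quantile(0.25, w_std)
        assert abs(np.mean(s.values <= q25) - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)

    def test_ks_self_consistency(self, w_std):
        """Draws pass a KS test against their own CDF in >= 95% of replicates."""
        n, crit = 10 ** 4, 1.63 / np.sqrt(10 ** 4)
        passed = 0
        for seed in range(20):
            s = olinh_rvs(n, w_std, seed=seed)
            d = stats.kstest(s.values, lambda x: olinh_cdf(x, w_std)).statistic
            passed += d < crit
        assert passed >= 19
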