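"""Distribution-level properties: exactness of the closed forms, sub-model
consistency, the compounding construction, and sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import poighl as pg
from poighl import GHLParams, LPoiGHLParams, PoiGHLParams

P111 = PoiGHLParams(1.0, 1.0, 1.0)


class TestCdf:
    def test_lower_endpoint_and_monotonicity(self, param_grid):
        xs = np.linspace(0.0, 30.0, 200)
        for p in param_grid:
            vals = pg.cdf(xs, p)
            assert vals[0] == 0.0
            assert np.all(np.diff(vals) >= -1e-15)
            assert np.all((vals >= 0) & (vals <= 1))

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            pg.cdf(-0.1, P111)
        with pytest.raises(ValueError):
            pg.pdf(np.array([0.5, -1.0]), P111)

    def test_printed_median_small_params(self):
        # the (0.1, 0.1, 0.1) median is 0.0152 to four decimals
        p = PoiGHLParams(0.1, 0.1, 0.1)
        assert pg.cdf(0.0152, p) == pytest.approx(0.5, abs=5e-3)

    def test_cdf_equals_integrated_pdf(self):
        val, _ = integrate.quad(lambda t: pg.pdf(t, P111), 0.0, 1.0,
                                epsabs=1e-12, epsrel=1e-12, limit=200)
        assert pg.cdf(1.0, P111) == pytest.approx(val, abs=1e-10)

    def test_sf_complements_cdf(self, param_grid):
        xs = np.linspace(0.01, 20.0, 60)
        for p in param_grid:
            np.testing.assert_allclose(
                pg.sf(xs, p), 1.0 - np.asarray(pg.cdf(xs, p)), atol=1e-12
            )
            assert pg.sf(0.0, p) == pytest.approx(1.0, abs=1e-14)


class TestPdf:
    @pytest.mark.parametrize("p", [P111, PoiGHLParams(0.5, 3.0, 0.4)])
    def test_normalizes(self, p):
        total = pg.expect(lambda x: np.ones_like(x), p)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_normalization_across_grid(self, param_grid):
        for p in param_grid:
            assert pg.expect(lambda x: 1.0, p) == pytest.approx(1.0, abs=1e-8)

    def test_log_and_plain_agree(self):
        xs = np.linspace(0.05, 8.0, 20)
        for p in (P111, PoiGHLParams(2.0, 0.3, 0.6)):
            np.testing.assert_allclose(
                pg.pdf(xs, p), np.exp(pg.logpdf(xs, p)), rtol=1e-12
            )

    def test_origin_limits(self):
        # a < 1 diverges, a = 1 tends to alpha*lam / (2 (1 - e^-lam)), a > 1 vanishes
        assert pg.pdf(0.0, PoiGHLParams(1.0, 1.0, 0.5)) == np.inf
        lim = 1.0 * 1.0 / (2.0 * (1.0 - np.exp(-1.0)))
        assert pg.pdf(1e-9, P111) == pytest.approx(lim, rel=1e-6)
        assert pg.pdf(0.0, P111) == pytest.approx(lim, rel=1e-12)
        assert pg.pdf(0.0, PoiGHLParams(1.0, 1.0, 2.0)) == 0.0

    def test_large_arguments_do_not_overflow(self):
        p = PoiGHLParams(1.0, 700.0, 1.0)
        assert np.isfinite(pg.logpdf(1.0, p))
        assert np.isfinite(pg.logpdf(700.0, P111))
        assert pg.cdf(700.0, P111) == pytest.approx(1.0)


class TestHazard:
    def test_hrf_is_pdf_over_sf(self):
        xs = np.linspace(0.1, 6.0, 25)
        for p in (P111, PoiGHLParams(0.7, 2.0, 1.8)):
            np.testing.assert_allclose(
                pg.hrf(xs, p) * pg.sf(xs, p), pg.pdf(xs, p), rtol=1e-10
            )

    def test_origin_limit_a_one(self):
        lim = 1.0 / (2.0 * (1.0 - np.exp(-1.0)))
        assert pg.hrf(1e-9, P111) == pytest.approx(lim, rel=1e-6)


class TestQuantile:
    @pytest.mark.parametrize(
        "params, median",
        [((0.1, 0.1, 0.1), 0.0152), ((1.0, 1.2, 1.3), 0.9794)],
    )
    def test_printed_medians(self, params, median):
        assert pg.quantile(0.5, PoiGHLParams(*params)) == pytest.approx(
            median, abs=5e-5
        )

    def test_round_trip(self, param_grid):
        probs = np.concatenate(
            [[1e-4, 1e-3], np.linspace(0.01, 0.99, 25), [1 - 1e-3, 1 - 1e-4]]
        )
        for p in param_grid:
            q = pg.quantile(probs, p)
            assert np.all(np.diff(q) > 0)
            np.testing.assert_allclose(pg.cdf(q, p), probs, atol=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        prob=st.floats(1e-4, 1 - 1e-4),
        alpha=st.floats(0.1, 5.0),
        lam=st.floats(0.05, 8.0),
        a=st.floats(0.2, 4.0),
    )
    def test_round_trip_hypothesis(self, prob, alpha, lam, a):
        p = PoiGHLParams(alpha, lam, a)
        assert pg.cdf(pg.quantile(prob, p), p) == pytest.approx(prob, abs=1e-9)

    def test_domain(self):
        for bad in (0.0, 1.0, -0.3, 1.5):
            with pytest.raises(ValueError):
                pg.quantile(bad, P111)
        assert pg.quantile(1e-12, P111) < 1e-5


class TestSampling:
    def test_reproducible(self):
        a = pg.sample(100, P111, seed=42)
        b = pg.sample(100, P111, seed=42)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, pg.sample(100, P111, seed=43))

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            pg.sample(0, P111, seed=1)

    def test_ks_against_cdf(self):
        xs = pg.sample(10_000, PoiGHLParams(1.0, 2.0, 0.7), seed=5)
        stat = stats.kstest(xs, lambda t: pg.cdf(t, PoiGHLParams(1.0, 2.0, 0.7)))
        assert stat.pvalue > 0.01

    def test_sample_mean_matches_printed_first_moment(self):
        p = PoiGHLParams(1.0, 1.2, 1.3)
        xs = pg.sample(50_000, p, seed=11)
        se = xs.std(ddof=1) / np.sqrt(xs.size)
        assert abs(xs.mean() - 1.2504) < 3 * se

    def test_empirical_cdf_sup_distance_shrinks(self):
        p = PoiGHLParams(0.8, 0.5, 1.5)

        def sup_dist(n, seed):
            xs = np.sort(pg.sample(n, p, seed))
            u = np.asarray(pg.cdf(xs, p))
            i = np.arange(1, n + 1)
            return max(np.max(i / n - u), np.max(u - (i - 1) / n))

        assert sup_dist(100_000, 3) < sup_dist(1_000, 3)
        assert sup_dist(100_000, 3) < 0.01

    def test_change_of_variable_truncated_exponential(self):
        # V = G(X) must follow lam e^{-lam v} / (1 - e^{-lam}) on (0, 1)
        p = PoiGHLParams(0.6, 2.5, 1.7)
        xs = pg.sample(20_000, p, seed=9)
        v = np.tanh(p.alpha * xs / 2.0) ** p.a
        trunc_cdf = lambda t: np.expm1(-p.lam * t) / np.expm1(-p.lam)
        assert stats.kstest(v, trunc_cdf).pvalue > 0.01


class TestQuantileShapeMeasures:
    def test_bowley_range_and_direct_evaluation(self):
        p = PoiGHLParams(1.0, 0.5, 2.0)
        q = {k: pg.quantile(k, p) for k in (0.25, 0.5, 0.75)}
        direct = (q[0.75] - 2 * q[0.5] + q[0.25]) / (q[0.75] - q[0.25])
        bs = pg.bowley_skewness(p)
        assert bs == pytest.approx(direct, rel=1e-12)
        assert -1.0 < bs < 1.0

    def test_moors_direct_evaluation(self):
        p = PoiGHLParams(1.0, 0.5, 2.0)
        e = {k: pg.quantile(k / 8, p) for k in range(1, 8)}
        direct = (e[7] - e[5] + e[3] - e[1]) / (e[6] - e[2])
        assert pg.moors_kurtosis(p) == pytest.approx(direct, rel=1e-12)


class TestSubmodels:
    def test_hlp_closed_form(self):
        p = PoiGHLParams(0.8, 2.0, 1.0)
        xs = np.linspace(0.1, 10, 40)
        t = np.exp(-p.alpha * xs)
        expected = (1 - np.exp(-p.lam * (1 - t) / (1 + t))) / (1 - np.exp(-p.lam))
        np.testing.assert_allclose(pg.cdf(xs, p), expected, rtol=1e-12)

    def test_ghl_is_small_lam_limit(self):
        p = PoiGHLParams(0.8, 1e-8, 1.6)
        g = pg.submodel("ghl", p)
        assert isinstance(g, GHLParams)
        xs = np.linspace(0.05, 12, 60)
        diff = np.abs(
            np.asarray(pg.cdf(xs, p)) - pg.ghl_cdf(xs, g.alpha, g.a)
        )
        assert diff.max() <= 1e-7

    def test_hl_equals_ghl_with_unit_shape(self):
        p = PoiGHLParams(1.3, 0.5, 2.0)
        hl = pg.submodel("hl", p)
        xs = np.linspace(0.1, 8, 30)
        np.testing.assert_allclose(
            pg.ghl_cdf(xs, hl.alpha, 1.0), np.tanh(1.3 * xs / 2), rtol=1e-14
        )

    def test_hlp_fixes_shape(self):
        sub = pg.submodel("hlp", PoiGHLParams(1.0, 2.0, 3.0))
        assert sub.a == 1.0 and sub.lam == 2.0

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            pg.submodel("weibull", P111)

    def test_compounding_identity(self):
        # integrating the truncated-exponential mixing density up to the GHL
        # cdf must reproduce the PoiGHL cdf
        p = PoiGHLParams(0.9, 1.7, 0.8)
        for x in np.linspace(0.1, 7, 15):
            g = pg.ghl_cdf(x, p.alpha, p.a)
            val, _ = integrate.quad(
                lambda z: p.lam * np.exp(-p.lam * z) / (1 - np.exp(-p.lam)),
                0.0, g,
            )
            assert val == pytest.approx(pg.cdf(x, p), abs=1e-10)


class TestLogPoiGHL:
    Q = LPoiGHLParams(lam=1.5, a=2.0, mu=0.3, sigma=0.8)

    def test_normalizes(self):
        val, _ = integrate.quad(
            lambda y: pg.lpoighl_pdf(y, self.Q), -np.inf, np.inf,
            epsabs=1e-12, epsrel=1e-12, limit=300,
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_log_transform_of_poighl_sample(self):
        q = self.Q
        xs = pg.sample(100_000, q.to_poighl(), seed=17)
        ys = q.sigma * np.log(xs)
        assert stats.kstest(ys, lambda t: pg.lpoighl_cdf(t, q)).pvalue > 0.01

    def test_standardized_form(self):
        z = LPoiGHLParams(lam=1.5, a=2.0, mu=0.0, sigma=1.0)
        ys = np.linspace(-4, 3, 50)
        # mu=0, sigma=1 is the standardized z-form
        np.testing.assert_allclose(
            pg.lpoighl_cdf(ys, z),
            np.expm1(-z.lam * np.tanh(np.exp(ys) / 2) ** z.a) / np.expm1(-z.lam),
            rtol=1e-12,
        )


class TestDensityShape:
    @pytest.mark.parametrize(
        "params, expected",
        [((1.0, 3.0, 0.9), True), ((1.0, 1.0, 0.5), False), ((1.0, 5.0, 0.3), False)],
    )
    def test_condition(self, params, expected):
        assert pg.density_decreasing_condition(PoiGHLParams(*params)) is expected

    def test_condition_implies_decreasing_logdensity(self):
        p = PoiGHLParams(1.0, 3.0, 0.9)
        assert pg.density_decreasing_condition(p)
        xs = np.linspace(1e-3, 15, 200)
        lp = pg.logpdf(xs, p)
        assert np.all(np.diff(lp) < 0)
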