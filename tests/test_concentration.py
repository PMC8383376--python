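"""Concentration curve and index: worked examples, identities, inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mchequity.concentration import (
    RankedHealthSeries,
    analyze_series,
    ci_covariance,
    ci_discrete,
    ci_from_curve,
    ci_standard_error,
    classify_direction,
    concentration_curve,
    fractional_ranks,
    significance_stars,
)


class TestFractionalRanks:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            ([1, 1, 1, 1], [0.25, 0.50, 0.75, 1.00]),  # r_i = i/N
            ([1.0], [1.0]),
            ([1, 3], [0.25, 1.00]),  # hand cumulative sum
        ],
    )
    def test_endpoint_convention(self, weights, expected):
        np.testing.assert_allclose(fractional_ranks(weights), expected)

    def test_midpoint_convention(self):
        np.testing.assert_allclose(
            fractional_ranks([1, 1], convention="midpoint"), [0.25, 0.75]
        )

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="index 1"):
            fractional_ranks([1.0, 0.0, 2.0])


class TestConcentrationCurve:
    def test_constant_h_is_diagonal(self):
        s = RankedHealthSeries.from_ordered([2.0] * 5)
        curve = concentration_curve(s)
        np.testing.assert_allclose(curve.L, curve.p)

    def test_hand_computed_points(self):
        s = RankedHealthSeries.from_ordered([0, 0, 1, 1])
        curve = concentration_curve(s)
        np.testing.assert_allclose(curve.p, [0, 0.25, 0.5, 0.75, 1.0])
        np.testing.assert_allclose(curve.L, [0, 0, 0, 0.5, 1.0])

    def test_mass_on_poorest_lies_above_diagonal(self):
        s = RankedHealthSeries.from_ordered([1, 0, 0, 0])
        curve = concentration_curve(s)
        interior = (curve.p > 0) & (curve.p < 1)
        assert np.all(curve.L[interior] > curve.p[interior])

    def test_endpoints_and_monotonicity(self, rng):
        h = rng.random(50)
        s = RankedHealthSeries.from_ordered(h, weights=rng.random(50) + 0.1)
        curve = concentration_curve(s)
        assert curve.p[0] == 0 and curve.L[0] == 0
        assert curve.p[-1] == 1 and curve.L[-1] == pytest.approx(1)
        assert np.all(np.diff(curve.L) >= -1e-15)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            concentration_curve(RankedHealthSeries.from_ordered([0.0, 0.0]))


class TestIndexForms:
    def test_diagonal_curve_gives_zero(self):
        s = RankedHealthSeries.from_ordered([1.0] * 10)
        assert ci_from_curve(concentration_curve(s)) == pytest.approx(0, abs=1e-15)

    def test_curve_form_matches_hand_trapezoid(self):
        # points (0,0),(.25,0),(.5,0),(.75,.5),(1,1): area = 0.0625 + 0.1875 = 0.25
        s = RankedHealthSeries.from_ordered([0, 0, 1, 1])
        assert ci_from_curve(concentration_curve(s)) == pytest.approx(1 - 2 * 0.25)

    def test_extreme_concentration_approaches_one(self):
        n = 10_000
        h = np.zeros(n)
        h[-1] = 1.0
        s = RankedHealthSeries.from_ordered(h)
        assert ci_covariance(s) == pytest.approx(1.0, abs=2 / n)

    @pytest.mark.parametrize(
        "h, expected",
        [
            ([0, 0, 1, 1], 0.5),    # (2/(4*0.5))*1.75 - 1 - 0.25
            ([1, 1, 0, 0], -0.5),   # rank reversal negates
            ([3, 3, 3], 0.0),       # constant
        ],
    )
    def test_discrete_form_examples(self, h, expected):
        assert ci_discrete(h) == pytest.approx(expected, abs=1e-15)

    def test_covariance_form_hand_example(self):
        s = RankedHealthSeries.from_ordered([0, 0, 1, 1])
        # (2/0.5) * (mean(h*r) - 0.5*0.625) = 0.5
        assert ci_covariance(s) == pytest.approx(0.5, abs=1e-15)

    def test_constant_h_zero_for_any_weights(self, rng):
        w = rng.random(30) + 0.05
        s = RankedHealthSeries.from_ordered(np.full(30, 0.7), weights=w)
        assert ci_covariance(s) == pytest.approx(0, abs=1e-15)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            ci_discrete([0, 0, 0])


class TestAlgebraicProperties:
    """Spec-level identities among the three computational routes."""

    @given(
        st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=200).filter(
            lambda h: sum(h) > 1e-6
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_discrete_equals_covariance_equal_weights(self, h):
        s = RankedHealthSeries.from_ordered(h)
        assert abs(ci_discrete(h) - ci_covariance(s)) <= 1e-12

    @given(st.integers(0, 2**32 - 1), st.sampled_from([10, 100, 1000]))
    @settings(max_examples=60, deadline=None)
    def test_curve_form_within_one_over_n(self, seed, n):
        rng = np.random.default_rng(seed)
        h = rng.binomial(1, 0.3, n).astype(float)
        if h.sum() == 0:
            h[0] = 1.0
        s = RankedHealthSeries.from_ordered(h)
        assert abs(ci_from_curve(concentration_curve(s)) - ci_covariance(s)) <= 1 / n

    @given(st.integers(0, 2**32 - 1), st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, seed, k):
        rng = np.random.default_rng(seed)
        h = rng.random(40)
        w = rng.random(40) + 0.1
        s1 = RankedHealthSeries.from_ordered(h, weights=w)
        s2 = RankedHealthSeries.from_ordered(k * h, weights=w)
        assert ci_covariance(s1) == pytest.approx(ci_covariance(s2), abs=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_under_rank_reversal_equal_weights(self, seed):
        # exact under endpoint ranks when weights are equal
        rng = np.random.default_rng(seed)
        h = rng.random(60)
        fwd = RankedHealthSeries.from_ordered(h)
        rev = RankedHealthSeries.from_ordered(h[::-1])
        assert ci_covariance(rev) == pytest.approx(-ci_covariance(fwd), abs=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_under_rank_reversal_weighted_midpoint(self, seed):
        # with unequal weights the identity r + r_reversed = 1 (hence exact
        # antisymmetry) holds under the midpoint rank convention
        rng = np.random.default_rng(seed)
        h = rng.random(60)
        w = rng.random(60) + 0.1
        fwd = RankedHealthSeries.from_ordered(h, weights=w, convention="midpoint")
        rev = RankedHealthSeries.from_ordered(
            h[::-1], weights=w[::-1], convention="midpoint"
        )
        assert ci_covariance(rev) == pytest.approx(-ci_covariance(fwd), abs=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.random(30) ** 3
        s = RankedHealthSeries.from_ordered(h, weights=rng.random(30) + 0.1)
        assert -1.0 <= ci_covariance(s) <= 1.0


class TestStandardError:
    def test_analytic_refuses_small_samples_bootstrap_runs(self):
        s = RankedHealthSeries.from_ordered([0, 0, 0, 1])
        with pytest.raises(ValueError, match="N >= 30"):
            ci_standard_error(s, method="analytic")
        se, p = ci_standard_error(s, method="bootstrap", B=200, rng=0)
        assert se >= 0 and 0 <= p <= 1

    def test_small_bootstrap_warns(self):
        s = RankedHealthSeries.from_ordered([0, 1, 0, 1, 1])
        with pytest.warns(UserWarning, match="B=50"):
            ci_standard_error(s, method="bootstrap", B=50, rng=0)

    def test_analytic_close_to_bootstrap(self, rng):
        h = rng.binomial(1, 0.3, 500).astype(float)
        w = rng.random(500) + 0.5
        s = RankedHealthSeries.from_ordered(h, weights=w)
        se_a, _ = ci_standard_error(s, method="analytic")
        se_b, _ = ci_standard_error(s, method="bootstrap", B=2000, rng=rng)
        assert se_a == pytest.approx(se_b, rel=0.15)

    def test_analytic_se_matches_wls_oracle(self, rng):
        # independent route: statsmodels WLS of the transformed variable on rank
        import statsmodels.api as sm

        h = rng.binomial(1, 0.4, 200).astype(float)
        w = rng.random(200) + 0.5
        s = RankedHealthSeries.from_ordered(h, weights=w)
        var_r = np.average(
            (s.fractional_rank - np.average(s.fractional_rank, weights=w)) ** 2,
            weights=w,
        )
        y = 2 * var_r * s.h / s.mu
        fit = sm.WLS(y, sm.add_constant(s.fractional_rank), weights=w).fit(cov_type="HC1")
        se, _ = ci_standard_error(s, method="analytic")
        assert se == pytest.approx(fit.bse[1], rel=1e-10)
        # the regression slope reproduces the covariance-form estimate
        assert fit.params[1] == pytest.approx(ci_covariance(s), abs=1e-10)


class TestBoundedNormalizations:
    def test_wagstaff_and_erreygers_on_binary_series(self):
        from mchequity.concentration import erreygers_corrected, wagstaff_normalized

        s = RankedHealthSeries.from_ordered([0, 0, 1, 1])
        C = ci_covariance(s)  # 0.5 at mu = 0.5
        assert wagstaff_normalized(C, s.mu) == pytest.approx(1.0)
        assert erreygers_corrected(C, s.mu) == pytest.approx(1.0)
        # mirror property: shortfall 1-h reverses the Erreygers index
        s_short = RankedHealthSeries.from_ordered([1, 1, 0, 0])
        assert erreygers_corrected(
            ci_covariance(s_short), s_short.mu
        ) == pytest.approx(-erreygers_corrected(C, s.mu))

    def test_degenerate_prevalence_rejected(self):
        from mchequity.concentration import wagstaff_normalized

        with pytest.raises(ValueError):
            wagstaff_normalized(0.1, 1.0)


class TestClassification:
    @pytest.mark.parametrize(
        "C, p, expected",
        [
            (-0.133, 0.001, "pro-poor"),
            (0.076, 0.001, "pro-rich"),
            (-0.021, 0.45, "equal"),
            (0.0, 0.001, "equal"),
        ],
    )
    def test_direction(self, C, p, expected):
        assert classify_direction(C, p) == expected

    @pytest.mark.parametrize(
        "p, stars",
        [(0.005, "***"), (0.03, "**"), (0.07, "*"), (0.2, ""), (0.01, "**"), (0.1, "")],
    )
    def test_star_ladder(self, p, stars):
        assert significance_stars(p) == stars

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


def test_analyze_series_end_to_end(rng):
    h = np.sort(rng.binomial(1, np.linspace(0.1, 0.6, 1000)).astype(float))
    # h sorted ascending with rank: strongly pro-rich
    s = RankedHealthSeries.from_ordered(h)
    res = analyze_series(s)
    assert res.C > 0 and res.direction == "pro-rich" and res.stars == "***"
    assert res.N == 1000 and res.mu == pytest.approx(h.mean())
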