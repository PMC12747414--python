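"""Hyper-exponential survival model: evaluation, fitting, tolerance."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prism_rarity import (FitError, HyperExponentialModel, HyperExpResults,
                          NotFoundError, SurvivalCurve, ValidationError,
                          fit_response, survival_probability)


class TestSurvivalProbability:
    @pytest.mark.parametrize("alpha,beta,n,expected,places", [
        (0.104, 0.019, 7, 0.19, 2),     # calibration enzyme at n0
        (-0.047, 0.054, 10, 0.007, 3),  # fluorescent protein at n0
        (0.096, 0.039, 12, 0.0011, 4),  # isomerase at its reference n
    ])
    def test_published_fit_values(self, alpha, beta, n, expected, places):
        assert round(survival_probability(alpha, beta, n), places) == expected

    @pytest.mark.parametrize("alpha,beta", [(0.5, 0.01), (-0.3, 0.2), (0, 0)])
    def test_unity_at_zero_substitutions(self, alpha, beta):
        assert survival_probability(alpha, beta, 0) == 1.0

    @given(alpha=st.floats(0, 1), beta=st.floats(1e-4, 0.1),
           n=st.integers(0, 50))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_decreasing_under_epistasis(self, alpha, beta, n):
        assert (survival_probability(alpha, beta, n)
                > survival_probability(alpha, beta, n + 1))


class TestSurvivalCurve:
    def test_counts_must_match_proportion(self):
        with pytest.raises(ValidationError):
            SurvivalCurve((0, 1), (1.0, 0.6), (10, 10), (10, 5))

    def test_n_must_increase(self):
        with pytest.raises(ValidationError):
            SurvivalCurve((0, 2, 1), (1.0, 0.5, 0.7))

    def test_proportion_bounds(self):
        with pytest.raises(ValidationError):
            SurvivalCurve((0, 1, 2), (1.0, 1.2, 0.5))

    def test_from_counts_exact_ratio(self):
        c = SurvivalCurve.from_counts([0, 1, 2], [10, 7, 3], [10, 10, 10])
        assert c.proportion == (1.0, 0.7, 0.3)


class TestFitting:
    def test_noiseless_recovery_to_1e6(self, noiseless_curve):
        res = fit_response(noiseless_curve)
        assert res.alpha == pytest.approx(0.104, abs=1e-6)
        assert res.beta == pytest.approx(0.019, abs=1e-6)
        assert res.r2_hyper == pytest.approx(1.0, abs=1e-9)

    def test_pure_exponential_nests(self):
        n = tuple(range(12))
        p = tuple(math.exp(-0.2 * k) for k in n)
        res = fit_response(SurvivalCurve(n, p))
        assert abs(res.beta) < 1e-6
        assert res.r2_hyper - res.r2_exp < 1e-9
        assert res.r2_hyper >= res.r2_exp

    def test_fit_idempotence(self, noiseless_curve):
        first = fit_response(noiseless_curve)
        refit_curve = SurvivalCurve(
            noiseless_curve.n,
            tuple(float(first.predict(k)) for k in noiseless_curve.n))
        second = fit_response(refit_curve)
        assert second.alpha == pytest.approx(first.alpha, abs=1e-9)
        assert second.beta == pytest.approx(first.beta, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            HyperExponentialModel(SurvivalCurve((0, 1, 2), (1.0, 0.8, 0.6)),
                                  max_n=1)

    def test_max_n_excludes_tail(self, noiseless_curve):
        res = fit_response(noiseless_curve, max_n=8)
        assert res.model.exog.max() == 8
        assert res.alpha == pytest.approx(0.104, abs=1e-6)

    def test_negative_alpha_allowed(self):
        n = tuple(range(11))
        p = tuple(float(survival_probability(-0.047, 0.054, k)) for k in n)
        res = fit_response(SurvivalCurve(n, p))
        assert res.alpha == pytest.approx(-0.047, abs=1e-6)

    def test_summary_mentions_both_models(self, noiseless_curve):
        text = fit_response(noiseless_curve).summary()
        assert "alpha" in text and "exponential null" in text


class TestToleratedRatio:
    def test_calibration_enzyme_ratio_near_half_at_14(self, bla_fit):
        # published reading: P(15)/P(14) ~ 1/2
        assert bla_fit.tolerated_ratio(14) == pytest.approx(0.519, abs=5e-4)

    def test_fluorescent_ratio_near_third_at_10(self, gfp_fit):
        assert gfp_fit.tolerated_ratio(10) == pytest.approx(0.337, abs=5e-4)

    def test_constant_when_no_epistasis(self):
        res = HyperExpResults.from_params(0.5, 0.0)
        for n in (0, 5, 50):
            assert res.tolerated_ratio(n) == pytest.approx(math.exp(-0.5))

    def test_warns_outside_epistatic_regime(self):
        res = HyperExpResults.from_params(-0.5, 0.01)
        with pytest.warns(UserWarning):
            assert res.tolerated_ratio(0) > 1.0

    @given(beta=st.floats(1e-3, 0.3), n=st.integers(0, 100))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_decreasing_in_n(self, beta, n):
        res = HyperExpResults.from_params(0.05, beta)
        assert res.tolerated_ratio(n) > res.tolerated_ratio(n + 1)


class TestSelectReferenceN:
    def test_isomerase_reference_is_12(self, hisa_fit):
        assert hisa_fit.select_reference_n(1 / 3) == 12

    def test_analytically_forced_crossing(self):
        res = HyperExpResults.from_params(0.0, 0.05)
        target = math.exp(-0.05 * 21)  # exactly the ratio at n = 10
        assert res.select_reference_n(target) == 10

    def test_requires_epistasis(self):
        with pytest.raises(ValidationError):
            HyperExpResults.from_params(0.5, 0.0).select_reference_n(0.5)

    def test_not_found_when_out_of_range(self, bla_fit):
        with pytest.raises(NotFoundError):
            bla_fit.select_reference_n(1 / 3, n_max=5)


class TestEpistasisFlag:
    def test_beta_two_sigma_rule(self):
        assert HyperExpResults.from_params(0.1, 0.02, 0.01, 0.009).is_epistatic()
        assert not HyperExpResults.from_params(0.1, 0.02, 0.01, 0.011).is_epistatic()

    def test_configurable_threshold(self):
        r = HyperExpResults.from_params(0.1, 0.03, 0.01, 0.012)
        assert r.is_epistatic(k_sigma=2.0)
        assert not r.is_epistatic(k_sigma=3.0)
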