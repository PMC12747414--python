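"""Boundary extrapolation and the four upper-bound rarity estimators."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prism_rarity import (ValidationError, boundary_from_tolerance,
                          composite_rarity, format_exponent,
                          prob_functional_in_target,
                          rarity_from_nondestabilizing, rarity_from_tolerance,
                          tolerance_from_rarity)


class TestBoundaryFromTolerance:
    @pytest.mark.parametrize("p_n0,ptol,n0,expected", [
        (0.19, 1 / 3, 7, 89),     # calibration enzyme, measured tolerance
        (0.006, 1 / 2, 14, 139),  # same protein, conservative model ratio
        (0.0011, 1 / 3, 12, 90),  # isomerase with benchmark tolerance
    ])
    def test_published_boundaries(self, p_n0, ptol, n0, expected):
        assert boundary_from_tolerance(p_n0, ptol, n0) == expected

    def test_single_tolerated_step(self):
        p0 = 0.4
        assert boundary_from_tolerance(p0, 0.5, 3, p_min=p0 * 0.5) == 4

    def test_increasing_in_n0(self):
        vals = [boundary_from_tolerance(0.1, 1 / 3, n0) for n0 in range(0, 20)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_weaker_tolerance_pushes_boundary_out(self):
        # closer ptol to 1 -> shallower decay -> larger boundary
        assert (boundary_from_tolerance(0.1, 0.6, 5)
                > boundary_from_tolerance(0.1, 0.3, 5))

    @pytest.mark.parametrize("kwargs", [
        dict(p_n0=0.1, ptol=1.0, n0=5),
        dict(p_n0=1e-45, ptol=0.5, n0=5),  # p_min >= P(n0)
    ])
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValidationError):
            boundary_from_tolerance(**kwargs)

    def test_rounding_options(self):
        assert boundary_from_tolerance(0.006, 1 / 2, 14,
                                       rounding="floor") == 139
        assert boundary_from_tolerance(0.006, 1 / 2, 14,
                                       rounding="ceil") == 140


class TestInTargetBound:
    def test_benchmark_tolerance_exponent(self):
        assert format_exponent(prob_functional_in_target(1 / 3, 150)) == -72

    def test_conservative_tolerance_exponent(self):
        assert format_exponent(prob_functional_in_target(1 / 2, 150)) == -45

    def test_empty_product(self):
        assert prob_functional_in_target(0.7, 0) == 0.0


class TestCompositeRarity:
    def test_exponents_chain_as_printed(self):
        rep = composite_rarity(-73.594, -71.568, nb=150, ptol=1 / 3)
        assert (rep.exponent_pt, rep.exponent_pubt,
                rep.exponent_pub) == (-74, -72, -146)
        assert rep.log10_pub == pytest.approx(-145.162, abs=1e-3)

    def test_fluorescent_protein_chain(self):
        rep = composite_rarity(-67.7, -64.4, nb=135, ptol=1 / 3)
        assert rep.exponent_pub == -132

    def test_pt_identity(self):
        rep = composite_rarity(0.0, -12.3, nb=26, ptol=1 / 3)
        assert rep.exponent_pub == rep.exponent_pubt == -12
        assert rep.log10_pub == -12.3

    def test_formatted_exponent_is_sum_of_components(self):
        rep = composite_rarity(-10.4, -10.4, nb=22, ptol=1 / 3)
        # raw sum is -20.8 (rounds to -21); the chained convention sums
        # the individually rounded factors instead
        assert rep.exponent_pub == -20
        assert rep.log10_pub == pytest.approx(-20.8)

    def test_rejects_positive_log_probability(self):
        with pytest.raises(ValidationError):
            composite_rarity(0.5, -3.0, nb=5, ptol=0.5)

    def test_summary_contains_all_three(self):
        text = composite_rarity(-74.0, -72.0, nb=150, ptol=1 / 3).summary()
        assert "Pt" in text and "Pubt" in text and "Pub" in text


class TestWholeSequenceBounds:
    def test_all_tolerated_is_no_bound(self):
        assert rarity_from_tolerance(1.0, 500) == 0.0

    def test_direct_arithmetic(self):
        assert rarity_from_tolerance(0.5, 10) == pytest.approx(
            math.log10(2.0 ** -10))

    def test_discussion_forward_consistency(self):
        # Ptol = 74% over 300 residues sits at the 1e-40 threshold
        assert rarity_from_tolerance(0.74, 300) == pytest.approx(-39.2,
                                                                 abs=0.1)

    @pytest.mark.parametrize("pnd,L,expected", [
        (0.34, 263, -124),  # calibration enzyme row
        (0.40, 76, -31),    # ubiquitin row
        (0.37, 59, -26),    # cro repressor row
    ])
    def test_stability_table_floor_convention(self, pnd, L, expected):
        val = rarity_from_nondestabilizing(pnd, L)
        assert format_exponent(val, "floor") == expected

    def test_no_destabilization_no_bound(self):
        assert rarity_from_nondestabilizing(1.0, 300) == 0.0

    def test_tolerance_bound_weaker_than_composite_on_worked_case(self):
        # Ptol^L >= Pt * Ptol^nb for the calibration-enzyme numbers
        loose = rarity_from_tolerance(1 / 3, 263)
        tight = -73.594 + prob_functional_in_target(1 / 3, 150)
        assert loose >= tight


class TestInverseTolerance:
    @pytest.mark.parametrize("pfs,L,expected", [
        (-24, 35, 21.0),   # WW domain
        (-33, 35, 11.0),   # villin
        (-40, 300, 74.0),  # discussion-scale example
    ])
    def test_published_effective_tolerances(self, pfs, L, expected):
        assert tolerance_from_rarity(pfs, L) == expected

    @given(ptol=st.floats(0.05, 0.95), L=st.integers(20, 400))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip_within_half_percent(self, ptol, L):
        back = tolerance_from_rarity(rarity_from_tolerance(ptol, L), L)
        assert abs(back - 100 * ptol) <= 0.5

    def test_requires_rarity_below_one(self):
        with pytest.raises(ValidationError):
            tolerance_from_rarity(0.0, 100)


class TestExponentConventions:
    @pytest.mark.parametrize("log10,conv,expected", [
        (-73.594, "round", -74),
        (-72.1, "round", -72),
        (-123.22, "floor", -124),
        (-30.24, "floor", -31),
        (-31.0, "floor", -31),
    ])
    def test_both_conventions(self, log10, conv, expected):
        assert format_exponent(log10, conv) == expected

    def test_unknown_convention(self):
        with pytest.raises(ValidationError):
            format_exponent(-5.0, "ceiling")
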