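"""The isoreflective construct, the Kabirian coefficient and its translation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ordimirror.optinalysis_core import (
    alternative_coefficients,
    bicoefficient,
    build_construct,
    kabirian_coefficient,
    kc_to_probability,
    sm_ordinalysis,
)


def brute_force_kc(values, p):
    """Independent oracle: direct summation over the explicit d and R sequences."""
    n = len(values)
    d = np.concatenate([np.sort(np.asarray(values, dtype=float)), [0.0], np.full(n, float(p))])
    R = np.arange(1, 2 * n + 2, dtype=float)
    return (n + 1) * d.sum() / (R @ d)


class TestConstruct:
    def test_arrangement_and_optiscale(self):
        c = build_construct([0, 1, 2, 3, 4, 5, 6], 6)
        assert c.d == (0, 1, 2, 3, 4, 5, 6, 0, 6, 6, 6, 6, 6, 6, 6)
        assert list(c.R) == list(range(1, 16))
        assert c.r_c == 8

    def test_all_maximum(self):
        assert build_construct([4, 4], 4).d == (4, 4, 0, 4, 4)

    def test_data_sorted_ascending(self):
        assert build_construct([3, 1], 4).d == (1, 3, 0, 4, 4)

    @pytest.mark.parametrize("values,p", [([5, 1], 4), ([-1, 2], 4), ([1], 4), ([1, 2], 0)])
    def test_invalid_inputs(self, values, p):
        with pytest.raises(ValueError):
            build_construct(values, p)


class TestKabirianCoefficient:
    def test_worked_ten_item_example(self):
        # natural [2,3,...,3,4] -> whole [1,2,...,2,3] on a 5-point scale
        c = build_construct([1, 2, 2, 2, 2, 2, 2, 2, 2, 3], 4)
        assert kabirian_coefficient(c) == pytest.approx(0.847240, abs=5e-7)

    def test_worked_fifteen_item_example(self):
        whole = [v - 1 for v in [2, 2, 2, 2, 3, 1, 5, 3, 2, 2, 3, 2, 3, 2, 2]]
        assert kabirian_coefficient(build_construct(whole, 4)) == pytest.approx(
            0.783555, abs=5e-7)

    def test_perfect_proximity(self):
        for n, p in [(2, 4), (7, 6), (10, 0.06)]:
            assert kabirian_coefficient(build_construct([p] * n, p)) == pytest.approx(1.0)

    def test_floor_at_two_thirds(self):
        # all responses at the bottom: closed form (n+1)np / (3pn(n+1)/2) = 2/3
        for n, p in [(2, 4), (9, 2), (25, 0.06)]:
            kc = kabirian_coefficient(build_construct([0] * n, p))
            assert kc == pytest.approx(2 / 3, abs=1e-12)
            assert kc == pytest.approx(brute_force_kc([0] * n, p), abs=1e-12)

    @given(st.integers(2, 15), st.integers(0, 10_000), st.floats(0.5, 100))
    @settings(max_examples=200, derandomize=True)
    def test_closed_form_matches_brute_force(self, n, seed, p):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, p, size=n)
        kc = kabirian_coefficient(build_construct(values, p))
        assert kc == pytest.approx(brute_force_kc(values, p), abs=1e-12)
        assert 2 / 3 - 1e-12 <= kc <= 1 + 1e-12

    def test_scale_invariance(self):
        values = [1, 3, 0, 2, 4, 4]
        base = kabirian_coefficient(build_construct(values, 4))
        for c in (0.01, 2, 1000):
            scaled = kabirian_coefficient(build_construct([c * v for v in values], 4 * c))
            assert scaled == pytest.approx(base, abs=1e-12)


class TestBicoefficient:
    @pytest.mark.parametrize("kc,expected", [(1, 1), (2 / 3, 3 / 2), (9 / 11, 11 / 9)])
    def test_reciprocal(self, kc, expected):
        assert bicoefficient(kc) == pytest.approx(expected, abs=1e-15)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bicoefficient(0)


class TestProbabilityTranslation:
    @pytest.mark.parametrize("kc,n,expected", [
        (33 / 41, 10, 11 / 19),       # prints 0.5789
        (1.0, 7, 1.0),
        (9 / 11, 7, 47 / 79),         # prints 0.5949
        (1520 / 1780, 15, 0.6914),    # prints 0.6914
    ])
    def test_printed_cells(self, kc, n, expected):
        assert kc_to_probability(kc, n) == pytest.approx(expected, abs=5e-5)

    def test_lower_bound_value(self):
        for n in (2, 7, 40):
            assert kc_to_probability(2 / 3, n) == pytest.approx((n - 1) / (3 * n + 1))

    def test_monotone_in_kc(self):
        grid = np.linspace(2 / 3, 1, 200)
        probs = [kc_to_probability(k, 10) for k in grid]
        assert np.all(np.diff(probs) > 0)

    def test_out_of_model_coefficient_rejected(self):
        with pytest.raises(ValueError, match="out-of-model"):
            kc_to_probability(0.5, 10)
        with pytest.raises(ValueError, match="out-of-model"):
            kc_to_probability(1.2, 10)

    def test_float_overshoot_clamped(self):
        assert kc_to_probability(1 + 1e-12, 10) == 1.0


class TestAlternativeCoefficients:
    def test_perfect_proximity_complement(self):
        _, kcalt2 = alternative_coefficients(1.0, 10)
        assert kcalt2 == pytest.approx(11 / 21)

    def test_kcalt2_matches_numeric_inversion(self):
        n, kc = 10, 33 / 41
        psdev = 1 - kc_to_probability(kc, n)
        root = brentq(lambda x: kc_to_probability(x, n) - psdev, 2 / 3, 1, xtol=1e-14)
        _, kcalt2 = alternative_coefficients(kc, n)
        assert kcalt2 == pytest.approx(root, abs=1e-10)
        assert kcalt2 == pytest.approx(297 / 407, abs=1e-12)

    def test_kcalt1_is_identity(self):
        assert alternative_coefficients(0.8, 5)[0] == pytest.approx(0.8)


class TestSmOrdinalysis:
    def test_worked_selector_examples(self):
        assert sm_ordinalysis([1, 1, 1, 1, 1, 5, 5, 5, 5, 5], 5, 5,
                              "natural_numbers", "p-sdev") == pytest.approx(0.4211, abs=5e-5)
        assert sm_ordinalysis([5, 5, 5, 5, 5], 5, 5,
                              "natural_numbers", "p-sprox") == pytest.approx(1.0)
        assert sm_ordinalysis([1, 1, 5, 1, 1, 2, 4, 2, 5, 3, 1, 1, 5, 1, 3], 5, 5,
                              "natural_numbers", "kc-sprox") == pytest.approx(
                                  0.761010, abs=5e-7)

    def test_long_and_short_selector_forms_agree(self):
        data = [4, 3, 1, 4, 4, 2]
        for long, short in [("print:kc-sprox", "kc"), ("print:p-sprox", "pprox"),
                            ("print:p-sdev", "pdev"), ("print:all_in_list", "all_in_list")]:
            assert sm_ordinalysis(data, 5, 5, "natural_numbers", long) == \
                sm_ordinalysis(data, 5, 5, "natural_numbers", short)

    def test_dict_output_complementary_and_reciprocal(self):
        res = sm_ordinalysis([2, 4, 1, 3, 5], 5, 5, "natural_numbers", "all_in_dict")
        assert res["p_sprox"] + res["p_sdev"] == 1.0
        assert res["kc_sprox"] * res["kc2_sprox"] == pytest.approx(1.0, abs=1e-12)
        assert res["meta"]["alternative_coefficients"] == "provisional semantics"

    def test_unknown_selector_lists_valid_tags(self):
        with pytest.raises(ValueError, match="pprox"):
            sm_ordinalysis([1, 2], 5, 5, "natural_numbers", "print:everything")

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        data = list(rng.integers(1, 6, size=12))
        base = sm_ordinalysis(data, 5, 5, "natural_numbers", "all_in_list")
        for _ in range(5):
            rng.shuffle(data)
            assert sm_ordinalysis(data, 5, 5, "natural_numbers", "all_in_list") == base

    def test_monotone_dominance_single_step(self):
        data = [2, 3, 3, 1, 4]
        kc0 = sm_ordinalysis(data, 5, 5, "natural_numbers", "kc")
        bumped = [3, 3, 3, 1, 4]
        assert sm_ordinalysis(bumped, 5, 5, "natural_numbers", "kc") > kc0

    def test_decimal_scale_equals_integer_scale(self):
        dec = sm_ordinalysis([0.01 * i for i in range(1, 8)], 7, 0.07,
                             "natural_numbers", "all_in_list")
        ints = sm_ordinalysis(list(range(1, 8)), 7, 7, "natural_numbers", "all_in_list")
        assert dec == pytest.approx(ints, abs=1e-12)
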