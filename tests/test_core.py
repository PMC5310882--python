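"""Core PE metric: ranked values, Lorenz curves, closed forms, correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pequal import (
    FeatureTable,
    PEDomainError,
    ValidationError,
    correct_pe,
    lorenz_curve,
    pe_fixed,
    pe_from_curve,
    pe_proportional,
    ranked_values,
)
from conftest import gini_pairwise, random_table


def table(areas, protected):
    return FeatureTable.from_arrays(areas, protected)


class TestFeatureTable:
    def test_totals_are_sums(self):
        t = table([10, 100], [1, 50])
        assert t.n == 2
        assert t.total_area == 110.0
        assert t.total_protected == 51.0

    def test_rejects_negative_values(self):
        with pytest.raises(ValidationError, match="negative area"):
            table([-1, 10], [0, 1])
        with pytest.raises(ValidationError, match="negative protected"):
            table([10, 10], [-0.5, 1])

    def test_zero_protection_is_allowed(self):
        t = table([10, 10], [0, 5])
        assert t.total_protected == 5.0

    def test_protected_above_area_rejected_by_default(self):
        with pytest.raises(ValidationError, match="exceeds area"):
            table([10, 10], [11, 1])

    def test_clamp_mode_truncates_and_records(self):
        t = FeatureTable.from_arrays([10, 10], [11, 1], clamp=True)
        assert t.protected.tolist() == [10.0, 1.0]
        assert t.clamped_ids == ("f1",)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            FeatureTable([])


class TestRankedValues:
    @pytest.mark.parametrize(
        "variant, expected",
        [("proportional", [0.1, 0.5]), ("fixed", [1.0, 50.0])],
    )
    def test_two_feature_example(self, variant, expected):
        t = table([10, 100], [1, 50])
        assert ranked_values(t, variant).tolist() == expected

    def test_constant_protection_gives_constant_sequence(self):
        t = table([10, 20, 30], [5, 5, 5])
        assert ranked_values(t, "fixed").tolist() == [5.0, 5.0, 5.0]

    def test_zero_area_under_proportional_names_feature(self):
        t = FeatureTable([("ok", 10, 1), ("bad", 0, 0)])
        with pytest.raises(PEDomainError, match="'bad'"):
            ranked_values(t, "proportional")
        # fixed variant tolerates zero areas
        assert ranked_values(t, "fixed").tolist() == [0.0, 1.0]


class TestLorenzCurve:
    def test_equal_shares_accumulate_linearly(self):
        t = table([1] * 5, [0.1] * 5)
        c = lorenz_curve(t, "proportional")
        np.testing.assert_allclose(c.x, [0.2, 0.4, 0.6, 0.8, 1.0])
        np.testing.assert_allclose(c.y, [0.1, 0.2, 0.3, 0.4, 0.5])

    def test_perfect_inequality_curve(self):
        c = lorenz_curve(table([10, 10], [0, 5]), "fixed")
        assert c.y.tolist() == [0.0, 5.0]

    def test_cumulative_ends_at_total(self):
        c = lorenz_curve(table([10, 100], [1, 50]), "fixed")
        assert c.y.tolist() == [1.0, 51.0]
        assert c.x[-1] == 1.0

    def test_standardized_ends_at_one(self):
        c = lorenz_curve(table([10, 100], [1, 50]), "fixed")
        assert c.standardized()[-1] == 1.0


class TestClosedForms:
    def test_minimum_pe_is_half_at_n2(self):
        r = pe_fixed(table([10, 10], [0, 7]))
        assert r.raw == 0.5
        assert r.corrected == 0.0

    def test_minimum_pe_is_third_at_n3(self):
        r = pe_fixed(table([10, 10, 10], [0, 0, 7]))
        assert r.raw == pytest.approx(1 / 3, rel=1e-15)
        assert r.corrected == pytest.approx(0.0, abs=1e-15)

    def test_equal_protection_gives_one(self):
        r = pe_fixed(table([10, 20, 30, 40], [5, 5, 5, 5]))
        assert r.raw == 1.0
        assert r.corrected == 1.0

    def test_fixed_against_frozen_gini_oracle(self):
        # p=(1,2,3,4): pairwise Gini = 0.25, so raw PE = 0.75 (hand-computed)
        r = pe_fixed(table([9, 9, 9, 9], [1, 2, 3, 4]))
        assert r.raw == pytest.approx(0.75, rel=1e-14)

    def test_proportional_against_frozen_gini_oracle(self):
        # ratios (0.1,0.1,0.2,0.2,0.4): Gini = 0.28, raw PE = 0.72
        r = pe_proportional(table([10] * 5, [1, 1, 2, 2, 4]))
        assert r.raw == pytest.approx(0.72, rel=1e-14)

    def test_ten_percent_everywhere_gives_corrected_one(self):
        areas = np.array([3.0, 7.0, 11.0, 123.456, 9999.0])
        r = pe_proportional(table(areas, 0.1 * areas))
        assert r.corrected == pytest.approx(1.0, abs=1e-12)

    def test_no_protection_is_a_domain_error(self):
        with pytest.raises(PEDomainError, match="no protection"):
            pe_fixed(table([10, 10], [0, 0]))

    def test_single_feature_corrected_is_undefined(self):
        with pytest.raises(PEDomainError):
            pe_fixed(table([10], [5]))


class TestCorrection:
    @pytest.mark.parametrize(
        "raw, n, expected",
        [(0.5, 2, 0.0), (1.0, 2, 1.0), (1 / 3, 3, 0.0), (1.0, 50, 1.0)],
    )
    def test_fixed_points(self, raw, n, expected):
        assert correct_pe(raw, n) == pytest.approx(expected, abs=1e-15)

    def test_requires_two_features(self):
        with pytest.raises(PEDomainError):
            correct_pe(0.9, 1)

    def test_perfect_inequality_maps_to_zero_for_all_small_n(self):
        for n in range(2, 101):
            p = np.zeros(n)
            p[-1] = 7.0
            r = pe_fixed(table(np.full(n, 10.0), p))
            assert r.raw == pytest.approx(1 / n, rel=1e-12)
            assert r.corrected == pytest.approx(0.0, abs=1e-12)


class TestGeometryAgainstAlgebra:
    def test_equal_shares_curve_scores_one(self):
        c = lorenz_curve(table([1] * 5, [0.1] * 5), "proportional")
        assert pe_from_curve(c) == pytest.approx(1.0, rel=1e-15)

    def test_perfect_inequality_curve_scores_half(self):
        c = lorenz_curve(table([10, 10], [0, 5]), "fixed")
        assert pe_from_curve(c) == 0.5

    def test_zero_curve_is_domain_error(self):
        from pequal import LorenzCurve

        c = LorenzCurve(x=np.array([0.5, 1.0]), y=np.array([0.0, 0.0]), variant="fixed")
        with pytest.raises(PEDomainError):
            pe_from_curve(c)

    @pytest.mark.parametrize("variant", ["proportional", "fixed"])
    def test_random_tables_match_closed_form(self, rng, variant):
        compute = pe_proportional if variant == "proportional" else pe_fixed
        for _ in range(50):
            t = random_table(rng)
            geometric = pe_from_curve(lorenz_curve(t, variant))
            assert geometric == pytest.approx(compute(t).raw, rel=1e-12)


# -- property tests ----------------------------------------------------------

protections = st.lists(
    st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
    min_size=2,
    max_size=40,
).filter(lambda p: sum(p) > 1e-9)


@settings(max_examples=200, derandomize=True)
@given(protections)
def test_pe_is_one_minus_pairwise_gini(p):
    """Raw PE equals 1 - G with G the independent pairwise-mean-difference Gini."""
    t = FeatureTable.from_arrays(np.full(len(p), 2e6), p)
    assert pe_fixed(t).raw == pytest.approx(1 - gini_pairwise(p), rel=1e-10, abs=1e-10)


@settings(max_examples=100, derandomize=True)
@given(protections, st.randoms(use_true_random=False))
def test_pe_is_permutation_invariant(p, pyrandom):
    shuffled = list(p)
    pyrandom.shuffle(shuffled)
    t1 = FeatureTable.from_arrays(np.full(len(p), 2e6), p)
    t2 = FeatureTable.from_arrays(np.full(len(p), 2e6), shuffled)
    assert pe_fixed(t1).raw == pe_fixed(t2).raw


@settings(max_examples=100, derandomize=True)
@given(protections, st.floats(min_value=1e-3, max_value=1e3))
def test_pe_is_scale_invariant(p, scale):
    """Rescaling all p_i (fixed) or all a_i and p_i jointly (proportional)."""
    a = np.full(len(p), 2e6)
    base_f = pe_fixed(FeatureTable.from_arrays(a, p)).raw
    scaled_f = pe_fixed(FeatureTable.from_arrays(a * scale, np.asarray(p) * scale)).raw
    assert scaled_f == pytest.approx(base_f, rel=1e-9)
    a2 = np.asarray(p) + 1.0  # any positive areas
    base_p = pe_proportional(FeatureTable.from_arrays(a2, p)).raw
    joint = pe_proportional(
        FeatureTable.from_arrays(a2 * scale, np.asarray(p) * scale)
    ).raw
    assert joint == pytest.approx(base_p, rel=1e-9)


@settings(max_examples=200, derandomize=True)
@given(protections)
def test_pe_bounds_and_correction_ordering(p):
    """Raw in [1/N, 1]; corrected in [0, 1], below raw, converging as N grows."""
    n = len(p)
    r = pe_fixed(FeatureTable.from_arrays(np.full(n, 2e6), p))
    assert 1 / n - 1e-12 <= r.raw <= 1 + 1e-12
    assert -1e-12 <= r.corrected <= 1 + 1e-12
    assert r.corrected <= r.raw + 1e-12
    assert abs(r.raw - r.corrected) < r.raw / (n - 1) + 1 / (n - 1) + 1e-12
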