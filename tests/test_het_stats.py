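"""Tests of the heteroplasmy shift / variance statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mthet.errors import (
    BoundaryError,
    DegenerateInputError,
    InsufficientDataError,
    RankDeficiencyError,
)
from mthet.het_stats import (
    age_effect,
    compare_stages,
    fit_transmission,
    heteroplasmy_shift,
    normalized_variance,
    transformed_shift,
)

frac = st.floats(min_value=0.01, max_value=0.99)


class TestShift:
    @pytest.mark.parametrize("h,h0,expected", [
        (0.5, 0.5, 0.0),
        (0.68, 0.75, -0.07),
        (1.0, 0.0, 1.0),
    ])
    def test_values(self, h, h0, expected):
        assert heteroplasmy_shift(h, h0) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(BoundaryError):
            heteroplasmy_shift(1.2, 0.5)


class TestTransformedShift:
    def test_identity_is_zero(self):
        for h in (0.1, 0.5, 0.93):
            assert transformed_shift(h, h) == pytest.approx(0.0)

    def test_known_value(self):
        # ln(0.68 * 0.25 / (0.75 * 0.32)) evaluated independently
        assert transformed_shift(0.68, 0.75) == pytest.approx(-0.3448404862917)

    @given(a=frac, b=frac)
    @settings(deadline=None, max_examples=100)
    def test_antisymmetry(self, a, b):
        assert transformed_shift(a, b) == pytest.approx(-transformed_shift(b, a))

    @given(a=frac, b=frac)
    @settings(deadline=None, max_examples=100)
    def test_sign_tracks_direction(self, a, b):
        v = transformed_shift(a, b)
        if a > b + 1e-9:
            assert v > 0
        elif a + 1e-9 < b:
            assert v < 0

    @given(h0=frac, h1=frac, h2=frac)
    @settings(deadline=None, max_examples=100)
    def test_strictly_monotone_in_h(self, h0, h1, h2):
        lo, hi = sorted([h1, h2])
        if lo < hi:
            assert transformed_shift(lo, h0) < transformed_shift(hi, h0)

    def test_boundary_error_and_clamp(self):
        with pytest.raises(BoundaryError):
            transformed_shift(0.0, 0.5)
        v = transformed_shift(0.0, 0.5, boundary="clamp", eps=1e-4)
        assert v == pytest.approx(np.log(1e-4 * 0.5 / (0.5 * (1 - 1e-4))))


class TestNormalizedVariance:
    def test_constant_sample_is_zero(self):
        assert normalized_variance([0.6] * 5) == 0.0

    def test_fixation_saturates_at_one(self):
        assert normalized_variance([0, 0, 1, 1]) == pytest.approx(1.0)

    def test_two_point_sample(self):
        # population variance 0.01, mu(1-mu) = 0.25
        assert normalized_variance([0.4, 0.6]) == pytest.approx(0.04)

    def test_sample_variance_convention_flag(self):
        assert normalized_variance([0.4, 0.6], ddof=1) == pytest.approx(0.08)

    @given(st.lists(frac, min_size=3, max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_relabelling_invariance(self, hs):
        hs = np.array(hs)
        assert normalized_variance(hs) == pytest.approx(
            normalized_variance(1 - hs))

    def test_degenerate_mean(self):
        with pytest.raises(DegenerateInputError):
            normalized_variance([0.0, 0.0, 0.0])


class TestTransmissionFit:
    def test_identity_line(self):
        h0 = np.linspace(0.1, 0.9, 20)
        pairs = pd.DataFrame({"mother_h0": h0, "offspring_h": h0})
        fit = fit_transmission(pairs)
        assert fit.regression.slope == pytest.approx(1.0)
        assert fit.regression.intercept == pytest.approx(0.0, abs=1e-12)
        assert not fit.selection_signature
        assert np.allclose(fit.per_mother["mean_shift"], 0.0)

    def test_noiseless_selection_line(self):
        h0 = np.linspace(0.1, 0.9, 30)
        pairs = pd.DataFrame({"mother_h0": h0, "offspring_h": 0.5 * h0 + 0.25})
        fit = fit_transmission(pairs)
        assert fit.regression.slope == pytest.approx(0.5)
        assert fit.regression.intercept == pytest.approx(0.25)
        assert fit.selection_signature
        assert fit.crossing_h0 == pytest.approx(0.5)

    def test_per_mother_table_groups_by_id(self):
        pairs = pd.DataFrame({
            "mother_id": ["a", "a", "b", "b"],
            "mother_h0": [0.3, 0.3, 0.7, 0.7],
            "offspring_h": [0.4, 0.5, 0.6, 0.5],
        })
        fit = fit_transmission(pairs)
        tab = fit.per_mother.set_index("mother_id")
        assert tab.loc["a", "mean_shift"] == pytest.approx(0.15)
        assert tab.loc["b", "mean_shift"] == pytest.approx(-0.15)

    def test_identical_mothers_rank_deficient(self):
        pairs = pd.DataFrame({"mother_h0": [0.5] * 5,
                              "offspring_h": [0.4, 0.5, 0.6, 0.5, 0.45]})
        with pytest.raises(RankDeficiencyError):
            fit_transmission(pairs)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            fit_transmission(pd.DataFrame({"mother_h0": [0.4], "offspring_h": [0.5]}))


class TestAgeEffect:
    def test_noiseless_linear_construction_recovered(self):
        age = np.linspace(2, 12, 40)
        h0 = np.full(40, 0.5)
        # offspring chosen so the transformed shift is exactly 0.1 * age
        h = 1 / (1 + np.exp(-(0.1 * age + np.log(h0 / (1 - h0)))))
        pairs = pd.DataFrame({"mother_h0": h0, "offspring_h": h,
                              "maternal_age": age})
        rep = age_effect(pairs)
        assert rep.slope == pytest.approx(0.1)

    def test_missing_ages_dropped_and_counted(self):
        pairs = pd.DataFrame({"mother_h0": [0.5] * 6,
                              "offspring_h": [0.4, 0.5, 0.6, 0.45, 0.55, 0.5],
                              "maternal_age": [2, 4, 6, 8, np.nan, np.nan]})
        rep = age_effect(pairs)
        assert rep.n == 4 and rep.n_dropped == 2

    def test_equal_ages_rank_deficient(self):
        pairs = pd.DataFrame({"mother_h0": [0.5] * 4,
                              "offspring_h": [0.4, 0.5, 0.6, 0.45],
                              "maternal_age": [6, 6, 6, 6]})
        with pytest.raises(RankDeficiencyError):
            age_effect(pairs)

    def test_null_slope_type_one_error(self):
        # shifts independent of age: slope test should rarely reject
        rejections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            age = r.uniform(2, 12, 500)
            h = np.clip(0.5 + r.normal(0, 0.05, 500), 0.01, 0.99)
            pairs = pd.DataFrame({"mother_h0": 0.5, "offspring_h": h,
                                  "maternal_age": age})
            rejections += age_effect(pairs).slope_p <= 0.05
        assert rejections <= 2  # >=90% non-rejection over 20 seeds


class TestCompareStages:
    def test_bonferroni_definition(self):
        r = np.random.default_rng(1)
        groups = {"a": r.normal(0, 1, 50), "b": r.normal(0, 1, 50)}
        rep = compare_stages(groups, corrections=5)
        for row in rep.one_sample.itertuples():
            assert row.p_adj == pytest.approx(min(1.0, row.p_raw * 5))

    def test_same_distribution_not_significant(self):
        r = np.random.default_rng(2)
        g = r.normal(0, 1, 200)
        rep = compare_stages({"a": g, "b": g + 0.0})
        assert rep.two_sample["p_adj"].iloc[0] > 0.5

    def test_power_for_large_separation(self):
        # mean difference 1.0 at SD 1.0, n=100: essentially always detected
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            rep = compare_stages({"lo": r.normal(0, 1, 100),
                                  "hi": r.normal(1, 1, 100)}, corrections=5)
            hits += rep.two_sample["p_adj"].iloc[0] <= 0.05
        assert hits >= 19

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            compare_stages({"a": [0.5, 0.5], "b": [0.1, 0.2]})
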