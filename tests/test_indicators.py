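import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipwdid import (
    ValidationError,
    build_indicators,
    cdds,
    fcs,
    fgds,
    fit_knowledge_weights,
    food_security,
    hdds,
    knowledge_score,
    standardize,
    vita_diversity,
    vita_freq,
)
from ipwdid.indicators import FoodGroupMap


def _recall(fg_map, consumed=()):
    row = {c: (1 if c in consumed else 0) for c in fg_map.categories}
    return pd.DataFrame([row])


def _freq(fg_map, **days):
    row = {c: days.get(c, 0) for c in fg_map.categories}
    return pd.DataFrame([row])


class TestKnowledgeWeights:
    def test_all_correct_gives_weight_one(self):
        resp = pd.DataFrame({"q1": [1, 1, 1, 1]})
        w = fit_knowledge_weights(resp)
        assert w.weights["q1"] == 1.0

    def test_quarter_correct_gives_weight_four(self):
        resp = pd.DataFrame({"q1": [1] * 50 + [0] * 150})
        w = fit_knowledge_weights(resp)
        assert w.weights["q1"] == pytest.approx(4.0)

    def test_two_items_direct_formula(self):
        resp = pd.DataFrame({"easy": [1, 1, 1, 1], "hard": [1, 0, 0, 0]})
        w = fit_knowledge_weights(resp)
        assert w.weights["easy"] == pytest.approx(1.0)
        assert w.weights["hard"] == pytest.approx(4.0)

    def test_never_correct_item_excluded_with_warning(self):
        resp = pd.DataFrame({"ok": [1, 0], "dead": [0, 0]})
        with pytest.warns(UserWarning, match="dead"):
            w = fit_knowledge_weights(resp)
        assert "dead" in w.excluded
        assert "dead" not in w.items

    def test_reference_subsample(self):
        resp = pd.DataFrame({"q": [1, 1, 0, 0]})
        w = fit_knowledge_weights(resp, reference=[True, True, False, False])
        assert w.weights["q"] == 1.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            fit_knowledge_weights(pd.DataFrame({"q": [0.5, 1.0]}))


class TestKnowledgeScore:
    def test_all_zero_responses(self):
        resp = pd.DataFrame({"a": [1, 1], "b": [1, 1]})
        w = fit_knowledge_weights(resp)
        zeros = pd.DataFrame({"a": [0, 0], "b": [0, 0]})
        assert (knowledge_score(zeros, w) == 0).all()

    def test_direct_sum(self):
        ref = pd.DataFrame({"a": [1, 1, 1, 1], "b": [1, 0, 0, 0]})
        w = fit_knowledge_weights(ref)  # weights 1.0 and 4.0
        resp = pd.DataFrame({"a": [1], "b": [1]})
        assert knowledge_score(resp, w).iloc[0] == pytest.approx(5.0)

    def test_missing_scored_as_incorrect(self):
        ref = pd.DataFrame({"a": [1, 0], "b": [1, 1]})
        w = fit_knowledge_weights(ref)
        resp = pd.DataFrame({"a": [np.nan], "b": [1.0]})
        assert knowledge_score(resp, w).iloc[0] == pytest.approx(1.0)

    def test_unknown_item_rejected(self):
        ref = pd.DataFrame({"a": [1, 0]})
        w = fit_knowledge_weights(ref)
        with pytest.raises(ValidationError, match="items"):
            knowledge_score(ref, w, items=["zzz"])

    @given(st.integers(0, 2**12 - 1), st.integers(1, 11))
    @settings(max_examples=40, deadline=None)
    def test_subscores_add_to_combined(self, mask, split):
        items = [f"q{i}" for i in range(12)]
        ref = pd.DataFrame(
            np.random.default_rng(0).integers(0, 2, size=(30, 12)), columns=items
        )
        ref.iloc[0] = 1  # ensure every item has a correct answer
        w = fit_knowledge_weights(ref)
        resp = pd.DataFrame([[int(bool(mask & (1 << i))) for i in range(12)]], columns=items)
        total = knowledge_score(resp, w).iloc[0]
        left = knowledge_score(resp, w, items=items[:split]).iloc[0]
        right = knowledge_score(resp, w, items=items[split:]).iloc[0]
        assert total == pytest.approx(left + right)


class TestStandardize:
    def test_reference_mean_maps_to_zero(self):
        x = pd.Series([1.0, 2.0, 3.0])
        z = standardize(x)
        assert z.values.mean() == pytest.approx(0.0)
        assert z.values.std(ddof=0) == pytest.approx(1.0)

    def test_two_sd_above_mean(self):
        x = pd.Series([0.0, 2.0, 4.0, 6.0, 8.0])
        z = standardize(x)
        hi = (x.iloc[-1] - z.ref_mean) / z.ref_sd
        assert z.values.iloc[-1] == pytest.approx(hi)
        probe = z.ref_mean + 2 * z.ref_sd
        assert (probe - z.ref_mean) / z.ref_sd == pytest.approx(2.0)

    def test_zero_sd_fails(self):
        with pytest.raises(ValidationError, match="zero standard deviation"):
            standardize(pd.Series([3.0, 3.0, 3.0]))

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, a, b):
        x = pd.Series([1.0, 2.0, 5.0, 9.0])
        z1 = standardize(x).values
        z2 = standardize(a * x + b).values
        assert np.allclose(z1, z2, atol=1e-9)


class TestDiversityScores:
    def test_all_zero(self, fg_map):
        r = _recall(fg_map)
        assert hdds(r, fg_map).iloc[0] == 0
        assert cdds(r, fg_map).iloc[0] == 0
        assert fgds(r, fg_map).iloc[0] == 0
        assert vita_diversity(r, fg_map).iloc[0] == 0

    def test_all_one_hits_upper_bounds(self, fg_map):
        r = _recall(fg_map, consumed=fg_map.categories)
        assert hdds(r, fg_map).iloc[0] == 8
        assert cdds(r, fg_map).iloc[0] == 8
        assert fgds(r, fg_map).iloc[0] == 10
        assert vita_diversity(r, fg_map).iloc[0] == 6

    def test_green_leafy_vegetables_only(self, fg_map):
        r = _recall(fg_map, consumed=["vitaminA_vegetables"])
        assert fgds(r, fg_map).iloc[0] == 1
        assert vita_diversity(r, fg_map).iloc[0] == 1
        assert hdds(r, fg_map).iloc[0] == 1

    def test_non_binary_indicator_rejected(self, fg_map):
        r = _recall(fg_map)
        r["cereals"] = 2
        with pytest.raises(ValidationError):
            hdds(r, fg_map)

    @given(mask=st.integers(0, 2**12 - 1), extra=st.integers(0, 11))
    @settings(max_examples=60, deadline=None)
    def test_adding_a_category_never_decreases_any_score(self, fg_map, mask, extra):
        cats = list(fg_map.categories)
        consumed = [c for i, c in enumerate(cats) if mask & (1 << i)]
        r0 = _recall(fg_map, consumed)
        r1 = _recall(fg_map, set(consumed) | {cats[extra]})
        for fn in (hdds, cdds, fgds, vita_diversity):
            assert fn(r1, fg_map).iloc[0] >= fn(r0, fg_map).iloc[0]


class TestFCS:
    def test_all_zero(self, fg_map):
        assert fcs(_freq(fg_map), fg_map).iloc[0] == 0.0

    def test_cap_identity_at_daily_consumption(self, fg_map):
        f = _freq(fg_map, **{c: 7 for c in fg_map.categories})
        expected = 7 * sum(fg_map.fcs_weights.values())
        assert fcs(f, fg_map).iloc[0] == pytest.approx(expected)

    def test_group_sum_then_cap_then_weight(self, fg_map):
        # staples group (weight 2) has two member items: 5 + 4 days -> cap 7
        f = _freq(fg_map, cereals=5, white_roots_tubers=4)
        assert fcs(f, fg_map).iloc[0] == pytest.approx(min(9, 7) * 2.0)

    def test_negative_frequency_rejected(self, fg_map):
        f = _freq(fg_map, cereals=-1)
        with pytest.raises(ValidationError, match="non-negative"):
            fcs(f, fg_map)

    @given(days=st.lists(st.integers(0, 7), min_size=12, max_size=12),
           bump=st.integers(0, 11))
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_bounded(self, fg_map, days, bump):
        cats = list(fg_map.categories)
        f0 = pd.DataFrame([dict(zip(cats, days))])
        more = list(days)
        more[bump] = min(7, more[bump] + 1)
        f1 = pd.DataFrame([dict(zip(cats, more))])
        s0, s1 = fcs(f0, fg_map).iloc[0], fcs(f1, fg_map).iloc[0]
        assert s1 >= s0
        assert 0 <= s0 <= 7 * sum(fg_map.fcs_weights.values())


class TestVitaFreq:
    def test_all_zero(self, fg_map):
        assert vita_freq(_freq(fg_map), fg_map).iloc[0] == 0

    def test_daily_consumption_capped_at_seven(self, fg_map):
        f = _freq(fg_map, **{c: 7 for c in fg_map.vitamin_a_items})
        assert vita_freq(f, fg_map).iloc[0] == 7

    def test_disjoint_day_union(self, fg_map):
        f = _freq(fg_map, vitaminA_vegetables=2, vitaminA_fruits=3)
        assert vita_freq(f, fg_map).iloc[0] == 5


class TestFoodSecurity:
    def _months(self, flags):
        return pd.DataFrame([flags], columns=[f"m{i}" for i in range(12)])

    def test_all_zero(self):
        z = self._months([0] * 12)
        out = food_security(z, z, pd.Series([0]), pd.Series([0]))
        assert out.iloc[0].tolist() == [0, 0, 0, 0]

    def test_all_months_flagged(self):
        ones = self._months([1] * 12)
        zero = self._months([0] * 12)
        out = food_security(ones, zero, pd.Series([1]), pd.Series([4]))
        assert out["mihfp"].iloc[0] == 12

    def test_three_months(self):
        flags = self._months([1, 1, 1] + [0] * 9)
        zero = self._months([0] * 12)
        out = food_security(flags, zero, pd.Series([0]), pd.Series([2]))
        assert out["mihfp"].iloc[0] == 3
        assert out["food_insecurity_score"].iloc[0] == 2

    def test_wrong_length_rejected(self):
        bad = pd.DataFrame([[0] * 11])
        good = self._months([0] * 12)
        with pytest.raises(ValidationError, match="12"):
            food_security(bad, good, pd.Series([0]), pd.Series([0]))


class TestFoodGroupMapValidation:
    def test_scheme_group_counts(self, fg_map):
        assert len(fg_map.schemes["hdds"]) == 8
        assert len(fg_map.schemes["cdds"]) == 8
        assert len(fg_map.schemes["fgds"]) == 10
        assert len(fg_map.schemes["vitamin_a"]) == 6
        assert len(fg_map.schemes["fcs"]) == 7

    def test_default_group_composition(self, fg_map):
        fgds_groups = fg_map.schemes["fgds"]
        assert set(fgds_groups["starchy_staples"]) == {"cereals", "white_roots_tubers"}
        assert fgds_groups["organ_meat"] == ("organ_meat",)
        assert fgds_groups["oil"] == ("oils_fats",)
        assert "vitaminA_vegetables" in fg_map.schemes["vitamin_a"]
        cdds_groups = fg_map.schemes["cdds"]
        assert cdds_groups["organ_meat"] == ("organ_meat",)
        assert set(cdds_groups["vitaminA_fruits_vegetables"]) == {
            "vitaminA_vegetables",
            "vitaminA_fruits",
        }

    def test_fcs_weights_standard_vector(self, fg_map):
        assert fg_map.fcs_weights == {
            "staples": 2.0, "pulses": 3.0, "vegetables": 1.0, "fruit": 1.0,
            "meat_fish": 4.0, "milk": 4.0, "oil": 0.5,
        }

    def test_unknown_category_rejected(self, fg_map):
        schemes = {s: dict(g) for s, g in fg_map.schemes.items()}
        schemes["hdds"] = dict(schemes["hdds"], eggs=("unobtainium",))
        with pytest.raises(ValidationError, match="unobtainium"):
            FoodGroupMap(
                categories=fg_map.categories,
                schemes=schemes,
                fcs_weights=dict(fg_map.fcs_weights),
                vitamin_a_items=fg_map.vitamin_a_items,
            )

    def test_nonpositive_fcs_weight_rejected(self, fg_map):
        weights = dict(fg_map.fcs_weights, oil=0.0)
        with pytest.raises(ValidationError, match="> 0"):
            FoodGroupMap(
                categories=fg_map.categories,
                schemes={s: dict(g) for s, g in fg_map.schemes.items()},
                fcs_weights=weights,
                vitamin_a_items=fg_map.vitamin_a_items,
            )


class TestBuildIndicators:
    def test_ranges_and_additivity(self, small_panel, fg_map):
        ind = build_indicators(small_panel, fg_map)
        assert ind["hdds"].between(0, 8).all()
        assert ind["cdds"].between(0, 8).all()
        assert ind["fgds"].between(0, 10).all()
        assert ind["vita_diversity"].between(0, 6).all()
        assert (ind["fcs"] >= 0).all()
        assert ind["vita_freq_days"].between(0, 7).all()
        assert ind["mihfp"].between(0, 12).all()
        assert ind["relief_months"].between(0, 12).all()
        assert np.allclose(
            ind["knowledge_combined"],
            ind["knowledge_production"] + ind["knowledge_vitaminA"],
        )

    def test_standardized_columns_baseline_reference(self, small_panel, fg_map):
        ind = build_indicators(small_panel, fg_map)
        base = ind[ind["wave"] == 0]
        assert base["knowledge_combined_std"].mean() == pytest.approx(0.0, abs=1e-9)
        assert base["knowledge_combined_std"].std(ddof=0) == pytest.approx(1.0)
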