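"""GI assignment hierarchy and dietary GI / glycaemic-load arithmetic."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import glycodiary as gd
from glycodiary import gi as gi_mod
from glycodiary.errors import CompositionError, DegenerateDataError, UnresolvedCodeError

from conftest import EMPTY_ANALOGUES, EMPTY_GI, EMPTY_RECIPES, gi_rows, make_composition, make_diary


def _food(code: str, carb: float) -> pd.Series:
    return pd.Series({"food_code": code, "carb_g": carb})


class TestAssignmentHierarchy:
    def test_low_carb_food_gets_zero(self):
        a = gd.assign_gi(_food("celery", 3.0), gi_rows(("celery", 40.0, "UK")),
                         EMPTY_ANALOGUES, EMPTY_RECIPES)
        assert (a.gi, a.rule) == (0.0, "low_carb_zero")

    def test_mean_of_non_uk_matches(self):
        table = gi_rows(("rice", 45.0, "other"), ("rice", 55.0, "other"))
        a = gd.assign_gi(_food("rice", 28.0), table, EMPTY_ANALOGUES, EMPTY_RECIPES)
        assert (a.gi, a.rule) == (50.0, "mean_of_matches")

    def test_uk_studies_preferred_over_others(self):
        table = gi_rows(("bread", 40.0, "UK"), ("bread", 60.0, "other"))
        a = gd.assign_gi(_food("bread", 47.0), table, EMPTY_ANALOGUES, EMPTY_RECIPES)
        assert (a.gi, a.rule) == (40.0, "uk_preferred")
        assert a.source_codes == ("bread",)

    def test_single_match_is_direct(self):
        a = gd.assign_gi(_food("bread", 47.0), gi_rows(("bread", 70.0, "other")),
                         EMPTY_ANALOGUES, EMPTY_RECIPES)
        assert (a.gi, a.rule) == (70.0, "direct")

    def test_unmatchable_carbohydrate_food_defaults_to_50(self):
        a = gd.assign_gi(_food("novel", 20.0), EMPTY_GI, EMPTY_ANALOGUES, EMPTY_RECIPES)
        assert (a.gi, a.rule) == (50.0, "default_50")

    def test_analogue_imputation(self):
        analogues = pd.DataFrame({"food_code": ["spelt"], "analogue_code": ["wheat"]})
        a = gd.assign_gi(_food("spelt", 30.0), gi_rows(("wheat", 62.0, "other")),
                         analogues, EMPTY_RECIPES)
        assert (a.gi, a.rule) == (62.0, "analogue_imputed")
        assert a.source_codes == ("wheat",)

    def test_pattern_rows_match_by_glob(self):
        table = gi_rows(("apple*", 38.0, "other"))
        a = gd.assign_gi(_food("apple_braeburn", 12.0), table, EMPTY_ANALOGUES, EMPTY_RECIPES)
        assert (a.gi, a.rule) == (38.0, "direct")

    def test_negative_carbohydrate_rejected(self):
        with pytest.raises(CompositionError):
            gd.assign_gi(_food("bad", -1.0), EMPTY_GI, EMPTY_ANALOGUES, EMPTY_RECIPES)

    def test_exactly_one_rule_per_synthetic_food(self, cohort_small):
        c = cohort_small
        assignments = gd.assign_all(c.composition, c.gi_table, c.analogue_map, c.recipes)
        assert len(assignments) == len(c.composition)
        assert assignments["rule"].isin(gi_mod.RULES).all()
        counts = gi_mod.rule_counts(assignments)
        assert sum(counts.values()) == len(c.composition)


class TestComposite:
    table = gi_rows(("rice", 70.0, "other"), ("peas", 40.0, "other"),
                    ("bread", 70.0, "other"), ("potato", 80.0, "other"))

    def test_predominant_component_wins(self):
        gi, rule, _ = gd.resolve_composite([("rice", 0.8), ("peas", 0.2)], self.table)
        assert (gi, rule) == (70.0, "composite_predominant")

    def test_mean_when_no_dominance(self):
        gi, rule, _ = gd.resolve_composite([("bread", 0.5), ("potato", 0.5)], self.table)
        assert (gi, rule) == (75.0, "composite_mean")

    def test_single_component_identity(self):
        gi, _, _ = gd.resolve_composite([("rice", 1.0)], self.table)
        assert gi == 70.0

    def test_bad_shares_and_unknown_component(self):
        with pytest.raises(CompositionError):
            gd.resolve_composite([("rice", 0.6), ("peas", 0.6)], self.table)
        with pytest.raises(UnresolvedCodeError):
            gd.resolve_composite([("quinoa", 1.0)], self.table)
        with pytest.raises(UnresolvedCodeError):
            gd.resolve_composite([], self.table)

    def test_dish_resolves_through_hierarchy(self):
        recipes = pd.DataFrame(
            {"dish_code": ["stew", "stew"], "component_code": ["rice", "peas"],
             "carb_share": [0.8, 0.2]}
        )
        a = gd.assign_gi(_food("stew", 15.0), self.table, EMPTY_ANALOGUES, recipes)
        assert (a.gi, a.rule) == (70.0, "composite_predominant")


class TestDietaryGIGL:
    comp = make_composition([
        {"food_code": "a", "carb_g": 25.0},
        {"food_code": "b", "carb_g": 75.0},
        {"food_code": "zero", "carb_g": 0.0},
    ])
    assignments = pd.DataFrame({"food_code": ["a", "b", "zero"],
                                "gi": [40.0, 80.0, 0.0],
                                "rule": ["direct", "direct", "low_carb_zero"],
                                "source_codes": ["", "", ""]})

    def test_single_food_identity(self):
        day = make_diary([(1, "a", 100.0)])
        assert gd.dietary_gi_day(day, self.comp, self.assignments) == pytest.approx(40.0)

    def test_carbohydrate_weighted_mean(self):
        # 25 g carb at GI 40 + 75 g at GI 80 -> 0.25*40 + 0.75*80 = 70
        day = make_diary([(1, "a", 100.0), (1, "b", 100.0)])
        assert gd.dietary_gi_day(day, self.comp, self.assignments) == pytest.approx(70.0)

    def test_zero_carb_day_is_undefined(self):
        day = make_diary([(1, "zero", 500.0)])
        assert gd.dietary_gi_day(day, self.comp, self.assignments) is None

    def test_gl_scaling_convention(self):
        # GI 50 on 100 g carb -> GL 50 under the /100 convention
        comp = make_composition([{"food_code": "x", "carb_g": 50.0},
                                 {"food_code": "y", "carb_g": 100.0}])
        asg = pd.DataFrame({"food_code": ["x", "y"], "gi": [50.0, 70.0],
                            "rule": ["direct", "direct"], "source_codes": ["", ""]})
        day = make_diary([(1, "x", 100.0), (1, "y", 100.0)])
        # 50/100*50 + 70/100*100 = 25 + 70
        assert gd.dietary_gl_day(day, comp, asg) == pytest.approx(95.0)
        literal = gd.GIConfig(gl_per_100=False)
        assert gd.dietary_gl_day(day, comp, asg, literal) == pytest.approx(9500.0)

    def test_empty_day_gl_zero(self):
        assert gd.dietary_gl_day(make_diary([]), self.comp, self.assignments) == 0.0

    def test_identical_days_collapse(self):
        entries = make_diary([(d, "a", 100.0) for d in (1, 2, 3, 4)]
                             + [(d, "b", 50.0) for d in (1, 2, 3, 4)])
        summ = gd.glycaemic_summary(entries, self.comp, self.assignments)
        day1 = entries[entries.day_index == 1]
        assert summ["dietary_gi"].iloc[0] == pytest.approx(
            gd.dietary_gi_day(day1, self.comp, self.assignments))
        assert summ["dietary_gl"].iloc[0] == pytest.approx(
            gd.dietary_gl_day(day1, self.comp, self.assignments))

    def test_per_day_gl_mean(self):
        # four days with GL 100,110,120,130 -> participant GL 115
        comp = make_composition([{"food_code": "x", "carb_g": 100.0}])
        asg = pd.DataFrame({"food_code": ["x"], "gi": [50.0],
                            "rule": ["direct"], "source_codes": [""]})
        entries = make_diary([(1, "x", 200.0), (2, "x", 220.0),
                              (3, "x", 240.0), (4, "x", 260.0)])
        summ = gd.glycaemic_summary(entries, comp, asg)
        assert summ["dietary_gl"].iloc[0] == pytest.approx(115.0)

    def test_all_days_undefined_raises(self):
        entries = make_diary([(1, "zero", 100.0), (2, "zero", 100.0)])
        with pytest.raises(DegenerateDataError):
            gd.glycaemic_summary(entries, self.comp, self.assignments)


class TestGlycaemicProperties:
    def _cohort_terms(self, cohort_small):
        c = cohort_small
        asg = gd.assign_all(c.composition, c.gi_table, c.analogue_map, c.recipes)
        return c, asg

    def test_boundedness(self, cohort_small):
        """Per-day GI lies within the GI range of carb-contributing foods."""
        c, asg = self._cohort_terms(cohort_small)
        terms = gi_mod.item_glycaemic_terms(c.diaries, c.composition, asg)
        carb = terms[terms["carb_item"] > 0]
        days = gi_mod.per_day_glycaemics(c.diaries, c.composition, asg)
        bounds = carb.groupby(["participant_id", "day_index"])["gi_food"].agg(["min", "max"])
        joined = days.set_index(["participant_id", "day_index"]).join(bounds)
        defined = joined.dropna(subset=["gi"])
        assert (defined["gi"] >= defined["min"] - 1e-9).all()
        assert (defined["gi"] <= defined["max"] + 1e-9).all()

    @pytest.mark.parametrize("k", [0.5, 3.0])
    def test_amount_rescaling(self, cohort_small, k):
        """Scaling every amount by k leaves GI unchanged and scales GL by k."""
        c, asg = self._cohort_terms(cohort_small)
        base = gd.glycaemic_summary(c.diaries, c.composition, asg)
        scaled_diary = c.diaries.assign(amount=c.diaries["amount"] * k)
        scaled = gd.glycaemic_summary(scaled_diary, c.composition, asg)
        np.testing.assert_allclose(scaled["dietary_gi"], base["dietary_gi"], rtol=1e-9)
        np.testing.assert_allclose(scaled["dietary_gl"], base["dietary_gl"] * k, rtol=1e-9)

    def test_brute_force_item_oracle(self, cohort_small):
        """Participant totals equal a per-item python re-summation."""
        c, asg = self._cohort_terms(cohort_small)
        summ = gd.glycaemic_summary(c.diaries, c.composition, asg)
        comp = c.composition.set_index("food_code")
        gi_map = asg.set_index("food_code")["gi"].to_dict()
        pid = summ["participant_id"].iloc[3]
        rows = c.diaries[c.diaries["participant_id"] == pid]
        num = den = 0.0
        gl_by_day: dict[int, float] = {}
        for _, r in rows.iterrows():
            carb = r["amount"] * comp.loc[r["food_code"], "carb_g"] / 100.0
            num += gi_map[r["food_code"]] * carb
            den += carb
            gl_by_day[r["day_index"]] = gl_by_day.get(r["day_index"], 0.0) + \
                gi_map[r["food_code"]] / 100.0 * carb
        row = summ[summ["participant_id"] == pid].iloc[0]
        assert row["dietary_gi"] == pytest.approx(num / den, rel=1e-12)
        assert row["dietary_gl"] == pytest.approx(np.mean(list(gl_by_day.values())), rel=1e-12)
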