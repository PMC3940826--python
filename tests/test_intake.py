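"""Nutrient expansion, percent-energy profile and recommendation compliance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import glycodiary as gd
from glycodiary import intake
from glycodiary.errors import DegenerateDataError, UnresolvedCodeError
from glycodiary.schemas import NUTRIENT_COLUMNS

from conftest import make_composition, make_diary


def test_daily_totals_linear_expansion():
    comp = make_composition([{"food_code": "f", "protein_g": 10.0, "energy_kcal": 40.0}])
    totals = gd.daily_totals(make_diary([(1, "f", 200.0)]), comp)
    assert totals["protein_g"].iloc[0] == pytest.approx(20.0)
    assert totals["energy_kcal"].iloc[0] == pytest.approx(80.0)


def test_daily_totals_zero_amount_day_is_zero_vector():
    comp = make_composition([{"food_code": "f", "protein_g": 10.0, "energy_kcal": 40.0}])
    totals = gd.daily_totals(make_diary([(1, "f", 0.0)]), comp)
    assert totals[NUTRIENT_COLUMNS].to_numpy() == pytest.approx(0.0)


def test_daily_totals_unresolved_code():
    comp = make_composition([{"food_code": "f"}])
    with pytest.raises(UnresolvedCodeError):
        gd.daily_totals(make_diary([(1, "ghost", 10.0)]), comp)


def test_daily_totals_brute_force_oracle(cohort_small):
    """Vectorised expansion equals a per-item python re-summation."""
    c = cohort_small
    totals = gd.daily_totals(c.diaries, c.composition)
    comp = c.composition.set_index("food_code")
    pid, day = totals.iloc[5][["participant_id", "day_index"]]
    rows = c.diaries[(c.diaries.participant_id == pid) & (c.diaries.day_index == day)]
    for nutrient in ("energy_kcal", "fibre_g", "vitamin_c_mg", "sodium_mg"):
        manual = sum(r["amount"] * comp.loc[r["food_code"], nutrient] / 100.0
                     for _, r in rows.iterrows())
        got = totals[(totals.participant_id == pid) & (totals.day_index == day)][nutrient].iloc[0]
        assert got == pytest.approx(manual, rel=1e-12)


def test_percent_energy_identities():
    means = pd.DataFrame([{c: 0.0 for c in NUTRIENT_COLUMNS} | {
        "participant_id": "P1", "energy_kcal": 1000.0, "protein_g": 50.0}])
    pe = gd.percent_energy(means)
    assert pe["pe_protein_g"].iloc[0] == pytest.approx(20.0)

    all_fat = pd.DataFrame([{c: 0.0 for c in NUTRIENT_COLUMNS} | {
        "participant_id": "P1", "energy_kcal": 900.0, "fat_g": 100.0}])
    assert gd.percent_energy(all_fat)["pe_fat_g"].iloc[0] == pytest.approx(100.0)

    with pytest.raises(DegenerateDataError):
        gd.percent_energy(pd.DataFrame([{c: 0.0 for c in NUTRIENT_COLUMNS}
                                        | {"participant_id": "P1"}]))


def test_percent_energy_conservation_on_synthetic(analysis_small):
    """Protein+fat+carbohydrate+alcohol %E sum to 100 on factor-consistent data."""
    s = analysis_small.summaries
    total = s["pe_protein_g"] + s["pe_fat_g"] + s["pe_carb_g"] + s["pe_alcohol_g"]
    np.testing.assert_allclose(total, 100.0, atol=1e-6)


def test_linearity_under_amount_doubling(cohort_small):
    c = cohort_small
    base = gd.summarise_cohort(c.diaries, c.composition)
    doubled = gd.summarise_cohort(c.diaries.assign(amount=c.diaries.amount * 2), c.composition)
    for col in NUTRIENT_COLUMNS:
        np.testing.assert_allclose(doubled[col], base[col] * 2, rtol=1e-9)
    for col in [f"pe_{n}" for n in intake.PERCENT_ENERGY_NUTRIENTS]:
        np.testing.assert_allclose(doubled[col], base[col], rtol=1e-9)


class TestCompliance:
    def _summary(self, **kwargs):
        base = {f"pe_{n}": 15.0 for n in intake.PERCENT_ENERGY_NUTRIENTS}
        base |= {c: 1000.0 for c in NUTRIENT_COLUMNS}
        base.update(kwargs)
        return base

    def test_upper_bounds_strict(self):
        flags = gd.check_compliance(self._summary(pe_satfat_g=9.5), "male")
        assert flags["saturated_fat"]
        assert not gd.check_compliance(self._summary(pe_satfat_g=10.0), "male")["saturated_fat"]
        assert not gd.check_compliance(self._summary(pe_fat_g=35.0), "male")["fat"]

    def test_lower_bounds_inclusive(self):
        assert gd.check_compliance(self._summary(fibre_g=24.0), "male")["fibre"]
        assert not gd.check_compliance(self._summary(fibre_g=23.999), "male")["fibre"]

    def test_bands_inclusive(self):
        assert gd.check_compliance(self._summary(pe_mufa_g=10.0), "male")["mufa"]
        assert gd.check_compliance(self._summary(pe_mufa_g=20.0), "male")["mufa"]
        assert not gd.check_compliance(self._summary(pe_mufa_g=9.0), "male")["mufa"]

    def test_iron_is_sex_specific(self):
        male = gd.check_compliance(self._summary(iron_mg=9.5), "male")
        female = gd.check_compliance(self._summary(iron_mg=9.5), "female")
        assert not male["iron_male"]
        assert female["iron_female"]
        assert "iron_female" not in male and "iron_male" not in female

    def test_flags_are_pure(self):
        s = self._summary()
        assert gd.check_compliance(s, "male") == gd.check_compliance(dict(s), "male")


def test_recommendations_frame_carries_sources():
    df = intake.recommendations_frame()
    assert set(df["source"]) == {"DNSG-EASD", "DUK", "Irish-RDA"}
    both = df.dropna(subset=["lower", "upper"])
    assert (both["lower"] <= both["upper"]).all()


class TestSupplementContribution:
    def test_extremes_and_oracle(self):
        comp = make_composition([
            {"food_code": "food", "vitamin_d_ug": 2.0},
            {"food_code": "pill", "vitamin_d_ug": 300.0, "is_supplement": True,
             "group_id": "nutritional_supplements"},
        ])
        none = gd.supplement_contribution(make_diary([(1, "food", 100.0)]), comp, "vitamin_d_ug")
        assert none["pct_from_supplements"].iloc[0] == 0.0
        all_supp = gd.supplement_contribution(make_diary([(1, "pill", 2.0)]), comp, "vitamin_d_ug")
        assert all_supp["pct_from_supplements"].iloc[0] == pytest.approx(100.0)
        mixed = gd.supplement_contribution(
            make_diary([(1, "food", 100.0), (2, "pill", 2.0)]), comp, "vitamin_d_ug")
        # 2 ug from food, 6 ug from the supplement
        assert mixed["pct_from_supplements"].iloc[0] == pytest.approx(100 * 6 / 8)

    def test_zero_total_gives_zero(self):
        comp = make_composition([{"food_code": "water"}])
        out = gd.supplement_contribution(make_diary([(1, "water", 500.0)]), comp, "iron_mg")
        assert out["pct_from_supplements"].iloc[0] == 0.0
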