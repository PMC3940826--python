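"""Synthetic matched-cohort generator.

Generates internally consistent cohorts with the structure the analysis
assumes: age/sex/BMI/social-class matched T2DM-ND pairs, 4-day diaries with
at least one weekend day, a food catalogue spanning all 38 groups with a GI
reference table that exercises every branch of the assignment hierarchy
(UK and non-UK rows, multiple published values, analogues, composite
recipes, uncovered foods), and a configurable under-reporting fraction.

Intakes follow a zero-inflated log-normal model: a participant-level
Bernoulli "consumer" gate per food group, a day-level eating gate, then a
log-normal daily amount. T2DM arm effects multiply both the consumer-gate
odds and the amount scale, mirroring surveys where arms differ in both the
fraction of consumers and the consumed amount. Group-level consumer
fractions and typical daily grams are set to magnitudes reported for Irish
adult survey data; composition vectors are energy-consistent with the UK
conversion factors so percent-of-energy identities hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SyntheticConfig
from .errors import ConfigError
from .groups import FOOD_GROUPS, GROUP_IDS
from .schemas import (
    COMPOSITION_COLUMNS,
    DIARY_COLUMNS,
    PROFILE_COLUMNS,
    SOCIAL_CLASSES,
)

#: global multiplier on typical daily grams, set so mean reported energy
#: intake lands near 2300 kcal/day before under-reporting injection
PORTION_SCALE = 1.45


@dataclass(frozen=True)
class GroupArchetype:
    """Per-100 g composition archetype and intake model for one food group."""

    carb: float            # available carbohydrate g/100 g
    sugars: float
    nm_frac: float         # fraction of sugars that are non-milk sugars
    protein: float
    fat: float
    fat_split: tuple[float, float, float]  # sat, mufa, pufa shares of fat
    fibre: float
    alcohol: float
    sodium: float          # mg/100 g
    calcium: float
    magnesium: float
    iron: float
    vitd: float            # ug/100 g
    b12: float
    folate: float
    vitc: float
    gi: float              # typical published GI for carbohydrate foods
    consumer_p: float      # fraction of participants ever eating the group
    day_p: float           # probability a consumer eats the group on a day
    daily_g: float         # median daily grams for a consumer on an eating day
    sigma: float = 0.5     # log-normal spread of daily grams


_STD_SPLIT = (0.3, 0.35, 0.2)
_DAIRY_SPLIT = (0.62, 0.28, 0.04)
_MEAT_SPLIT = (0.38, 0.45, 0.1)

ARCHETYPES: dict[str, GroupArchetype] = {
    "white_bread": GroupArchetype(47, 3, 1.0, 8.5, 2.0, _STD_SPLIT, 2.5, 0, 450, 110, 25, 1.1, 0, 0, 60, 0, 72, 0.80, 0.80, 80),
    "wholemeal_brown_bread": GroupArchetype(40, 3, 1.0, 9.5, 2.5, _STD_SPLIT, 6.5, 0, 400, 100, 70, 2.4, 0, 0, 40, 0, 68, 0.71, 0.80, 75),
    "wholegrain_bread": GroupArchetype(38, 3.5, 1.0, 10, 3.5, _STD_SPLIT, 7.5, 0, 380, 90, 80, 2.5, 0, 0, 40, 0, 54, 0.19, 0.60, 55),
    "pasta_rice_grains": GroupArchetype(28, 1, 1.0, 4.5, 1.0, _STD_SPLIT, 1.8, 0, 5, 10, 25, 0.6, 0, 0, 10, 0, 60, 0.48, 0.50, 140),
    "refined_breakfast_cereals": GroupArchetype(82, 12, 1.0, 7, 1.5, _STD_SPLIT, 3.0, 0, 500, 30, 30, 8.0, 2.0, 0.8, 160, 0, 80, 0.30, 0.60, 35),
    "wholegrain_breakfast_cereals": GroupArchetype(65, 15, 1.0, 10, 4.0, _STD_SPLIT, 9.0, 0, 250, 50, 110, 9.0, 2.0, 0.8, 150, 0, 58, 0.65, 0.70, 55),
    "biscuits": GroupArchetype(65, 28, 1.0, 6, 22, (0.5, 0.35, 0.1), 2.5, 0, 350, 80, 20, 1.8, 0, 0, 20, 0, 62, 0.55, 0.60, 25),
    "cakes_pastries_buns": GroupArchetype(52, 30, 1.0, 5.5, 18, (0.45, 0.4, 0.1), 1.5, 0, 300, 70, 15, 1.3, 0.3, 0.2, 20, 0, 55, 0.63, 0.50, 55),
    "creams_desserts": GroupArchetype(22, 18, 0.6, 3.5, 10, _DAIRY_SPLIT, 0.3, 0, 80, 100, 12, 0.2, 0.2, 0.3, 8, 1, 45, 0.49, 0.45, 70),
    "full_fat_milk_yogurt": GroupArchetype(4.7, 4.7, 0.05, 3.4, 3.8, _DAIRY_SPLIT, 0, 0, 45, 120, 11, 0.03, 0.1, 0.9, 6, 1, 35, 0.77, 0.80, 200, 0.6),
    "low_fat_milk_yogurt": GroupArchetype(5.6, 5.6, 0.10, 3.6, 1.2, _DAIRY_SPLIT, 0, 0, 45, 125, 11, 0.03, 0.1, 0.9, 6, 1, 33, 0.59, 0.80, 200, 0.6),
    "cheeses": GroupArchetype(0.5, 0.5, 0.05, 24, 33, _DAIRY_SPLIT, 0, 0, 700, 720, 25, 0.5, 0.3, 1.2, 30, 0, 0, 0.64, 0.60, 25),
    "sugars_syrups_preserves": GroupArchetype(95, 93, 1.0, 0.2, 0, _STD_SPLIT, 0, 0, 10, 10, 3, 0.2, 0, 0, 2, 1, 65, 0.73, 0.70, 20),
    "chocolate_confectionery": GroupArchetype(57, 52, 1.0, 7, 30, (0.6, 0.32, 0.03), 2.0, 0, 100, 200, 50, 1.6, 0, 0.4, 15, 0, 45, 0.36, 0.50, 25),
    "non_chocolate_confectionery": GroupArchetype(85, 70, 1.0, 0.5, 0.5, _STD_SPLIT, 0, 0, 30, 10, 3, 0.3, 0, 0, 2, 5, 70, 0.17, 0.40, 25),
    "eggs": GroupArchetype(0.5, 0.5, 1.0, 12.5, 9.0, (0.3, 0.45, 0.15), 0, 0, 140, 55, 12, 1.9, 1.6, 1.1, 50, 0, 0, 0.60, 0.50, 60),
    "butter_full_fat_spreads": GroupArchetype(0.5, 0.5, 1.0, 0.5, 80, (0.55, 0.3, 0.06), 0, 0, 600, 15, 2, 0.1, 1.0, 0, 2, 0, 0, 0.75, 0.80, 18),
    "lower_fat_spreads": GroupArchetype(1.0, 1.0, 1.0, 0.5, 40, (0.3, 0.4, 0.25), 0, 0, 500, 10, 2, 0.1, 5.0, 0, 2, 0, 0, 0.34, 0.70, 15),
    "oils": GroupArchetype(0, 0, 1.0, 0, 99.5, (0.14, 0.6, 0.22), 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0.08, 0.60, 8),
    "potatoes": GroupArchetype(17, 1, 1.0, 2.0, 0.2, _STD_SPLIT, 1.5, 0, 10, 6, 20, 0.5, 0, 0, 25, 10, 78, 0.86, 0.75, 130),
    "chipped_fried_roast_potatoes": GroupArchetype(26, 1, 1.0, 3.0, 8.0, (0.3, 0.45, 0.2), 2.0, 0, 150, 12, 25, 0.8, 0, 0, 25, 8, 75, 0.67, 0.50, 90),
    "peas_beans_lentils": GroupArchetype(14, 2, 1.0, 6.0, 1.0, _STD_SPLIT, 5.0, 0, 100, 35, 30, 1.8, 0, 0, 60, 10, 40, 0.64, 0.50, 55),
    "other_vegetables": GroupArchetype(5.5, 3.5, 1.0, 2.0, 0.5, _STD_SPLIT, 2.8, 0, 30, 40, 15, 0.8, 0, 0, 60, 25, 45, 0.98, 0.80, 110),
    "fruit": GroupArchetype(12, 11.5, 1.0, 0.8, 0.2, _STD_SPLIT, 1.8, 0, 3, 12, 10, 0.3, 0, 0, 15, 35, 42, 0.82, 0.70, 130),
    "fruit_juices": GroupArchetype(10, 10, 1.0, 0.4, 0, _STD_SPLIT, 0.1, 0, 5, 10, 9, 0.2, 0, 0, 15, 30, 50, 0.40, 0.60, 180, 0.6),
    "white_fish_shellfish": GroupArchetype(0.5, 0, 1.0, 18, 1.5, (0.2, 0.3, 0.35), 0, 0, 120, 25, 25, 0.4, 1.5, 1.5, 12, 0, 0, 0.44, 0.35, 65),
    "oily_fish": GroupArchetype(0, 0, 1.0, 20, 12, (0.22, 0.4, 0.3), 0, 0, 350, 60, 30, 1.0, 8.0, 5.0, 15, 0, 0, 0.32, 0.30, 45),
    "poultry": GroupArchetype(0.3, 0, 1.0, 27, 6.0, _MEAT_SPLIT, 0, 0, 90, 10, 25, 0.7, 0.3, 0.4, 10, 0, 0, 0.74, 0.50, 85),
    "red_meat": GroupArchetype(0.3, 0, 1.0, 26, 10, (0.42, 0.45, 0.05), 0, 0, 80, 8, 22, 2.5, 0.6, 2.0, 8, 0, 0, 0.71, 0.50, 80),
    "other_meat_products": GroupArchetype(6, 1, 1.0, 15, 18, (0.4, 0.45, 0.08), 0.8, 0, 800, 30, 18, 1.4, 0.5, 1.0, 8, 0, 50, 0.91, 0.70, 60),
    "savoury_snacks": GroupArchetype(52, 2, 1.0, 6.0, 30, (0.3, 0.4, 0.25), 4.0, 0, 1000, 30, 40, 1.5, 0, 0, 30, 10, 55, 0.18, 0.50, 20),
    "herbs_spices_nuts_seeds": GroupArchetype(10, 3, 1.0, 15, 45, (0.12, 0.55, 0.28), 6.0, 0, 100, 80, 150, 2.5, 0, 0, 60, 1, 20, 0.11, 0.40, 12),
    "soups_sauces": GroupArchetype(7, 3, 1.0, 2.0, 4.0, (0.35, 0.4, 0.2), 0.8, 0, 350, 25, 10, 0.4, 0, 0, 10, 2, 50, 0.78, 0.60, 110),
    "savouries": GroupArchetype(25, 2, 1.0, 9.0, 10, (0.4, 0.4, 0.15), 1.5, 0, 450, 110, 20, 1.1, 0.3, 0.4, 20, 2, 60, 0.38, 0.40, 110),
    "alcoholic_beverages": GroupArchetype(3, 2, 1.0, 0.3, 0, _STD_SPLIT, 0, 4.5, 8, 8, 8, 0.05, 0, 0, 5, 0, 0, 0.58, 0.50, 330, 0.7),
    "low_energy_beverages": GroupArchetype(0.4, 0.2, 1.0, 0.1, 0, _STD_SPLIT, 0, 0, 4, 3, 2, 0.02, 0, 0, 1, 0, 0, 1.00, 1.00, 1000, 0.4),
    "high_energy_beverages": GroupArchetype(10, 10, 1.0, 0.1, 0, _STD_SPLIT, 0, 0, 8, 5, 2, 0.05, 0, 0, 2, 8, 60, 0.33, 0.50, 160, 0.6),
    "nutritional_supplements": GroupArchetype(2, 1, 1.0, 0.5, 0.5, _STD_SPLIT, 0, 0, 50, 9000, 5000, 900, 330, 160, 13000, 4000, 0, 0.25, 0.90, 1.5, 0.3),
}

assert set(ARCHETYPES) == set(GROUP_IDS)

_OCCASIONS = ("breakfast", "morning_snack", "lunch", "afternoon_snack", "dinner", "evening_snack")
_METHODS = ("weighed", "manufacturer", "atlas", "average_portion", "household", "estimated")
_METHOD_P = (0.45, 0.15, 0.14, 0.14, 0.09, 0.03)


@dataclass
class Cohort:
    """A complete synthetic cohort: the six input tables of the pipeline."""

    profiles: pd.DataFrame
    composition: pd.DataFrame
    gi_table: pd.DataFrame
    analogue_map: pd.DataFrame
    recipes: pd.DataFrame
    diaries: pd.DataFrame
    underreported_ids: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the six input CSVs; returns name -> path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("profiles", "composition", "gi_table",
                     "analogue_map", "recipes", "diaries"):
            df = getattr(self, name)
            fname = "diary.csv" if name == "diaries" else f"{name}.csv"
            path = out_dir / fname
            df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
            paths[name] = path
        return paths


#: arm-neutral base rate of regular supplement use; any arm difference comes
#: exclusively through arm_effects["nutritional_supplements"] so the null
#: configuration (no arm effects) leaves the arms fully exchangeable
SUPPLEMENT_USE_P = 0.32


def _odds_tilt(p: float, effect: float) -> float:
    """Multiply the odds of a Bernoulli gate by ``effect``."""
    if p >= 1.0:
        return 1.0
    odds = p / (1.0 - p) * effect
    return odds / (1.0 + odds)


def _generate_profiles(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_pairs
    supp_effect = config.arm_effects.get("nutritional_supplements", 1.0)
    supp_p = {"T2DM": _odds_tilt(SUPPLEMENT_USE_P, supp_effect), "ND": SUPPLEMENT_USE_P}
    sex = np.where(rng.random(n) < 0.637, "male", "female")
    age_case = np.clip(rng.normal(57.4, 5.6, n), 30, 75)
    age_ctrl = np.clip(age_case + rng.uniform(-2, 2, n), 30, 75)
    height = np.where(
        sex == "male", rng.normal(1.74, 0.06, n), rng.normal(1.61, 0.06, n)
    ).clip(1.45, 2.0)
    bmi_case = np.clip(rng.normal(32.5, 5.8, n), 21, 50)
    bmi_ctrl = np.clip(bmi_case + rng.uniform(-1.5, 1.5, n), 20, 50)
    social = rng.choice(len(SOCIAL_CLASSES), size=n, p=[0.45, 0.22, 0.19, 0.14])

    rows = []
    for i in range(n):
        pair_id = f"PR{i + 1:04d}"
        for arm, age, bmi in (
            ("T2DM", age_case[i], bmi_case[i]),
            ("ND", age_ctrl[i], bmi_ctrl[i]),
        ):
            rows.append(
                {
                    "participant_id": f"{'T' if arm == 'T2DM' else 'N'}{i + 1:04d}",
                    "arm": arm,
                    "pair_id": pair_id,
                    "sex": sex[i],
                    "age": round(float(age), 1),
                    "weight": round(float(bmi * height[i] ** 2), 1),
                    "height": round(float(height[i]), 3),
                    "social_class": SOCIAL_CLASSES[social[i]],
                    "supplement_user": bool(rng.random() < supp_p[arm]),
                }
            )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def _allocate_catalogue(config: SyntheticConfig, rng: np.random.Generator) -> dict[str, int]:
    counts = {gid: 2 for gid in GROUP_IDS}
    extras = config.food_catalogue_size - 2 * len(GROUP_IDS)
    weights = np.array([ARCHETYPES[g].consumer_p for g in GROUP_IDS])
    picks = rng.choice(len(GROUP_IDS), size=extras, p=weights / weights.sum())
    for idx in picks:
        counts[GROUP_IDS[idx]] += 1
    return counts


def _generate_catalogue(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Composition table + GI reference table + analogue map + recipes."""
    counts = _allocate_catalogue(config, rng)
    comp_rows, gi_rows, analogue_rows, recipe_rows = [], [], [], []
    covered_codes: list[str] = []  # codes with direct reference rows, for analogues/recipes

    for gid in GROUP_IDS:
        arch = ARCHETYPES[gid]
        for k in range(counts[gid]):
            code = f"{gid}.{k + 1:02d}"
            jitter = np.exp(rng.normal(0, 0.12, 16))
            carb = arch.carb * jitter[0]
            sugars = min(arch.sugars * jitter[1], carb)
            protein = arch.protein * jitter[2]
            fat = arch.fat * jitter[3]
            alcohol = arch.alcohol * jitter[4]
            sat, mufa, pufa = (s * fat for s in arch.fat_split)
            rec = {
                "food_code": code,
                "description": f"{FOOD_GROUPS[gid]} (variant {k + 1})",
                "group_id": gid,
                "is_supplement": gid == "nutritional_supplements",
                "energy_kcal": 4.0 * protein + 9.0 * fat + 3.75 * carb + 7.0 * alcohol,
                "protein_g": protein,
                "fat_g": fat,
                "satfat_g": sat,
                "mufa_g": mufa,
                "pufa_g": pufa,
                "carb_g": carb,
                "starch_g": carb - sugars,
                "sugars_g": sugars,
                "nonmilk_sugars_g": arch.nm_frac * sugars,
                "fibre_g": arch.fibre * jitter[5],
                "alcohol_g": alcohol,
                "sodium_mg": arch.sodium * jitter[6],
                "calcium_mg": arch.calcium * jitter[7],
                "magnesium_mg": arch.magnesium * jitter[8],
                "iron_mg": arch.iron * jitter[9],
                "vitamin_d_ug": arch.vitd * jitter[10],
                "vitamin_b12_ug": arch.b12 * jitter[11],
                "folate_ug": arch.folate * jitter[12],
                "vitamin_c_mg": arch.vitc * jitter[13],
            }
            comp_rows.append(rec)

            if carb <= 5.0:
                continue  # low-carb rule will fire; no reference coverage needed
            true_gi = float(np.clip(rng.normal(arch.gi, 4.0), 15, 115))
            u = rng.random()
            if u < 0.30:  # single UK study
                gi_rows.append({"food_code": code, "gi": round(true_gi, 1), "country_tag": "UK"})
                covered_codes.append(code)
            elif u < 0.50:  # single non-UK study
                gi_rows.append({"food_code": code, "gi": round(true_gi, 1), "country_tag": "other"})
                covered_codes.append(code)
            elif u < 0.70:  # multiple published values, mixed countries
                n_rows = int(rng.integers(2, 4))
                tags = rng.random(n_rows) < 0.4
                for is_uk in tags:
                    gi_rows.append(
                        {
                            "food_code": code,
                            "gi": round(float(np.clip(rng.normal(true_gi, 6.0), 15, 115)), 1),
                            "country_tag": "UK" if is_uk else "other",
                        }
                    )
                covered_codes.append(code)
            elif u < 0.80:  # analogue imputation
                if covered_codes:
                    analogue_rows.append(
                        {"food_code": code, "analogue_code": covered_codes[int(rng.integers(len(covered_codes)))]}
                    )
            elif u < 0.90:  # composite dish
                if len(covered_codes) >= 2:
                    n_comp = int(rng.integers(2, 4))
                    comps = rng.choice(len(covered_codes), size=min(n_comp, len(covered_codes)), replace=False)
                    shares = rng.dirichlet(np.ones(len(comps)) * 1.2)
                    for ci, share in zip(comps, shares):
                        recipe_rows.append(
                            {"dish_code": code, "component_code": covered_codes[ci], "carb_share": float(share)}
                        )
            # else: no coverage -> default GI 50

    composition = pd.DataFrame(comp_rows, columns=COMPOSITION_COLUMNS)
    gi_table = pd.DataFrame(gi_rows, columns=["food_code", "gi", "country_tag"])
    analogue_map = pd.DataFrame(analogue_rows, columns=["food_code", "analogue_code"])
    recipes = pd.DataFrame(recipe_rows, columns=["dish_code", "component_code", "carb_share"])
    # normalise recipe shares exactly to 1 per dish (dirichlet already sums to 1,
    # but rounding on write must not break the reader's tolerance)
    if len(recipes):
        totals = recipes.groupby("dish_code")["carb_share"].transform("sum")
        recipes["carb_share"] = recipes["carb_share"] / totals
    return composition, gi_table, analogue_map, recipes


def _generate_diaries(
    config: SyntheticConfig,
    rng: np.random.Generator,
    profiles: pd.DataFrame,
    composition: pd.DataFrame,
) -> pd.DataFrame:
    n_part = len(profiles)
    days = config.recording_days
    is_t2dm = (profiles["arm"] == "T2DM").to_numpy()
    supplement_user = profiles["supplement_user"].to_numpy(dtype=bool)
    portion_mult = np.exp(rng.normal(0.0, 0.18, n_part))  # person-level appetite
    weekend_day = rng.integers(1, days + 1, size=n_part)

    # occasion is a free label; occasion_lambda bounds the label variety/day
    n_labels = int(np.clip(round(config.occasion_lambda * 2), 1, len(_OCCASIONS)))
    occasions = _OCCASIONS[:n_labels]

    foods_by_group = {
        gid: composition.loc[composition["group_id"] == gid, "food_code"].to_numpy()
        for gid in GROUP_IDS
    }

    frames = []
    for gid in GROUP_IDS:
        arch = ARCHETYPES[gid]
        effect = config.arm_effects.get(gid, 1.0)
        p = np.full(n_part, arch.consumer_p)
        odds = p / (1 - p + 1e-12) * np.where(is_t2dm, effect, 1.0)
        p_arm = np.where(p >= 1.0, 1.0, odds / (1 + odds))
        if gid == "nutritional_supplements":
            # gate decided at profile level (arm tilt already applied there);
            # the effect must not also shrink the dose of those who do take them
            consumer = supplement_user
            effect = 1.0
        else:
            consumer = rng.random(n_part) < p_arm

        eat = rng.random((n_part, days)) < arch.day_p
        eat &= consumer[:, None]
        if gid == "low_energy_beverages":
            eat[:] = True  # guarantees every participant-day has an entry
        idx_part, idx_day = np.nonzero(eat)
        if not len(idx_part):
            continue
        amount_scale = np.where(is_t2dm[idx_part], effect, 1.0)
        amounts = (
            arch.daily_g * PORTION_SCALE * amount_scale * portion_mult[idx_part]
            * np.exp(rng.normal(0.0, arch.sigma, len(idx_part)))
        )
        foods = foods_by_group[gid][rng.integers(0, len(foods_by_group[gid]), len(idx_part))]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": profiles["participant_id"].to_numpy()[idx_part],
                    "day_index": idx_day + 1,
                    "is_weekend": (idx_day + 1) == weekend_day[idx_part],
                    "occasion": rng.choice(occasions, size=len(idx_part)),
                    "food_code": foods,
                    "amount": np.round(amounts, 1),
                    "method": rng.choice(_METHODS, size=len(idx_part), p=_METHOD_P),
                    "location": np.where(rng.random(len(idx_part)) < 0.85, "home", "out"),
                }
            )
        )
    diary = pd.concat(frames, ignore_index=True)
    diary = diary.sort_values(
        ["participant_id", "day_index", "occasion", "food_code"], kind="mergesort"
    ).reset_index(drop=True)
    return diary[DIARY_COLUMNS]


def inject_underreporting(
    diaries: pd.DataFrame,
    profiles: pd.DataFrame,
    fraction: float,
    scale_range: tuple[float, float] = (0.6, 0.95),
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Deflate a random subset of participants' reported amounts.

    Each selected participant's every amount is multiplied by one factor
    drawn uniformly from ``scale_range``. Returns (modified copy, altered ids).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError(f"fraction must be in [0,1], got {fraction}")
    if not len(diaries):
        raise ConfigError("empty diaries")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = profiles["participant_id"].to_numpy()
    selected = ids[rng.random(len(ids)) < fraction]
    out = diaries.copy()
    if len(selected):
        factors = pd.Series(
            rng.uniform(scale_range[0], scale_range[1], len(selected)), index=selected
        )
        mask = out["participant_id"].isin(factors.index)
        out.loc[mask, "amount"] = (
            out.loc[mask, "amount"].to_numpy()
            * factors.reindex(out.loc[mask, "participant_id"]).to_numpy()
        )
    return out, sorted(selected.tolist())


def generate_cohort(config: SyntheticConfig | None = None, **kwargs) -> Cohort:
    """Generate a complete synthetic cohort (deterministic given the seed)."""
    if config is None:
        config = SyntheticConfig(**kwargs)
    elif kwargs:
        config = config.model_copy(update=kwargs)
    rng = np.random.default_rng(config.seed)
    profiles = _generate_profiles(config, rng)
    composition, gi_table, analogue_map, recipes = _generate_catalogue(config, rng)
    diaries = _generate_diaries(config, rng, profiles, composition)
    underreported: list[str] = []
    if config.underreport_fraction > 0:
        diaries, underreported = inject_underreporting(
            diaries, profiles, config.underreport_fraction, config.underreport_scale, rng
        )
    return Cohort(
        profiles=profiles,
        composition=composition,
        gi_table=gi_table,
        analogue_map=analogue_map,
        recipes=recipes,
        diaries=diaries,
        underreported_ids=underreported,
    )
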