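"""The 38-group food classification used throughout the pipeline.

Foods are aggregated into 38 mutually exclusive, exhaustive groups of the
kind used in national adult nutrition surveys, with breakfast cereals split
into refined and wholegrain variants and nutritional supplements kept as
their own group so their contribution to micronutrient intake can be
isolated.
"""

from __future__ import annotations

# group_id -> display name; order is the canonical reporting order.
FOOD_GROUPS: dict[str, str] = {
    "white_bread": "White bread and rolls",
    "wholemeal_brown_bread": "Wholemeal and brown bread and rolls",
    "wholegrain_bread": "Wholegrain breads",
    "pasta_rice_grains": "Pasta, rice and grains",
    "refined_breakfast_cereals": "Refined breakfast cereals",
    "wholegrain_breakfast_cereals": "Wholegrain breakfast cereals",
    "biscuits": "Biscuits",
    "cakes_pastries_buns": "Cakes, pastries and buns",
    "creams_desserts": "Creams, ice creams and desserts",
    "full_fat_milk_yogurt": "Full-fat milk and yogurts",
    "low_fat_milk_yogurt": "Low-fat milk and yoghurts",
    "cheeses": "Cheeses",
    "sugars_syrups_preserves": "Sugars, syrups, preserves and sweeteners",
    "chocolate_confectionery": "Chocolate confectionery",
    "non_chocolate_confectionery": "Non-chocolate confectionery",
    "eggs": "Eggs and egg dishes",
    "butter_full_fat_spreads": "Butter and full-fat spreads",
    "lower_fat_spreads": "Lower-fat spreads",
    "oils": "Oils",
    "potatoes": "Potatoes incl. processed/homemade potato",
    "chipped_fried_roast_potatoes": "Chipped, fried and roasted potato",
    "peas_beans_lentils": "Peas, beans and lentils",
    "other_vegetables": "Other vegetables",
    "fruit": "Fruit",
    "fruit_juices": "Fruit juices",
    "white_fish_shellfish": "White fish and shellfish",
    "oily_fish": "Oily fish",
    "poultry": "Poultry",
    "red_meat": "Red meat",
    "other_meat_products": "Other meat and meat products",
    "savoury_snacks": "Savoury snacks",
    "herbs_spices_nuts_seeds": "Herbs, spices, nuts and seeds",
    "soups_sauces": "Soups and sauces",
    "savouries": "Savouries",
    "alcoholic_beverages": "Alcoholic beverages",
    "low_energy_beverages": "Low-energy beverages",
    "high_energy_beverages": "High-energy beverages",
    "nutritional_supplements": "Nutritional supplements",
}

GROUP_IDS: list[str] = list(FOOD_GROUPS)

N_GROUPS = len(GROUP_IDS)
assert N_GROUPS == 38


def validate_group_id(group_id: str) -> str:
    if group_id not in FOOD_GROUPS:
        raise KeyError(f"unknown food group id: {group_id!r}")
    return group_id
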