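"""Walk every branch of the GI assignment hierarchy on hand-built tables.

Each food below triggers a different rule; the printed rule and value show
the precedence order: low-carb zero, reference match (UK preferred, mean of
matches), composite recipe, analogue, default 50.
"""

import pandas as pd

import glycodiary as gd

gi_table = pd.DataFrame(
    [("white_loaf", 70.0, "UK"), ("white_loaf", 95.0, "other"),
     ("basmati", 57.0, "other"), ("basmati", 63.0, "other"),
     ("potato_boiled", 78.0, "UK")],
    columns=["food_code", "gi", "country_tag"],
)
analogues = pd.DataFrame({"food_code": ["spelt_loaf"], "analogue_code": ["white_loaf"]})
recipes = pd.DataFrame(
    {"dish_code": ["shepherds_pie"] * 2,
     "component_code": ["potato_boiled", "white_loaf"],
     "carb_share": [0.8, 0.2]}
)

foods = [
    ("cheddar", 0.1),        # low-carb zero
    ("white_loaf", 47.0),    # UK rows preferred over the non-UK 95
    ("basmati", 28.0),       # mean of two non-UK studies
    ("shepherds_pie", 12.0), # composite: potato dominates at 80% of carb
    ("spelt_loaf", 40.0),    # analogue of white_loaf
    ("novel_bar", 30.0),     # nothing matches -> default 50
]

for code, carb in foods:
    a = gd.assign_gi(pd.Series({"food_code": code, "carb_g": carb}),
                     gi_table, analogues, recipes)
    src = f" (from {', '.join(a.source_codes)})" if a.source_codes else ""
    print(f"{code:<14} carb {carb:>5.1f} g/100g -> GI {a.gi:5.1f}  rule={a.rule}{src}")
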