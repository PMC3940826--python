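"""Dietary GI and glycaemic load for a synthetic cohort.

Assigns GIs across the whole catalogue, then computes each participant's
carbohydrate-weighted dietary GI and mean daily glycaemic load. Dietary GI
is dimensionless (glucose = 100); GL has units of GI-weighted grams of
carbohydrate per day — values near 100-150 are typical adult diets.
"""

import glycodiary as gd
from glycodiary.gi import rule_counts

cohort = gd.generate_cohort(n_pairs=30, seed=7)
assignments = gd.assign_all(cohort.composition, cohort.gi_table,
                            cohort.analogue_map, cohort.recipes)
print("GI rule frequencies over the catalogue:")
for rule, n in rule_counts(assignments).items():
    if n:
        print(f"  {rule:<22} {n}")

glyc = gd.glycaemic_summary(cohort.diaries, cohort.composition, assignments)
arm = cohort.profiles.set_index("participant_id")["arm"]
glyc["arm"] = glyc["participant_id"].map(arm)

print("\nper-arm dietary GI and GL (median):")
print(glyc.groupby("arm")[["dietary_gi", "dietary_gl"]].median().round(1))
print("\nDietary GI hovers near the catalogue's carb-weighted GI; GL differs"
      "\nbetween arms when the arms eat different amounts of carbohydrate.")
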