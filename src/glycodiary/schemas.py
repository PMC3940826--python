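"""Column schemas for all delimited input and output tables.

All tables are comma-separated UTF-8 with "." as the decimal separator.
Output schemas carry a deterministic column order and sort keys so that a
re-run on identical inputs is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: per-100 g nutrient columns of the food composition table, in canonical order
NUTRIENT_COLUMNS: list[str] = [
    "energy_kcal",
    "protein_g",
    "fat_g",
    "satfat_g",
    "mufa_g",
    "pufa_g",
    "carb_g",          # available carbohydrate (monosaccharide equivalents)
    "starch_g",
    "sugars_g",
    "nonmilk_sugars_g",
    "fibre_g",
    "alcohol_g",
    "sodium_mg",
    "calcium_mg",
    "magnesium_mg",
    "iron_mg",
    "vitamin_d_ug",
    "vitamin_b12_ug",
    "folate_ug",
    "vitamin_c_mg",
]

PROFILE_COLUMNS = [
    "participant_id", "arm", "pair_id", "sex", "age",
    "weight", "height", "social_class", "supplement_user",
]

DIARY_COLUMNS = [
    "participant_id", "day_index", "is_weekend", "occasion",
    "food_code", "amount", "method", "location",
]

COMPOSITION_COLUMNS = (
    ["food_code", "description", "group_id", "is_supplement"] + NUTRIENT_COLUMNS
)

GI_TABLE_COLUMNS = ["food_code", "gi", "country_tag"]
ANALOGUE_MAP_COLUMNS = ["food_code", "analogue_code"]
RECIPE_COLUMNS = ["dish_code", "component_code", "carb_share"]

ARMS = ("T2DM", "ND")
SEXES = ("male", "female")
SOCIAL_CLASSES = (
    "professional_managerial_technical",
    "non_manual_skilled",
    "manual_skilled",
    "semiskilled_unskilled",
)
QUANTIFICATION_METHODS = (
    "weighed", "manufacturer", "atlas", "average_portion", "household", "estimated",
)
LOCATIONS = ("home", "out")
COUNTRY_TAGS = ("UK", "other")


@dataclass(frozen=True)
class OutputSchema:
    """Declared column order and sort keys of one output table."""

    schema_id: str
    columns: list[str]
    sort_keys: list[str] = field(default_factory=list)


def _schema(schema_id: str, columns: list[str], sort_keys: list[str]) -> OutputSchema:
    return OutputSchema(schema_id=schema_id, columns=columns, sort_keys=sort_keys)


_ARM_STATS = [
    "t2dm_median", "t2dm_q1", "t2dm_q3",
    "nd_median", "nd_q1", "nd_q3",
]

OUTPUT_SCHEMAS: dict[str, OutputSchema] = {
    s.schema_id: s
    for s in [
        _schema(
            "table1",
            ["variable", "kind", "test", "n_pairs",
             "t2dm_summary", "nd_summary", "statistic", "p_value"],
            ["variable"],
        ),
        _schema(
            "table2",
            ["variable"] + _ARM_STATS
            + ["t2dm_meeting_pct", "nd_meeting_pct", "test", "statistic", "p_value"],
            ["variable"],
        ),
        _schema(
            "table3",
            ["group_id", "display_name",
             "t2dm_median", "t2dm_q1", "t2dm_q3", "t2dm_min", "t2dm_max",
             "t2dm_pct_consumers",
             "t2dm_cons_median", "t2dm_cons_q1", "t2dm_cons_q3",
             "nd_median", "nd_q1", "nd_q3", "nd_min", "nd_max",
             "nd_pct_consumers",
             "nd_cons_median", "nd_cons_q1", "nd_cons_q3",
             "statistic", "p_value"],
            ["group_id"],
        ),
        _schema(
            "table4",
            ["group_id", "nutrient"] + _ARM_STATS + ["statistic", "p_value"],
            ["nutrient", "group_id"],
        ),
        _schema(
            "fig1",
            ["rank", "group_id", "display_name"] + _ARM_STATS
            + ["statistic", "p_value"],
            ["rank"],
        ),
        _schema(
            "flags",
            ["participant_id", "arm", "ei", "bmr", "ratio", "flagged"],
            ["participant_id"],
        ),
        _schema(
            "comparisons",
            ["variable", "family", "test", "route_reason", "n_pairs",
             "statistic", "p_value", "p_bh", "significant"],
            ["family", "variable"],
        ),
    ]
}
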