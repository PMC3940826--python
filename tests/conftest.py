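"""Shared fixtures: small synthetic cohorts and written input directories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import glycodiary as gd
from glycodiary.schemas import NUTRIENT_COLUMNS


@pytest.fixture(scope="session")
def cohort_small() -> gd.Cohort:
    """An 8-pair cohort with default settings (under-reporting included)."""
    return gd.generate_cohort(n_pairs=8, seed=42)


@pytest.fixture(scope="session")
def analysis_small(cohort_small: gd.Cohort) -> gd.AnalysisResult:
    c = cohort_small
    return gd.analyse(c.profiles, c.diaries, c.composition,
                      c.gi_table, c.analogue_map, c.recipes)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, cohort_small: gd.Cohort):
    """The small cohort written out as the six input CSVs."""
    out = tmp_path_factory.mktemp("cohort")
    cohort_small.write(out)
    return out


def make_composition(rows: list[dict]) -> pd.DataFrame:
    """Build a composition frame from sparse dicts (unnamed nutrients -> 0)."""
    out = []
    for row in rows:
        rec = {c: 0.0 for c in NUTRIENT_COLUMNS}
        rec.update({"description": row.get("food_code", ""), "group_id": "other_vegetables",
                    "is_supplement": False})
        rec.update(row)
        out.append(rec)
    df = pd.DataFrame(out)
    cols = ["food_code", "description", "group_id", "is_supplement"] + NUTRIENT_COLUMNS
    return df[cols]


def make_diary(entries: list[tuple], participant: str = "P1") -> pd.DataFrame:
    """Diary frame from (day, food_code, grams) tuples."""
    return pd.DataFrame(
        [
            {"participant_id": participant, "day_index": day, "is_weekend": day == 4,
             "occasion": "lunch", "food_code": code, "amount": float(amount),
             "method": "weighed", "location": "home"}
            for day, code, amount in entries
        ]
    )


EMPTY_GI = pd.DataFrame(columns=["food_code", "gi", "country_tag"])
EMPTY_ANALOGUES = pd.DataFrame(columns=["food_code", "analogue_code"])
EMPTY_RECIPES = pd.DataFrame(columns=["dish_code", "component_code", "carb_share"])


def gi_rows(*rows: tuple[str, float, str]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["food_code", "gi", "country_tag"])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
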