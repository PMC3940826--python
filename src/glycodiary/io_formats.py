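"""Reading, validation and writing of all delimited tables.

Input tables are comma-separated UTF-8. Validation is strict: structural
violations (broken pairs, short diaries, unresolved food codes, blank
nutrient cells) raise rather than silently dropping rows, so every number
downstream is backed by a fully resolved diary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import schemas
from .errors import (
    CompositionError,
    CoverageError,
    PairingError,
    SchemaError,
    UnresolvedCodeError,
    WeekendRuleError,
)
from .groups import FOOD_GROUPS
from .schemas import (
    ANALOGUE_MAP_COLUMNS,
    ARMS,
    COMPOSITION_COLUMNS,
    COUNTRY_TAGS,
    DIARY_COLUMNS,
    GI_TABLE_COLUMNS,
    LOCATIONS,
    NUTRIENT_COLUMNS,
    OUTPUT_SCHEMAS,
    PROFILE_COLUMNS,
    QUANTIFICATION_METHODS,
    RECIPE_COLUMNS,
    SEXES,
    SOCIAL_CLASSES,
)

#: tolerance for the sub-component nutrient invariants (g per 100 g)
_NUTRIENT_TOL = 0.5


def _read_csv(path: str | Path, required: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{name} file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} {path} missing columns: {missing}")
    return df


def _to_float(df: pd.DataFrame, cols: list[str], name: str) -> pd.DataFrame:
    for col in cols:
        blank = df[col].astype(str).str.strip() == ""
        if blank.any():
            rows = df.index[blank].tolist()[:10]
            raise SchemaError(
                f"{name}: column {col!r} has blank values (rows {rows}); "
                "missing values must be recorded as 0, not left empty"
            )
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise SchemaError(f"{name}: column {col!r} is not numeric: {exc}") from exc
    return df


def _to_bool(series: pd.Series, name: str, col: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    vals = series.astype(str).str.strip().str.lower()
    bad = ~vals.isin(mapping)
    if bad.any():
        raise SchemaError(f"{name}: column {col!r} has non-boolean values: "
                          f"{sorted(series[bad].unique())[:5]}")
    return vals.map(mapping)


def _check_enum(series: pd.Series, allowed: tuple[str, ...], name: str, col: str) -> None:
    bad = ~series.isin(allowed)
    if bad.any():
        raise SchemaError(
            f"{name}: column {col!r} has values outside {allowed}: "
            f"{sorted(series[bad].unique())[:5]}"
        )


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read participant profiles and enforce the matched-pair invariants.

    Returns a DataFrame with a derived ``bmi`` column. Each pair_id must map
    to exactly one T2DM and one ND member of the same sex.
    """
    df = _read_csv(path, PROFILE_COLUMNS, "profiles")
    df = _to_float(df, ["age", "weight", "height"], "profiles")
    df["supplement_user"] = _to_bool(df["supplement_user"], "profiles", "supplement_user")
    _check_enum(df["arm"], ARMS, "profiles", "arm")
    _check_enum(df["sex"], SEXES, "profiles", "sex")
    _check_enum(df["social_class"], SOCIAL_CLASSES, "profiles", "social_class")

    if df["participant_id"].duplicated().any():
        dups = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise SchemaError(f"profiles: duplicated participant ids {dups[:5]}")
    if (df["age"] <= 18).any() or (df["weight"] <= 0).any() or (df["height"] <= 0).any():
        raise SchemaError("profiles: age must be > 18 and weight/height > 0")

    bad_pairs: list[str] = []
    for pair_id, grp in df.groupby("pair_id"):
        arms = sorted(grp["arm"])
        if len(grp) != 2 or arms != ["ND", "T2DM"]:
            bad_pairs.append(str(pair_id))
        elif grp["sex"].nunique() != 1:
            bad_pairs.append(str(pair_id))
    if bad_pairs:
        raise PairingError(
            f"pairs must contain exactly one T2DM and one ND member of the same "
            f"sex; offending pair ids: {bad_pairs[:10]}",
            pair_ids=bad_pairs,
        )

    df["bmi"] = df["weight"] / df["height"] ** 2
    return df.reset_index(drop=True)


def read_diary(
    path: str | Path,
    composition: pd.DataFrame | None = None,
    expected_days: int = 4,
    require_weekend: bool = True,
) -> pd.DataFrame:
    """Read diary entries and enforce the recording protocol.

    Every participant must cover exactly ``expected_days`` distinct day
    indices (1..expected_days) and, if ``require_weekend``, record at least
    one weekend day. If a composition table is given, every food code must
    resolve against it.
    """
    df = _read_csv(path, DIARY_COLUMNS, "diary")
    df = _to_float(df, ["amount"], "diary")
    df["day_index"] = df["day_index"].astype(int)
    df["is_weekend"] = _to_bool(df["is_weekend"], "diary", "is_weekend")
    _check_enum(df["method"], QUANTIFICATION_METHODS, "diary", "method")
    _check_enum(df["location"], LOCATIONS, "diary", "location")

    if (df["amount"] < 0).any() or not np.isfinite(df["amount"]).all():
        raise SchemaError("diary: amounts must be finite and non-negative")
    out_of_range = (df["day_index"] < 1) | (df["day_index"] > expected_days)
    if out_of_range.any():
        raise CoverageError(
            f"diary: day_index outside 1..{expected_days} for participants "
            f"{sorted(df.loc[out_of_range, 'participant_id'].unique())[:5]}"
        )

    short = []
    for pid, grp in df.groupby("participant_id"):
        if grp["day_index"].nunique() != expected_days:
            short.append(str(pid))
    if short:
        raise CoverageError(
            f"participants not covering exactly {expected_days} recorded days: {short[:10]}",
            participant_ids=short,
        )
    if require_weekend:
        weekendless = [
            str(pid) for pid, grp in df.groupby("participant_id")
            if not grp["is_weekend"].any()
        ]
        if weekendless:
            raise WeekendRuleError(
                f"participants with no recorded weekend day: {weekendless[:10]}",
                participant_ids=weekendless,
            )

    if composition is not None:
        known = set(composition["food_code"])
        unresolved = sorted(set(df["food_code"]) - known)
        if unresolved:
            raise UnresolvedCodeError(
                f"{len(unresolved)} diary food codes missing from the composition "
                f"table: {unresolved[:20]}",
                codes=unresolved,
            )
    return df.reset_index(drop=True)


def read_composition(path: str | Path) -> pd.DataFrame:
    """Read the per-100 g food composition table and check nutrient invariants."""
    df = _read_csv(path, COMPOSITION_COLUMNS, "composition")
    df = _to_float(df, NUTRIENT_COLUMNS, "composition")
    df["is_supplement"] = _to_bool(df["is_supplement"], "composition", "is_supplement")

    if df["food_code"].duplicated().any():
        raise SchemaError("composition: duplicated food codes")
    unknown = set(df["group_id"]) - set(FOOD_GROUPS)
    if unknown:
        raise SchemaError(f"composition: unknown group ids {sorted(unknown)[:5]}")
    neg = df[NUTRIENT_COLUMNS].lt(0).any(axis=1)
    if neg.any():
        raise CompositionError(
            f"composition: negative nutrient values for codes "
            f"{df.loc[neg, 'food_code'].tolist()[:5]}"
        )
    fat_parts = df["satfat_g"] + df["mufa_g"] + df["pufa_g"]
    if (fat_parts > df["fat_g"] + _NUTRIENT_TOL).any():
        raise CompositionError("composition: SFA+MUFA+PUFA exceeds total fat")
    carb_parts = df["starch_g"] + df["sugars_g"]
    if (carb_parts > df["carb_g"] + _NUTRIENT_TOL).any():
        raise CompositionError("composition: starch+sugars exceeds available carbohydrate")
    if (df["nonmilk_sugars_g"] > df["sugars_g"] + _NUTRIENT_TOL).any():
        raise CompositionError("composition: non-milk sugars exceed total sugars")
    return df.reset_index(drop=True)


def read_gi_table(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, GI_TABLE_COLUMNS, "gi_table")
    df = _to_float(df, ["gi"], "gi_table")
    _check_enum(df["country_tag"], COUNTRY_TAGS, "gi_table", "country_tag")
    if (df["gi"] < 0).any():
        raise SchemaError("gi_table: GI values must be >= 0")
    return df.reset_index(drop=True)


def read_analogue_map(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ANALOGUE_MAP_COLUMNS, "analogue_map")
    if df["food_code"].duplicated().any():
        raise SchemaError("analogue_map: duplicated food codes")
    return df.reset_index(drop=True)


def read_recipes(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, RECIPE_COLUMNS, "recipes")
    df = _to_float(df, ["carb_share"], "recipes")
    if (df["carb_share"] <= 0).any():
        raise SchemaError("recipes: carb shares must be > 0")
    bad = [
        str(dish) for dish, grp in df.groupby("dish_code")
        if abs(grp["carb_share"].sum() - 1.0) > 1e-6
    ]
    if bad:
        raise SchemaError(f"recipes: carb shares must sum to 1 per dish; offending: {bad[:5]}")
    return df.reset_index(drop=True)


def write_table(rows: pd.DataFrame | list[dict], path: str | Path, schema_id: str) -> Path:
    """Write an output table under a registered schema.

    Columns and row order are deterministic (sorted by the schema's keys);
    floats are written with 12 significant digits so a read-back reproduces
    them to that precision.
    """
    if schema_id not in OUTPUT_SCHEMAS:
        raise SchemaError(f"unknown output schema id: {schema_id!r}")
    schema = OUTPUT_SCHEMAS[schema_id]
    df = pd.DataFrame(rows, columns=schema.columns) if not isinstance(rows, pd.DataFrame) else rows.copy()
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"rows for schema {schema_id!r} missing columns {missing}")
    df = df[schema.columns]
    if len(df) and schema.sort_keys:
        df = df.sort_values(schema.sort_keys, kind="mergesort")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
    return path


def read_output_table(path: str | Path, schema_id: str) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    if schema_id not in OUTPUT_SCHEMAS:
        raise SchemaError(f"unknown output schema id: {schema_id!r}")
    return pd.read_csv(path)
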