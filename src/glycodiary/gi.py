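"""Hierarchical glycaemic-index assignment and dietary GI / glycaemic load.

Every food receives exactly one GI through a fixed rule hierarchy:

1. ``low_carb_zero`` — foods with <= 5 g available carbohydrate per 100 g are
   given GI 0 (a property of the food itself, so it is checked first);
2. reference-table match — the mean of matching published values, restricted
   to UK-study values when any exist (``direct`` for a single match,
   ``uk_preferred`` when the UK restriction discarded other rows,
   ``mean_of_matches`` otherwise);
3. composite dishes — the GI of the predominant carbohydrate source, or the
   mean GI of the carbohydrate sources when none dominates;
4. ``analogue_imputed`` — the GI of a closely equivalent food;
5. ``default_50`` — GI 50 when nothing above applies.

Dietary GI is the carbohydrate-weighted mean GI of everything eaten in a
day; dietary glycaemic load is sum(GI/100 x available carbohydrate (g)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fnmatch import fnmatchcase

import numpy as np
import pandas as pd

from .config import GIConfig
from .errors import CompositionError, DegenerateDataError, UnresolvedCodeError

RULES = (
    "direct",
    "mean_of_matches",
    "uk_preferred",
    "analogue_imputed",
    "low_carb_zero",
    "composite_predominant",
    "composite_mean",
    "default_50",
)


@dataclass(frozen=True)
class GIAssignment:
    """One food's assigned GI and the hierarchy rule that produced it."""

    food_code: str
    gi: float
    rule: str
    source_codes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown GI rule {self.rule!r}")
        if self.gi < 0:
            raise ValueError("assigned GI must be >= 0")


def _match_rows(gi_table: pd.DataFrame, food_code: str) -> pd.DataFrame:
    """Reference rows matching a food code: exact matches, else glob patterns."""
    exact = gi_table[gi_table["food_code"] == food_code]
    if len(exact):
        return exact
    has_wild = gi_table["food_code"].str.contains(r"[*?\[]", regex=True)
    if not has_wild.any():
        return exact
    patterns = gi_table[has_wild]
    hits = patterns[
        patterns["food_code"].map(lambda p: fnmatchcase(food_code, p))
    ]
    return hits


def _table_lookup(gi_table: pd.DataFrame, food_code: str) -> tuple[float, str, tuple[str, ...]] | None:
    """Mean GI over matching reference rows, UK studies preferred.

    Returns (gi, rule, source codes) or None if no row matches.
    """
    rows = _match_rows(gi_table, food_code)
    if not len(rows):
        return None
    uk = rows[rows["country_tag"] == "UK"]
    if len(uk):
        gi = float(uk["gi"].mean())
        if len(uk) < len(rows):
            rule = "uk_preferred"
        else:
            rule = "direct" if len(rows) == 1 else "mean_of_matches"
        used = uk
    else:
        gi = float(rows["gi"].mean())
        rule = "direct" if len(rows) == 1 else "mean_of_matches"
        used = rows
    return gi, rule, tuple(used["food_code"])


def resolve_composite(
    components: list[tuple[str, float]],
    gi_table: pd.DataFrame,
    mode: str | None = None,
    dominance_threshold: float = 0.5,
) -> tuple[float, str, tuple[str, ...]]:
    """GI of a composite dish from its carbohydrate-contributing components.

    ``components`` is a list of (component food code, carbohydrate share);
    shares must sum to 1. With ``mode=None`` the predominant component's GI
    is used when its share exceeds ``dominance_threshold``, otherwise the
    unweighted mean GI of all components.
    """
    if not components:
        raise UnresolvedCodeError("empty recipe")
    total = sum(share for _, share in components)
    if abs(total - 1.0) > 1e-6:
        raise CompositionError(f"recipe carb shares sum to {total}, expected 1")
    resolved: list[tuple[str, float, float]] = []
    for code, share in components:
        hit = _table_lookup(gi_table, code)
        if hit is None:
            raise UnresolvedCodeError(f"recipe component {code!r} has no reference GI",
                                      codes=[code])
        resolved.append((code, share, hit[0]))

    codes = tuple(code for code, _, _ in resolved)
    if mode is None:
        top_share = max(share for _, share, _ in resolved)
        mode = "predominant" if top_share > dominance_threshold else "mean"
    if mode == "predominant":
        code, _, gi = max(resolved, key=lambda t: t[1])
        return gi, "composite_predominant", (code,)
    if mode == "mean":
        gi = float(np.mean([g for _, _, g in resolved]))
        return gi, "composite_mean", codes
    raise ValueError(f"unknown composite mode {mode!r}")


def assign_gi(
    food: pd.Series | dict,
    gi_table: pd.DataFrame,
    analogue_map: pd.DataFrame,
    recipes: pd.DataFrame,
    config: GIConfig | None = None,
) -> GIAssignment:
    """Assign a GI to one composition record through the rule hierarchy."""
    config = config or GIConfig()
    code = str(food["food_code"])
    carb = float(food["carb_g"])
    if carb < 0 or not np.isfinite(carb):
        raise CompositionError(f"food {code!r}: invalid available carbohydrate {carb}")

    if carb <= config.low_carb_threshold_g:
        return GIAssignment(code, 0.0, "low_carb_zero")

    hit = _table_lookup(gi_table, code)
    if hit is not None:
        gi, rule, sources = hit
        return GIAssignment(code, gi, rule, sources)

    recipe_rows = recipes[recipes["dish_code"] == code] if len(recipes) else recipes
    if len(recipe_rows):
        try:
            gi, rule, sources = resolve_composite(
                list(zip(recipe_rows["component_code"], recipe_rows["carb_share"].astype(float))),
                gi_table,
                dominance_threshold=config.dominance_threshold,
            )
            return GIAssignment(code, gi, rule, sources)
        except UnresolvedCodeError:
            pass  # fall through to analogue / default

    if len(analogue_map):
        ana = analogue_map[analogue_map["food_code"] == code]
        if len(ana):
            analogue_code = str(ana.iloc[0]["analogue_code"])
            hit = _table_lookup(gi_table, analogue_code)
            if hit is not None:
                return GIAssignment(code, hit[0], "analogue_imputed", (analogue_code,))

    return GIAssignment(code, config.default_gi, "default_50")


def assign_all(
    composition: pd.DataFrame,
    gi_table: pd.DataFrame,
    analogue_map: pd.DataFrame,
    recipes: pd.DataFrame,
    config: GIConfig | None = None,
) -> pd.DataFrame:
    """GI assignments for every composition record.

    Returns a frame (food_code, gi, rule, source_codes); exactly one rule
    fires per food.
    """
    out = [
        assign_gi(row, gi_table, analogue_map, recipes, config)
        for _, row in composition.iterrows()
    ]
    return pd.DataFrame(
        {
            "food_code": [a.food_code for a in out],
            "gi": [a.gi for a in out],
            "rule": [a.rule for a in out],
            "source_codes": ["|".join(a.source_codes) for a in out],
        }
    )


def rule_counts(assignments: pd.DataFrame) -> dict[str, int]:
    """Frequency of each hierarchy rule over an assignment table."""
    counts = assignments["rule"].value_counts().to_dict()
    return {rule: int(counts.get(rule, 0)) for rule in RULES}


# ---------------------------------------------------------------------------
# dietary GI / GL


def item_glycaemic_terms(
    diary: pd.DataFrame,
    composition: pd.DataFrame,
    assignments: pd.DataFrame,
    config: GIConfig | None = None,
) -> pd.DataFrame:
    """Per-item carbohydrate and glycaemic-load terms.

    The returned frame carries one row per diary entry with ``carb_item``
    (g of available carbohydrate in the portion) and ``gl_item``
    (GI/100 x carb). Summing ``gl_item`` within any partition of the items
    (days, food groups) reproduces the corresponding GL exactly, which is
    what the food-group GL decomposition relies on.
    """
    config = config or GIConfig()
    comp = composition.set_index("food_code")
    gi_map = assignments.set_index("food_code")["gi"]

    missing = sorted(set(diary["food_code"]) - set(comp.index))
    if missing:
        raise UnresolvedCodeError(
            f"diary codes missing from composition: {missing[:10]}", codes=missing
        )
    out = diary.copy()
    out["carb_item"] = (
        out["amount"].to_numpy()
        * comp["carb_g"].reindex(out["food_code"]).to_numpy() / 100.0
    )
    gi_values = gi_map.reindex(out["food_code"])
    if gi_values.isna().any():
        missing = sorted(set(out.loc[gi_values.isna().to_numpy(), "food_code"]))
        raise UnresolvedCodeError(
            f"diary codes without a GI assignment: {missing[:10]}", codes=missing
        )
    out["gi_food"] = gi_values.to_numpy()
    scale = 100.0 if config.gl_per_100 else 1.0
    out["gl_item"] = out["gi_food"] * out["carb_item"] / scale
    return out


def dietary_gi_day(day_entries: pd.DataFrame, composition: pd.DataFrame,
                   assignments: pd.DataFrame, config: GIConfig | None = None) -> float | None:
    """Carbohydrate-weighted mean GI of one participant-day.

    Returns None (an undefined day) when the day's total available
    carbohydrate is zero.
    """
    terms = item_glycaemic_terms(day_entries, composition, assignments, config)
    total_carb = terms["carb_item"].sum()
    if total_carb <= 0:
        return None
    return float((terms["gi_food"] * terms["carb_item"]).sum() / total_carb)


def dietary_gl_day(day_entries: pd.DataFrame, composition: pd.DataFrame,
                   assignments: pd.DataFrame, config: GIConfig | None = None) -> float:
    """Glycaemic load of one participant-day (0 for an empty or zero-carb day)."""
    if not len(day_entries):
        return 0.0
    terms = item_glycaemic_terms(day_entries, composition, assignments, config)
    return float(terms["gl_item"].sum())


def per_day_glycaemics(
    diary: pd.DataFrame,
    composition: pd.DataFrame,
    assignments: pd.DataFrame,
    config: GIConfig | None = None,
) -> pd.DataFrame:
    """Per participant-day GI (NaN when undefined), GL and carbohydrate."""
    terms = item_glycaemic_terms(diary, composition, assignments, config)
    terms["gi_weighted"] = terms["gi_food"] * terms["carb_item"]
    agg = (
        terms.groupby(["participant_id", "day_index"], sort=True)
        .agg(carb_g=("carb_item", "sum"),
             gl=("gl_item", "sum"),
             _giw=("gi_weighted", "sum"))
        .reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["gi"] = np.where(agg["carb_g"] > 0, agg["_giw"] / agg["carb_g"], np.nan)
    return agg.drop(columns="_giw")


def glycaemic_summary(
    diary: pd.DataFrame,
    composition: pd.DataFrame,
    assignments: pd.DataFrame,
    config: GIConfig | None = None,
) -> pd.DataFrame:
    """Participant-level dietary GI and GL.

    Dietary GI is the carbohydrate-weighted mean over defined days
    (equivalent to pooling all items); dietary GL is the mean of the per-day
    loads over all recorded days. Participants whose every day has zero
    carbohydrate have no defined dietary GI and raise.
    """
    days = per_day_glycaemics(diary, composition, assignments, config)
    days["_giw"] = days["gi"].fillna(0.0) * days["carb_g"]
    agg = (
        days.groupby("participant_id", sort=True)
        .agg(total_carb=("carb_g", "sum"),
             _giw=("_giw", "sum"),
             dietary_gl=("gl", "mean"),
             n_days=("day_index", "nunique"))
        .reset_index()
    )
    undefined = agg[agg["total_carb"] <= 0]
    if len(undefined):
        raise DegenerateDataError(
            "participants with zero carbohydrate on every recorded day: "
            f"{undefined['participant_id'].tolist()[:10]}"
        )
    agg["dietary_gi"] = agg["_giw"] / agg["total_carb"]
    return agg[["participant_id", "dietary_gi", "dietary_gl", "total_carb", "n_days"]]
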