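"""Food-group aggregation: intakes, consumer statistics and contributions.

Foods are partitioned into the 38-group scheme; per-participant group
intakes are mean g/day over the recording period. "Consumers" of a group
are participants with any positive intake of it on any recorded day.
Contribution tables give each group's percent share of a participant's
energy, carbohydrate, protein, fat or glycaemic load; because every item
belongs to exactly one group the shares sum to 100 exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import GIConfig
from .errors import SchemaError
from .gi import item_glycaemic_terms
from .groups import FOOD_GROUPS, GROUP_IDS

#: nutrients for which contribution tables are produced
CONTRIBUTION_NUTRIENTS = ("energy_kcal", "carb_g", "protein_g", "fat_g", "gl")


def _check_scheme(composition: pd.DataFrame) -> None:
    unknown = set(composition["group_id"]) - set(FOOD_GROUPS)
    if unknown:
        raise SchemaError(f"composition group ids outside the scheme: {sorted(unknown)[:5]}")


def group_amounts(diary: pd.DataFrame, composition: pd.DataFrame) -> pd.DataFrame:
    """Mean g/day of each food group per participant.

    Grams are summed per group per day and averaged over the participant's
    recorded days; groups never eaten appear as 0 so the frame is a complete
    participants x 38 groups grid.
    """
    _check_scheme(composition)
    comp = composition.set_index("food_code")
    group = comp["group_id"].reindex(diary["food_code"]).to_numpy()
    df = pd.DataFrame(
        {
            "participant_id": diary["participant_id"].to_numpy(),
            "day_index": diary["day_index"].to_numpy(),
            "group_id": group,
            "amount": diary["amount"].to_numpy(),
        }
    )
    n_days = df.groupby("participant_id")["day_index"].nunique()
    per_group = (
        df.groupby(["participant_id", "group_id"], sort=True)["amount"].sum().unstack(fill_value=0.0)
    )
    per_group = per_group.reindex(columns=GROUP_IDS, fill_value=0.0)
    per_group = per_group.div(n_days, axis=0)
    per_group.index.name = "participant_id"
    return per_group.reset_index()


def _quantiles(values: np.ndarray) -> dict[str, float]:
    """Median and linear-interpolation (type-7) quartiles, plus range."""
    return {
        "median": float(np.quantile(values, 0.5)),
        "q1": float(np.quantile(values, 0.25)),
        "q3": float(np.quantile(values, 0.75)),
        "min": float(values.min()),
        "max": float(values.max()),
    }


def consumer_stats(amounts: pd.DataFrame, group_id: str) -> dict[str, float]:
    """Total-population and consumers-only summary of one group's intake.

    ``amounts`` is the output of :func:`group_amounts` (one arm's rows).
    Consumers-only statistics are NaN when the group has no consumers.
    """
    if group_id not in amounts.columns:
        raise SchemaError(f"group {group_id!r} absent from amounts table")
    values = amounts[group_id].to_numpy(dtype=float)
    if not len(values):
        raise SchemaError("consumer_stats requires at least one participant")
    out = {f"pop_{k}": v for k, v in _quantiles(values).items()}
    consumers = values[values > 0]
    out["pct_consumers"] = float(100.0 * len(consumers) / len(values))
    if len(consumers):
        out.update({f"cons_{k}": v for k, v in _quantiles(consumers).items()})
    else:
        out.update({f"cons_{k}": float("nan") for k in ("median", "q1", "q3", "min", "max")})
    return out


def contribution(
    diary: pd.DataFrame,
    composition: pd.DataFrame,
    nutrient: str,
    assignments: pd.DataFrame | None = None,
    gi_config: GIConfig | None = None,
) -> pd.DataFrame:
    """Percent contribution of each food group to a participant's intake.

    For ``nutrient="gl"`` the item-level glycaemic-load terms are regrouped,
    so summing group contributions reproduces the participant's total GL
    exactly. Participants with a zero total for the nutrient get all-zero
    rows and ``zero_total=True``.

    Returns a long frame (participant_id, group_id, percent, zero_total).
    """
    _check_scheme(composition)
    comp = composition.set_index("food_code")
    if nutrient == "gl":
        if assignments is None:
            raise SchemaError("GL contribution requires GI assignments")
        terms = item_glycaemic_terms(diary, composition, assignments, gi_config)
        item_value = terms["gl_item"].to_numpy()
    else:
        if nutrient not in comp.columns:
            raise SchemaError(f"unknown nutrient {nutrient!r}")
        per100 = comp[nutrient].reindex(diary["food_code"]).to_numpy()
        item_value = per100 * diary["amount"].to_numpy() / 100.0

    df = pd.DataFrame(
        {
            "participant_id": diary["participant_id"].to_numpy(),
            "group_id": comp["group_id"].reindex(diary["food_code"]).to_numpy(),
            "value": item_value,
        }
    )
    wide = (
        df.groupby(["participant_id", "group_id"], sort=True)["value"].sum().unstack(fill_value=0.0)
    ).reindex(columns=GROUP_IDS, fill_value=0.0)
    totals = wide.sum(axis=1)
    zero_total = totals <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = wide.div(totals.where(~zero_total, 1.0), axis=0) * 100.0
    pct.loc[zero_total] = 0.0
    long = pct.stack().rename("percent").reset_index()
    long["zero_total"] = long["participant_id"].map(zero_total)
    return long


def summarize_contributions(
    rows: pd.DataFrame,
    profiles: pd.DataFrame,
) -> pd.DataFrame:
    """Per-group, per-arm median (IQR) of percent contribution.

    ``rows`` is the long output of :func:`contribution`. The paired p-value
    is added by the comparison stage; this function only summarises.
    """
    arm = profiles.set_index("participant_id")["arm"]
    df = rows.copy()
    df["arm"] = df["participant_id"].map(arm)
    out = []
    for gid in GROUP_IDS:
        rec: dict[str, object] = {"group_id": gid}
        sub = df[df["group_id"] == gid]
        for arm_name, prefix in (("T2DM", "t2dm"), ("ND", "nd")):
            vals = sub.loc[sub["arm"] == arm_name, "percent"].to_numpy(dtype=float)
            if len(vals):
                q = _quantiles(vals)
                rec[f"{prefix}_median"] = q["median"]
                rec[f"{prefix}_q1"] = q["q1"]
                rec[f"{prefix}_q3"] = q["q3"]
            else:
                rec[f"{prefix}_median"] = rec[f"{prefix}_q1"] = rec[f"{prefix}_q3"] = float("nan")
        out.append(rec)
    return pd.DataFrame(out)
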