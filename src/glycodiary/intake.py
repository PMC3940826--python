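"""Nutrient expansion of diaries, percent-energy profiles and compliance.

Diary entries are expanded linearly against the per-100 g composition table
into per participant-day nutrient totals, averaged into per-participant mean
daily intakes, and expressed as percent of energy using metabolisable-energy
conversion factors (UK convention: protein 4.0, fat 9.0, available
carbohydrate as monosaccharide 3.75, alcohol 7.0 kcal/g). Compliance is
checked against dietary recommendation targets of the kind issued for
diabetes management (DNSG/EASD, Diabetes UK) and national RDAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EnergyFactors
from .errors import DegenerateDataError, SchemaError, UnresolvedCodeError
from .schemas import NUTRIENT_COLUMNS

#: nutrient -> kcal/g factor key for the %E profile
PERCENT_ENERGY_NUTRIENTS: dict[str, str] = {
    "protein_g": "protein",
    "fat_g": "fat",
    "satfat_g": "fat",
    "mufa_g": "fat",
    "pufa_g": "fat",
    "carb_g": "carbohydrate",
    "starch_g": "carbohydrate",
    "sugars_g": "carbohydrate",
    "nonmilk_sugars_g": "carbohydrate",
    "alcohol_g": "alcohol",
}


@dataclass(frozen=True)
class Recommendation:
    """One dietary target: a lower and/or upper bound on a summary metric.

    ``metric`` is either a %E key (``pe_<nutrient>``) or a mean daily amount
    key (nutrient column name). Upper bounds are strict (printed as "<x"),
    lower bounds are inclusive, and two-sided bands are inclusive on both
    ends. ``sex`` restricts sex-specific targets (iron).
    """

    metric: str
    lower: float | None = None
    upper: float | None = None
    band: bool = False
    source: str = ""
    sex: str | None = None

    def met(self, value: float) -> bool:
        if self.band:
            assert self.lower is not None and self.upper is not None
            return self.lower <= value <= self.upper
        if self.upper is not None:
            return value < self.upper
        assert self.lower is not None
        return value >= self.lower


#: default recommendation set (diabetes nutrition guidance + national RDAs)
RECOMMENDATIONS: dict[str, Recommendation] = {
    "protein": Recommendation("pe_protein_g", 10.0, 20.0, band=True, source="DNSG-EASD"),
    "fat": Recommendation("pe_fat_g", upper=35.0, source="DNSG-EASD"),
    "saturated_fat": Recommendation("pe_satfat_g", upper=10.0, source="DNSG-EASD"),
    "pufa": Recommendation("pe_pufa_g", upper=10.0, source="DNSG-EASD"),
    "mufa": Recommendation("pe_mufa_g", 10.0, 20.0, band=True, source="DNSG-EASD"),
    "carbohydrate": Recommendation("pe_carb_g", 45.0, 60.0, band=True, source="DNSG-EASD"),
    "fibre": Recommendation("fibre_g", lower=24.0, source="DUK"),
    "sodium": Recommendation("sodium_mg", upper=2300.0, source="Irish-RDA"),
    "calcium": Recommendation("calcium_mg", lower=800.0, source="Irish-RDA"),
    "iron_male": Recommendation("iron_mg", lower=10.0, source="Irish-RDA", sex="male"),
    "iron_female": Recommendation("iron_mg", lower=9.0, source="Irish-RDA", sex="female"),
    "vitamin_d": Recommendation("vitamin_d_ug", lower=10.0, source="Irish-RDA"),
    "vitamin_b12": Recommendation("vitamin_b12_ug", lower=1.4, source="Irish-RDA"),
    "folate": Recommendation("folate_ug", lower=300.0, source="Irish-RDA"),
    "vitamin_c": Recommendation("vitamin_c_mg", lower=60.0, source="Irish-RDA"),
}


def recommendations_frame(
    recommendations: dict[str, Recommendation] | None = None,
) -> pd.DataFrame:
    """The recommendation set as a table (target, metric, bounds, source, sex)."""
    recommendations = recommendations or RECOMMENDATIONS
    return pd.DataFrame(
        [
            {"target": name, "metric": r.metric, "lower": r.lower, "upper": r.upper,
             "band": r.band, "source": r.source, "sex": r.sex or "any"}
            for name, r in recommendations.items()
        ]
    )


def daily_totals(diary: pd.DataFrame, composition: pd.DataFrame) -> pd.DataFrame:
    """Per participant-day nutrient totals (exact linear aggregation).

    total_nutrient = sum over items of amount x per-100g value / 100.
    """
    comp = composition.set_index("food_code")
    missing = sorted(set(diary["food_code"]) - set(comp.index))
    if missing:
        raise UnresolvedCodeError(
            f"diary codes missing from composition: {missing[:10]}", codes=missing
        )
    per100 = comp[NUTRIENT_COLUMNS].reindex(diary["food_code"]).to_numpy()
    contrib = per100 * (diary["amount"].to_numpy()[:, None] / 100.0)
    wide = pd.DataFrame(contrib, columns=NUTRIENT_COLUMNS)
    wide["participant_id"] = diary["participant_id"].to_numpy()
    wide["day_index"] = diary["day_index"].to_numpy()
    return (
        wide.groupby(["participant_id", "day_index"], sort=True)[NUTRIENT_COLUMNS]
        .sum()
        .reset_index()
    )


def participant_means(totals: pd.DataFrame) -> pd.DataFrame:
    """Mean daily nutrient intake per participant over recorded days."""
    return (
        totals.groupby("participant_id", sort=True)[NUTRIENT_COLUMNS]
        .mean()
        .reset_index()
    )


def percent_energy(means: pd.DataFrame, factors: EnergyFactors | None = None) -> pd.DataFrame:
    """Percent of energy from each energy-yielding nutrient.

    %E = grams x kcal-per-gram factor / energy(kcal) x 100, computed on the
    participant's mean daily intake. Raises on zero reported energy.
    """
    factors = factors or EnergyFactors()
    energy = means["energy_kcal"].to_numpy()
    if (energy <= 0).any():
        bad = means.loc[energy <= 0, "participant_id"].tolist()
        raise DegenerateDataError(f"zero reported energy for participants {bad[:5]}")
    out = means[["participant_id"]].copy()
    for nutrient, factor_key in PERCENT_ENERGY_NUTRIENTS.items():
        factor = getattr(factors, factor_key)
        out[f"pe_{nutrient}"] = means[nutrient].to_numpy() * factor / energy * 100.0
    return out


def check_compliance(
    summary_row: pd.Series | dict,
    sex: str,
    recommendations: dict[str, Recommendation] | None = None,
) -> dict[str, bool]:
    """Per-target compliance flags for one participant summary.

    ``summary_row`` must carry the %E keys (pe_*) and mean daily amounts.
    Sex-specific targets are evaluated only for the matching sex.
    """
    recommendations = recommendations or RECOMMENDATIONS
    flags: dict[str, bool] = {}
    for name, rec in recommendations.items():
        if rec.sex is not None and rec.sex != sex:
            continue
        if rec.metric not in summary_row:
            raise SchemaError(f"summary missing metric {rec.metric!r} for target {name!r}")
        flags[name] = rec.met(float(summary_row[rec.metric]))
    return flags


def compliance_table(
    summaries: pd.DataFrame,
    profiles: pd.DataFrame,
    recommendations: dict[str, Recommendation] | None = None,
) -> pd.DataFrame:
    """Compliance flags for every participant (iron resolved by sex)."""
    recommendations = recommendations or RECOMMENDATIONS
    sex = profiles.set_index("participant_id")["sex"]
    rows = []
    for _, rec in summaries.iterrows():
        pid = rec["participant_id"]
        flags = check_compliance(rec, str(sex.loc[pid]), recommendations)
        # collapse the sex-specific iron targets into one column
        if "iron_male" in flags or "iron_female" in flags:
            flags["iron"] = flags.pop("iron_male", flags.pop("iron_female", None))
        rows.append({"participant_id": pid, **flags})
    return pd.DataFrame(rows)


def supplement_contribution(
    diary: pd.DataFrame,
    composition: pd.DataFrame,
    nutrient: str,
) -> pd.DataFrame:
    """Percent of a nutrient's intake coming from supplement-flagged items.

    Returns (participant_id, pct_from_supplements); 0 when the participant's
    total intake of the nutrient is 0.
    """
    if nutrient not in NUTRIENT_COLUMNS:
        raise SchemaError(f"unknown nutrient {nutrient!r}")
    comp = composition.set_index("food_code")
    per100 = comp[nutrient].reindex(diary["food_code"]).to_numpy()
    is_supp = comp["is_supplement"].reindex(diary["food_code"]).to_numpy()
    contrib = per100 * diary["amount"].to_numpy() / 100.0
    df = pd.DataFrame(
        {
            "participant_id": diary["participant_id"].to_numpy(),
            "total": contrib,
            "supp": np.where(is_supp, contrib, 0.0),
        }
    )
    agg = df.groupby("participant_id", sort=True).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(agg["total"] > 0, 100.0 * agg["supp"] / agg["total"], 0.0)
    return pd.DataFrame(
        {"participant_id": agg.index, "pct_from_supplements": pct}
    ).reset_index(drop=True)


def summarise_cohort(
    diary: pd.DataFrame,
    composition: pd.DataFrame,
    factors: EnergyFactors | None = None,
) -> pd.DataFrame:
    """Participant summaries: mean daily nutrients + percent-energy profile."""
    totals = daily_totals(diary, composition)
    means = participant_means(totals)
    pe = percent_energy(means, factors)
    return means.merge(pe, on="participant_id", validate="one_to_one")
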