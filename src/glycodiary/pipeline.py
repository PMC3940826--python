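"""End-to-end pipeline: diaries in, comparison tables out.

``run_pipeline`` reads the six input tables, assigns GIs, builds participant
summaries, applies the Goldberg screen, aggregates food groups and runs the
matched-pair comparison battery, writing the demographic table (table1),
nutrient table (table2), food-group intake table (table3), contribution
table (table4), the GL-contribution ranking (fig1), the under-reporting
flags, the full comparison list and a structured JSON run log. A
sensitivity re-run repeats every comparison after excluding whole pairs
containing a possible under-reporter and reports which significance flags
changed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gi as gi_mod
from . import grouping, intake, io_formats, stats
from .config import RunConfig, StatsConfig
from .energy import mean_daily_energy, screen_cohort
from .errors import DegenerateDataError
from .groups import FOOD_GROUPS, GROUP_IDS

#: nutrient-battery variables compared between arms (table2 order)
NUTRIENT_VARIABLES = [
    "energy_kcal",
    "pe_protein_g", "pe_fat_g", "pe_satfat_g", "pe_pufa_g", "pe_mufa_g",
    "pe_carb_g", "pe_starch_g", "pe_sugars_g", "pe_nonmilk_sugars_g",
    "pe_alcohol_g",
    "fibre_g", "dietary_gl", "dietary_gi",
    "sodium_mg", "calcium_mg", "magnesium_mg", "iron_mg",
    "vitamin_d_ug", "vitamin_b12_ug", "folate_ug", "vitamin_c_mg",
]

#: table2 metric -> compliance target name
_METRIC_TARGET = {
    "pe_protein_g": "protein",
    "pe_fat_g": "fat",
    "pe_satfat_g": "saturated_fat",
    "pe_pufa_g": "pufa",
    "pe_mufa_g": "mufa",
    "pe_carb_g": "carbohydrate",
    "fibre_g": "fibre",
    "sodium_mg": "sodium",
    "calcium_mg": "calcium",
    "iron_mg": "iron",
    "vitamin_d_ug": "vitamin_d",
    "vitamin_b12_ug": "vitamin_b12",
    "folate_ug": "folate",
    "vitamin_c_mg": "vitamin_c",
}

_CONTRIB_LABELS = {
    "energy_kcal": "energy",
    "carb_g": "carbohydrate",
    "protein_g": "protein",
    "fat_g": "fat",
    "gl": "glycaemic_load",
}


def compare_all(
    summaries: pd.DataFrame,
    profiles: pd.DataFrame,
    config: StatsConfig | None = None,
    group_amounts: pd.DataFrame | None = None,
    contributions: dict[str, pd.DataFrame] | None = None,
    include_demographics: bool = True,
) -> list[stats.ComparisonResult]:
    """One comparison per variable across the matched arms.

    Continuous variables are KS-routed; food-group intakes and contribution
    percentages always take the signed-rank route. Pairs with a value
    missing in either member are dropped per variable (pairwise deletion).
    """
    config = config or StatsConfig()
    results: list[stats.ComparisonResult] = []

    if include_demographics:
        for var in ("age", "bmi"):
            t2dm, nd = stats.paired_frame(
                profiles[["participant_id", var]], profiles, var
            )
            results.append(stats.compare_paired(var, t2dm, nd, "demographic", config))
        for var in ("sex", "social_class", "supplement_user"):
            by_arm = {
                arm: grp[var].astype(str).value_counts().to_dict()
                for arm, grp in profiles.groupby("arm")
            }
            results.append(
                stats.compare_categorical(var, by_arm.get("T2DM", {}), by_arm.get("ND", {}))
            )

    for var in NUTRIENT_VARIABLES:
        if var not in summaries.columns:
            continue
        t2dm, nd = stats.paired_frame(summaries[["participant_id", var]], profiles, var)
        results.append(stats.compare_paired(var, t2dm, nd, "nutrient", config))

    if group_amounts is not None:
        for gid in GROUP_IDS:
            t2dm, nd = stats.paired_frame(
                group_amounts[["participant_id", gid]], profiles, gid
            )
            results.append(
                stats.compare_paired(gid, t2dm, nd, "food_group", config, force_wilcoxon=True)
            )

    if contributions is not None:
        for nutrient, rows in contributions.items():
            label = _CONTRIB_LABELS.get(nutrient, nutrient)
            wide = rows.pivot(index="participant_id", columns="group_id", values="percent").reset_index()
            for gid in GROUP_IDS:
                t2dm, nd = stats.paired_frame(wide[["participant_id", gid]], profiles, gid)
                results.append(
                    stats.compare_paired(
                        f"{label}:{gid}", t2dm, nd, f"contribution_{label}",
                        config, force_wilcoxon=True,
                    )
                )
    return results


@dataclass
class AnalysisResult:
    """All in-memory products of one pipeline run."""

    assignments: pd.DataFrame
    summaries: pd.DataFrame
    group_amounts: pd.DataFrame
    contributions: dict[str, pd.DataFrame]
    flags: pd.DataFrame
    flagged_proportions: dict[str, float]
    retained_ids: list[str]
    comparisons: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    sensitivity: pd.DataFrame | None = None
    log: dict = field(default_factory=dict)


def _arm_quantiles(values: pd.DataFrame, profiles: pd.DataFrame, column: str) -> dict[str, float]:
    arm = profiles.set_index("participant_id")["arm"]
    merged = values.set_index("participant_id")[column]
    out = {}
    for arm_name, prefix in (("T2DM", "t2dm"), ("ND", "nd")):
        ids = arm.index[arm == arm_name]
        v = merged.reindex(ids).dropna().to_numpy(dtype=float)
        if len(v):
            out[f"{prefix}_median"] = float(np.quantile(v, 0.5))
            out[f"{prefix}_q1"] = float(np.quantile(v, 0.25))
            out[f"{prefix}_q3"] = float(np.quantile(v, 0.75))
        else:
            out[f"{prefix}_median"] = out[f"{prefix}_q1"] = out[f"{prefix}_q3"] = float("nan")
    return out


def analyse(
    profiles: pd.DataFrame,
    diaries: pd.DataFrame,
    composition: pd.DataFrame,
    gi_table: pd.DataFrame,
    analogue_map: pd.DataFrame,
    recipes: pd.DataFrame,
    config: RunConfig | None = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory tables."""
    if "bmi" not in profiles.columns:
        profiles = profiles.assign(bmi=profiles["weight"] / profiles["height"] ** 2)
    gi_cfg = config.gi if config else None
    stats_cfg = config.stats if config else StatsConfig()
    goldberg_cfg = config.goldberg if config else None
    factors = config.factors if config else None

    assignments = gi_mod.assign_all(composition, gi_table, analogue_map, recipes, gi_cfg)

    totals = intake.daily_totals(diaries, composition)
    summaries = intake.summarise_cohort(diaries, composition, factors)
    glyc = gi_mod.glycaemic_summary(diaries, composition, assignments, gi_cfg)
    summaries = summaries.merge(
        glyc[["participant_id", "dietary_gi", "dietary_gl"]],
        on="participant_id", validate="one_to_one",
    )

    ei = mean_daily_energy(totals)
    flags, proportions, retained = screen_cohort(ei, profiles, goldberg_cfg)
    summaries = summaries.merge(
        flags[["participant_id", "ratio", "flagged"]].rename(columns={"ratio": "ei_bmr"}),
        on="participant_id", validate="one_to_one",
    )

    amounts = grouping.group_amounts(diaries, composition)
    contributions = {
        nutrient: grouping.contribution(diaries, composition, nutrient,
                                        assignments=assignments, gi_config=gi_cfg)
        for nutrient in grouping.CONTRIBUTION_NUTRIENTS
    }

    results = compare_all(summaries, profiles, stats_cfg, amounts, contributions)
    comparisons = stats.results_frame(results, stats_cfg.alpha)

    compliance = intake.compliance_table(summaries, profiles)
    tables = _build_tables(profiles, summaries, compliance, amounts,
                           contributions, flags, results)

    log = {
        "n_pairs": int(profiles["pair_id"].nunique()),
        "n_participants": int(len(profiles)),
        "n_diary_rows": int(len(diaries)),
        "gi_rule_counts": gi_mod.rule_counts(assignments),
        "unresolved_codes": [],
        "flagged_proportion_pct": proportions,
        "n_retained_for_sensitivity": len(retained),
        "alpha": stats_cfg.alpha,
    }
    return AnalysisResult(
        assignments=assignments, summaries=summaries, group_amounts=amounts,
        contributions=contributions, flags=flags, flagged_proportions=proportions,
        retained_ids=retained, comparisons=comparisons, tables=tables, log=log,
    )


def _build_tables(
    profiles: pd.DataFrame,
    summaries: pd.DataFrame,
    compliance: pd.DataFrame,
    amounts: pd.DataFrame,
    contributions: dict[str, pd.DataFrame],
    flags: pd.DataFrame,
    results: list[stats.ComparisonResult],
) -> dict[str, pd.DataFrame]:
    by_var = {(r.family, r.variable): r for r in results}
    arm = profiles.set_index("participant_id")["arm"]

    # --- table1: demographics
    t1_rows = []
    for r in results:
        if r.family == "demographic":
            t1_rows.append(
                {"variable": r.variable,
                 "kind": "categorical" if r.test == "chi_square" else "continuous",
                 "test": r.test, "n_pairs": r.n_pairs,
                 "t2dm_summary": r.t2dm_summary, "nd_summary": r.nd_summary,
                 "statistic": r.statistic, "p_value": r.p_value}
            )
    table1 = pd.DataFrame(t1_rows)

    # --- table2: nutrients + % meeting recommendations
    comp_arm = compliance.merge(
        profiles[["participant_id", "arm"]], on="participant_id"
    ) if len(compliance) else None
    t2_rows = []
    for var in NUTRIENT_VARIABLES:
        if var not in summaries.columns:
            continue
        r = by_var.get(("nutrient", var))
        rec = {"variable": var,
               **_arm_quantiles(summaries[["participant_id", var]], profiles, var)}
        target = _METRIC_TARGET.get(var)
        for arm_name, prefix in (("T2DM", "t2dm"), ("ND", "nd")):
            if target and comp_arm is not None and target in comp_arm.columns:
                sub = comp_arm.loc[comp_arm["arm"] == arm_name, target]
                rec[f"{prefix}_meeting_pct"] = float(100.0 * sub.mean()) if len(sub) else float("nan")
            else:
                rec[f"{prefix}_meeting_pct"] = float("nan")
        rec.update({"test": r.test if r else "", "statistic": r.statistic if r else float("nan"),
                    "p_value": r.p_value if r else float("nan")})
        t2_rows.append(rec)
    table2 = pd.DataFrame(t2_rows)

    # --- table3: food-group intake, % consumers, consumers-only
    t3_rows = []
    for gid in GROUP_IDS:
        r = by_var.get(("food_group", gid))
        rec: dict[str, object] = {"group_id": gid, "display_name": FOOD_GROUPS[gid]}
        for arm_name, prefix in (("T2DM", "t2dm"), ("ND", "nd")):
            ids = arm.index[arm == arm_name]
            sub = amounts.set_index("participant_id").reindex(ids)
            cs = grouping.consumer_stats(sub.reset_index(), gid)
            rec.update({
                f"{prefix}_median": cs["pop_median"], f"{prefix}_q1": cs["pop_q1"],
                f"{prefix}_q3": cs["pop_q3"], f"{prefix}_min": cs["pop_min"],
                f"{prefix}_max": cs["pop_max"],
                f"{prefix}_pct_consumers": cs["pct_consumers"],
                f"{prefix}_cons_median": cs["cons_median"],
                f"{prefix}_cons_q1": cs["cons_q1"], f"{prefix}_cons_q3": cs["cons_q3"],
            })
        rec.update({"statistic": r.statistic if r else float("nan"),
                    "p_value": r.p_value if r else float("nan")})
        t3_rows.append(rec)
    table3 = pd.DataFrame(t3_rows)

    # --- table4: % contribution to energy/carbohydrate/protein/fat
    t4_rows = []
    for nutrient in ("energy_kcal", "carb_g", "protein_g", "fat_g"):
        label = _CONTRIB_LABELS[nutrient]
        summ = grouping.summarize_contributions(contributions[nutrient], profiles)
        for _, row in summ.iterrows():
            r = by_var.get((f"contribution_{label}", f"{label}:{row['group_id']}"))
            t4_rows.append(
                {"group_id": row["group_id"], "nutrient": label,
                 "t2dm_median": row["t2dm_median"], "t2dm_q1": row["t2dm_q1"],
                 "t2dm_q3": row["t2dm_q3"], "nd_median": row["nd_median"],
                 "nd_q1": row["nd_q1"], "nd_q3": row["nd_q3"],
                 "statistic": r.statistic if r else float("nan"),
                 "p_value": r.p_value if r else float("nan")}
            )
    table4 = pd.DataFrame(t4_rows)

    # --- fig1: GL contribution ranking (T2DM median descending)
    summ = grouping.summarize_contributions(contributions["gl"], profiles)
    summ = summ.sort_values(
        ["t2dm_median", "group_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    f1_rows = []
    for i, row in summ.iterrows():
        r = by_var.get(("contribution_glycaemic_load", f"glycaemic_load:{row['group_id']}"))
        f1_rows.append(
            {"rank": i + 1, "group_id": row["group_id"],
             "display_name": FOOD_GROUPS[row["group_id"]],
             "t2dm_median": row["t2dm_median"], "t2dm_q1": row["t2dm_q1"],
             "t2dm_q3": row["t2dm_q3"], "nd_median": row["nd_median"],
             "nd_q1": row["nd_q1"], "nd_q3": row["nd_q3"],
             "statistic": r.statistic if r else float("nan"),
             "p_value": r.p_value if r else float("nan")}
        )
    fig1 = pd.DataFrame(f1_rows)

    return {"table1": table1, "table2": table2, "table3": table3,
            "table4": table4, "fig1": fig1, "flags": flags}


def sensitivity_rerun(
    result: AnalysisResult,
    profiles: pd.DataFrame,
    config: StatsConfig | None = None,
) -> pd.DataFrame:
    """Repeat every comparison excluding pairs containing an under-reporter.

    A pair is dropped entirely when either member falls at or below the
    exclusion cutoff (matched tests need complete pairs). Returns a
    per-variable delta report (p_full, p_subset, flag_changed).
    """
    config = config or StatsConfig()
    retained = set(result.retained_ids)
    pair_ok = profiles.groupby("pair_id")["participant_id"].apply(
        lambda ids: all(pid in retained for pid in ids)
    )
    keep_pairs = set(pair_ok.index[pair_ok])
    sub_profiles = profiles[profiles["pair_id"].isin(keep_pairs)].reset_index(drop=True)
    if not len(sub_profiles):
        raise DegenerateDataError("sensitivity re-run: no retained pairs")

    sub_results = compare_all(
        result.summaries, sub_profiles, config,
        result.group_amounts, result.contributions,
        include_demographics=False,
    )
    sub = stats.results_frame(sub_results, config.alpha)
    full = result.comparisons[result.comparisons["family"] != "demographic"]
    delta = full[["variable", "family", "p_value", "significant"]].rename(
        columns={"p_value": "p_full", "significant": "significant_full"}
    ).merge(
        sub[["variable", "family", "p_value", "significant"]].rename(
            columns={"p_value": "p_subset", "significant": "significant_subset"}
        ),
        on=["variable", "family"], how="inner",
    )
    delta["flag_changed"] = delta["significant_full"] != delta["significant_subset"]
    delta["n_pairs_retained"] = len(keep_pairs)
    return delta


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """File-based pipeline: read inputs, analyse, write the eight outputs."""
    composition = io_formats.read_composition(config.composition)
    profiles = io_formats.read_profiles(config.profiles)
    diaries = io_formats.read_diary(
        config.diary, composition,
        expected_days=config.protocol.expected_days,
        require_weekend=config.protocol.require_weekend,
    )
    gi_table = io_formats.read_gi_table(config.gi_table)
    analogue_map = io_formats.read_analogue_map(config.analogue_map)
    recipes = io_formats.read_recipes(config.recipes)

    result = analyse(profiles, diaries, composition, gi_table, analogue_map,
                     recipes, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for schema_id in ("table1", "table2", "table3", "table4", "fig1", "flags"):
        io_formats.write_table(result.tables[schema_id], out / f"{schema_id}.csv", schema_id)
    io_formats.write_table(result.comparisons, out / "comparisons.csv", "comparisons")

    if config.sensitivity:
        delta = sensitivity_rerun(result, profiles, config.stats)
        result.sensitivity = delta
        result.log["sensitivity"] = {
            "n_pairs_retained": int(delta["n_pairs_retained"].iloc[0]) if len(delta) else 0,
            "n_flags_changed": int(delta["flag_changed"].sum()),
            "any_flag_changed": bool(delta["flag_changed"].any()),
            "changed_variables": delta.loc[delta["flag_changed"], "variable"].tolist(),
        }
    (out / "log.json").write_text(json.dumps(result.log, indent=2, sort_keys=True) + "\n")
    return result
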