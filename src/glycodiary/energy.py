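"""Predicted basal metabolic rate and the Goldberg energy-intake screen.

BMR is predicted from the weight-only equations of Henry (2005,
Public Health Nutrition 8:1133-1152; the "Oxford" equations), which give
BMR in MJ/day as a linear function of body weight within sex x age bands.
The Goldberg screen flags implausibly low reported energy intake by the
ratio of mean daily energy intake (EI) to predicted BMR against a fixed
cutoff (default 1.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import GoldbergConfig
from .errors import DegenerateDataError, SchemaError

#: Henry (2005) weight-only BMR coefficients, MJ/day = a x weight(kg) + b.
#: Bands are left-closed: [18, 30), [30, 60), [60, 70), [70, inf).
#: Transcribed from the published adult coefficient table.
HENRY_COEFFICIENTS: dict[str, list[tuple[float, float, float, float]]] = {
    # (age_lo, age_hi, a, b)
    "male": [
        (18.0, 30.0, 0.0669, 2.28),
        (30.0, 60.0, 0.0592, 2.48),
        (60.0, 70.0, 0.0543, 2.37),
        (70.0, float("inf"), 0.0573, 2.01),
    ],
    "female": [
        (18.0, 30.0, 0.0546, 2.33),
        (30.0, 60.0, 0.0407, 2.90),
        (60.0, 70.0, 0.0429, 2.39),
        (70.0, float("inf"), 0.0417, 2.41),
    ],
}

#: thermochemical kilocalories per megajoule
KCAL_PER_MJ = 1000.0 / 4.184


def henry_bmr(sex: str, age: float, weight: float) -> float:
    """Predicted BMR in kcal/day from sex, age (years) and weight (kg)."""
    if sex not in HENRY_COEFFICIENTS:
        raise SchemaError(f"sex must be 'male' or 'female', got {sex!r}")
    if not weight > 0:
        raise SchemaError(f"weight must be > 0 kg, got {weight}")
    if age < 18.0:
        raise SchemaError(f"age {age} below the supported adult bands (>= 18 y)")
    for lo, hi, a, b in HENRY_COEFFICIENTS[sex]:
        if lo <= age < hi:
            return (a * weight + b) * KCAL_PER_MJ
    raise AssertionError("unreachable: bands cover [18, inf)")


@dataclass(frozen=True)
class EnergyScreenResult:
    participant_id: str
    ei: float
    bmr: float
    ratio: float
    flagged: bool
    comparator: str


def goldberg_flag(
    participant_id: str,
    ei: float,
    bmr: float,
    config: GoldbergConfig | None = None,
) -> EnergyScreenResult:
    """Flag a participant as a possible under-reporter from EI/BMR.

    Default behaviour flags ratio < 1.1; the comparator (strict or
    inclusive) is configurable because the boundary case is convention.
    """
    config = config or GoldbergConfig()
    if not bmr > 0:
        raise DegenerateDataError(f"non-positive BMR for {participant_id}: {bmr}")
    ratio = ei / bmr
    if config.comparator == "lt":
        flagged = ratio < config.threshold
    else:
        flagged = ratio <= config.threshold
    return EnergyScreenResult(participant_id, ei, bmr, ratio, bool(flagged), config.comparator)


def screen_cohort(
    energy_intake: pd.DataFrame,
    profiles: pd.DataFrame,
    config: GoldbergConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, float], list[str]]:
    """Apply the Goldberg screen to a cohort.

    Parameters
    ----------
    energy_intake
        Frame with columns participant_id, ei (mean daily kcal).
    profiles
        Participant profiles (for sex/age/weight and arm).

    Returns
    -------
    flags : frame (participant_id, arm, ei, bmr, ratio, flagged)
    proportions : flagged proportion (percent) per arm
    retained : participant ids kept for the sensitivity re-run, i.e. those
        with ratio above the exclusion cutoff (default excludes ratio <= 1.1)
    """
    config = config or GoldbergConfig()
    prof = profiles.set_index("participant_id")
    missing = sorted(set(energy_intake["participant_id"]) - set(prof.index))
    if missing:
        raise SchemaError(f"energy summaries for unknown participants: {missing[:5]}")

    rows = []
    for _, rec in energy_intake.iterrows():
        pid = rec["participant_id"]
        p = prof.loc[pid]
        bmr = henry_bmr(str(p["sex"]), float(p["age"]), float(p["weight"]))
        res = goldberg_flag(pid, float(rec["ei"]), bmr, config)
        rows.append(
            {"participant_id": pid, "arm": p["arm"], "ei": res.ei,
             "bmr": res.bmr, "ratio": res.ratio, "flagged": res.flagged}
        )
    flags = pd.DataFrame(rows).sort_values("participant_id").reset_index(drop=True)

    proportions = {
        arm: float(100.0 * grp["flagged"].mean())
        for arm, grp in flags.groupby("arm")
    }
    if config.exclusion_comparator == "le":
        keep = flags["ratio"] > config.threshold
    else:
        keep = flags["ratio"] >= config.threshold
    retained = flags.loc[keep, "participant_id"].tolist()
    return flags, proportions, retained


def mean_daily_energy(daily_totals: pd.DataFrame) -> pd.DataFrame:
    """Mean daily energy intake per participant from per-day nutrient totals."""
    out = (
        daily_totals.groupby("participant_id", sort=True)["energy_kcal"]
        .mean()
        .rename("ei")
        .reset_index()
    )
    return out
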