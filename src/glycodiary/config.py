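"""Run and generator configuration (pydantic models + YAML loading)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError
from .groups import FOOD_GROUPS

#: default multiplicative intake shifts for the T2DM arm, by food group.
#: Values > 1 raise intake, < 1 lower it; the direction set mirrors the food
#: choices reported for adults with T2DM relative to matched controls
#: (more wholemeal/wholegrain bread, eggs, oils, vegetables, meat products,
#: savoury snacks and soups/sauces; less white bread, cakes, full-fat dairy,
#: chocolate, fruit juice, oily fish, alcohol and table sugars).
DEFAULT_ARM_EFFECTS: dict[str, float] = {
    "wholemeal_brown_bread": 1.5,
    "wholegrain_bread": 1.8,
    "eggs": 1.4,
    "oils": 2.5,
    "other_vegetables": 1.4,
    "other_meat_products": 1.4,
    "savoury_snacks": 1.7,
    "soups_sauces": 1.5,
    "white_bread": 0.55,
    "cakes_pastries_buns": 0.55,
    "refined_breakfast_cereals": 0.6,
    "full_fat_milk_yogurt": 0.45,
    "chocolate_confectionery": 0.55,
    "fruit_juices": 0.45,
    "oily_fish": 0.6,
    "alcoholic_beverages": 0.55,
    "sugars_syrups_preserves": 0.45,
    # lower regular supplement use in the T2DM arm (gate odds only)
    "nutritional_supplements": 0.45,
}


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic cohort generator."""

    n_pairs: int = Field(124, ge=1)
    seed: int = 0
    recording_days: int = Field(4, ge=1)
    food_catalogue_size: int = Field(120, ge=76)  # >=2 foods per group
    arm_effects: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_ARM_EFFECTS))
    underreport_fraction: float = Field(0.37, ge=0.0, le=1.0)
    underreport_scale: tuple[float, float] = (0.6, 0.95)
    occasion_lambda: float = Field(3.0, gt=0.0)

    @field_validator("arm_effects")
    @classmethod
    def _effects_positive(cls, v: dict[str, float]) -> dict[str, float]:
        for gid, eff in v.items():
            if gid not in FOOD_GROUPS:
                raise ValueError(f"arm_effects references unknown group {gid!r}")
            if eff <= 0:
                raise ValueError(f"arm_effects[{gid!r}] must be > 0, got {eff}")
        return v

    @model_validator(mode="after")
    def _scale_range_valid(self) -> "SyntheticConfig":
        lo, hi = self.underreport_scale
        if not (0 < lo <= hi):
            raise ValueError(f"underreport_scale must satisfy 0 < lo <= hi, got {self.underreport_scale}")
        return self


class GoldbergConfig(BaseModel):
    """Goldberg energy-intake plausibility screen settings."""

    threshold: float = Field(1.1, gt=0.0)
    comparator: Literal["lt", "le"] = "lt"
    #: comparator used when building the sensitivity-exclusion subset
    exclusion_comparator: Literal["lt", "le"] = "le"


class GIConfig(BaseModel):
    """GI assignment and glycaemic-load settings."""

    low_carb_threshold_g: float = Field(5.0, ge=0.0)  # per 100 g
    default_gi: float = Field(50.0, ge=0.0)
    dominance_threshold: float = Field(0.5, ge=0.0, le=1.0)
    #: divide GI by 100 in the load computation (the conventional scale, under
    #: which a day's load is ~100-150); False gives the literal sum GI x carb.
    gl_per_100: bool = True


class StatsConfig(BaseModel):
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    routing_alpha: float = Field(0.05, gt=0.0, lt=1.0)
    #: normality assessed on the pooled variable (both arms); "per_arm" requires
    #: normality in each arm separately.
    ks_scope: Literal["pooled", "per_arm"] = "pooled"


class DiaryProtocol(BaseModel):
    expected_days: int = Field(4, ge=1)
    require_weekend: bool = True


class EnergyFactors(BaseModel):
    """Metabolisable-energy conversion factors, kcal per gram (UK convention:
    available carbohydrate expressed as monosaccharide)."""

    protein: float = 4.0
    fat: float = 9.0
    carbohydrate: float = 3.75
    alcohol: float = 7.0


class RunConfig(BaseModel):
    """Configuration of a full pipeline run."""

    profiles: Path
    diary: Path
    composition: Path
    gi_table: Path
    analogue_map: Path
    recipes: Path
    out_dir: Path
    seed: int = 0
    sensitivity: bool = True
    goldberg: GoldbergConfig = Field(default_factory=GoldbergConfig)
    gi: GIConfig = Field(default_factory=GIConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    protocol: DiaryProtocol = Field(default_factory=DiaryProtocol)
    factors: EnergyFactors = Field(default_factory=EnergyFactors)

    def input_paths(self) -> dict[str, Path]:
        return {
            "profiles": self.profiles,
            "diary": self.diary,
            "composition": self.composition,
            "gi_table": self.gi_table,
            "analogue_map": self.analogue_map,
            "recipes": self.recipes,
        }


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file; relative paths resolve against it."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except Exception as exc:  # noqa: BLE001 - surface as config error
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    base = path.parent
    for key in ("profiles", "diary", "composition", "gi_table",
                "analogue_map", "recipes", "out_dir"):
        if key in raw and not Path(raw[key]).is_absolute():
            raw[key] = str(base / raw[key])
    try:
        return RunConfig(**raw)
    except Exception as exc:  # noqa: BLE001
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def load_synthetic_config(path: str | Path) -> SyntheticConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        return SyntheticConfig(**raw)
    except Exception as exc:  # noqa: BLE001
        raise ConfigError(f"invalid generator config {path}: {exc}") from exc
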