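"""Carbon-sequestration extrapolation of the pooled biomass effect.

Given a baseline aboveground-biomass (AGB) carbon growth rate for a
forest class, the pooled relative enhancement from climber removal, an
eligible area and a deduction for the biomass lost in removed climbers,
the additional sequestration over a horizon is

    CO2 = (AGBg_CR - AGBg_0 - AGBg_climber) * area * years * 44/12

with AGBg_CR = AGBg_0 * (1 + effect); 44/12 converts Mg C to Mg CO2.
Cost efficiency is the per-hectare removal cost times area divided by the
additional CO2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

C_TO_CO2 = 44.0 / 12.0


class ScenarioError(ValueError):
    pass


@dataclass
class Scenario:
    label: str
    agb_g0: float                 # Mg C ha-1 yr-1 baseline growth
    effect: float                 # pooled relative AGB enhancement (e.g. 2.09)
    area_ha: float
    agb_climber: float = 0.0      # Mg C ha-1 yr-1 deducted for removed climbers
    horizon_years: float = 10.0
    cost_per_ha_usd: float = 8.64
    cost_per_ha_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("agb_g0", "effect", "area_ha", "agb_climber",
                     "cost_per_ha_usd"):
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be >= 0")
        if self.horizon_years < 1:
            raise ScenarioError("horizon_years must be >= 1")


@dataclass
class ExtrapolationResult:
    scenario: Scenario
    agb_g_cr: float
    additional_co2_mg: float
    cost_total_usd: float
    cost_per_mg_co2: float
    cost_per_mg_co2_range: tuple[float, float] | None = None
    warnings: list[str] = field(default_factory=list)


def enhanced_growth_rate(agb_g0: float, effect: float) -> float:
    """AGBg_CR = AGBg_0 * (1 + effect)."""
    if agb_g0 < 0 or effect < -1:
        raise ScenarioError("baseline rate must be >= 0 and effect >= -1")
    return agb_g0 * (1.0 + effect)


def additional_sequestration(scenario: Scenario) -> float:
    """Additional Mg CO2 over the horizon (may be negative, with a warning
    upstream, if the climber deduction exceeds the enhancement)."""
    g_cr = enhanced_growth_rate(scenario.agb_g0, scenario.effect)
    net_rate = g_cr - scenario.agb_g0 - scenario.agb_climber
    return net_rate * scenario.area_ha * scenario.horizon_years * C_TO_CO2


def cost_efficiency(scenario: Scenario, additional_co2_mg: float
                    ) -> tuple[float, tuple[float, float] | None]:
    """US$ per additional Mg CO2 (with min/max from the per-ha cost range)."""
    if additional_co2_mg <= 0:
        raise ScenarioError("cost per Mg CO2 undefined for zero/negative "
                            "additional sequestration")
    mid = scenario.cost_per_ha_usd * scenario.area_ha / additional_co2_mg
    rng = None
    if scenario.cost_per_ha_range is not None:
        lo, hi = scenario.cost_per_ha_range
        rng = (lo * scenario.area_ha / additional_co2_mg,
               hi * scenario.area_ha / additional_co2_mg)
    return mid, rng


def run_scenario(scenario: Scenario) -> ExtrapolationResult:
    g_cr = enhanced_growth_rate(scenario.agb_g0, scenario.effect)
    co2 = additional_sequestration(scenario)
    warnings = []
    if co2 < 0:
        warnings.append("net growth rate negative: climber deduction exceeds "
                        "the removal enhancement")
    cost_total = scenario.cost_per_ha_usd * scenario.area_ha
    if co2 > 0:
        cost_mid, cost_rng = cost_efficiency(scenario, co2)
    else:
        cost_mid, cost_rng = float("nan"), None
    return ExtrapolationResult(scenario, g_cr, co2, cost_total, cost_mid,
                               cost_rng, warnings)


def load_scenarios(path: str | Path) -> list[Scenario]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ScenarioError("scenario file must be a YAML list of scenarios")
    out = []
    for entry in raw:
        rng = entry.pop("cost_per_ha_range", None)
        if rng is not None:
            rng = (float(rng[0]), float(rng[1]))
        out.append(Scenario(cost_per_ha_range=rng, **entry))
    return out


def extrapolation_table(scenarios: list[Scenario]) -> pd.DataFrame:
    """One row per scenario plus a Total row (summed area, CO2 and cost),
    mirroring the published global-extrapolation table layout."""
    rows = []
    for sc in scenarios:
        r = run_scenario(sc)
        rows.append({
            "label": sc.label,
            "agb_g0": sc.agb_g0,
            "agb_g_cr": r.agb_g_cr,
            "area_ha": sc.area_ha,
            "additional_co2_mg": r.additional_co2_mg,
            "cost_total_usd": r.cost_total_usd,
            "cost_per_mg_co2": r.cost_per_mg_co2,
            "cost_per_mg_co2_min":
                None if r.cost_per_mg_co2_range is None else r.cost_per_mg_co2_range[0],
            "cost_per_mg_co2_max":
                None if r.cost_per_mg_co2_range is None else r.cost_per_mg_co2_range[1],
        })
    df = pd.DataFrame(rows).astype({c: float for c in (
        "agb_g0", "agb_g_cr", "area_ha", "additional_co2_mg",
        "cost_total_usd", "cost_per_mg_co2", "cost_per_mg_co2_min",
        "cost_per_mg_co2_max")})
    df.loc[len(df)] = {
        "label": "Total",
        "agb_g0": np.nan, "agb_g_cr": np.nan,
        "area_ha": df["area_ha"].sum(),
        "additional_co2_mg": df["additional_co2_mg"].sum(),
        "cost_total_usd": df["cost_total_usd"].sum(),
        "cost_per_mg_co2": np.nan, "cost_per_mg_co2_min": np.nan,
        "cost_per_mg_co2_max": np.nan,
    }
    return df
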