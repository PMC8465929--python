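"""Ordinance scenario presets and the scenario comparison harness.

Four stylized staple-food-ordinance designs are shipped as editable YAML
presets, each described by qualitative stock and enforcement levels:

================  ===============  ============
preset            required stock   enforcement
================  ===============  ============
snap_minimum      low              moderate
snap_depth        high             high
minneapolis       moderate         low
wic               moderate-high    high
================  ===============  ============

The WIC design varies its depth-of-stock requirement by food: a targeted
subset carries the high requirement while the rest stays moderate.  By
default the targets are the longest-shelf-life half of the catalog, so
that deep required stocks sit on foods that can hold them without
spoiling; the subset is configurable per preset file or call.

All four scenarios are run with every demand-side slider (promotions and
perceived food quality) at the scale maximum of 5, the setting under
which the designs are compared.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .calibration import FoodParameters
from .domain import (
    EnforcementLevel,
    FoodOrdinance,
    FoodSpec,
    OrdinanceSpec,
    StockLevel,
    StoreAttributes,
    level_to_enforcement,
    level_to_min_stock,
)
from .economics import DemandLevers
from .engine import SimulationConfig, SimulationResult, ordinance_schedule, run_simulation

__all__ = [
    "PRESET_NAMES",
    "build_ordinance",
    "load_preset",
    "least_perishable_half",
    "compare_scenarios",
    "run_preset",
]

PRESET_NAMES = ("snap_minimum", "snap_depth", "minneapolis", "wic")


def least_perishable_half(catalog: Sequence[FoodSpec]) -> list[str]:
    """The longest-shelf-life half of the catalog (ties broken by id)."""
    ranked = sorted(catalog, key=lambda f: (-f.shelf_life_weeks, f.food_id))
    return [f.food_id for f in ranked[: (len(ranked) + 1) // 2]]


def _read_preset_file(name: str) -> dict:
    ref = importlib.resources.files("sfosim.data.presets").joinpath(f"{name}.yaml")
    if not ref.is_file():
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    with importlib.resources.as_file(ref) as path:
        return yaml.safe_load(Path(path).read_text())


def _stock_value(value) -> float:
    """A stock level given either qualitatively or in units."""
    if isinstance(value, (int, float)):
        return float(value)
    return level_to_min_stock(StockLevel(value))


def _enforcement_value(value) -> float:
    if isinstance(value, (int, float)):
        return float(value)
    return level_to_enforcement(EnforcementLevel(value))


def build_ordinance(
    cfg: dict,
    catalog: Sequence[FoodSpec],
    *,
    start_step: int = 3,
    spacing: int = 2,
    targets: Sequence[str] | None = None,
) -> tuple[OrdinanceSpec, DemandLevers]:
    """Build a numeric ordinance from a preset-style config mapping.

    ``stock`` and ``enforcement`` accept either a qualitative level name
    or a number (units / compliance fraction); ``targeted_stock`` plus
    ``targets`` raise the requirement for a food subset;
    ``stock_overrides`` sets per-food levels directly.  Activation weeks
    follow the phase-in schedule (one food every ``spacing`` weeks from
    ``start_step``).
    """
    base_stock = _stock_value(cfg.get("stock", 0))
    enforcement = _enforcement_value(cfg.get("enforcement", 0))
    promotions = cfg.get("promotions", {})
    training = float(promotions.get("training", 5))
    signage = float(promotions.get("signage", 5))

    target_ids: set[str] = set()
    target_stock = base_stock
    if "targeted_stock" in cfg:
        target_stock = _stock_value(cfg["targeted_stock"])
        if targets is not None:
            target_ids = set(targets)
        else:
            spec_targets = cfg.get("targets", "least_perishable_half")
            if spec_targets == "least_perishable_half":
                target_ids = set(least_perishable_half(catalog))
            else:
                target_ids = set(spec_targets)
    overrides = {k: _stock_value(v) for k, v in cfg.get("stock_overrides", {}).items()}

    schedule = ordinance_schedule(catalog, start_step=start_step, spacing=spacing)
    foods = {
        f.food_id: FoodOrdinance(
            min_stock=overrides.get(
                f.food_id, target_stock if f.food_id in target_ids else base_stock
            ),
            enforcement=enforcement,
            training=training,
            signage=signage,
            activation_time=schedule[f.food_id],
        )
        for f in catalog
    }
    levers = DemandLevers(
        training=training, signage=signage, convenience=5.0, taste=5.0, healthiness=5.0
    )
    return OrdinanceSpec(foods=foods), levers


def load_preset(
    name: str,
    catalog: Sequence[FoodSpec],
    *,
    start_step: int = 3,
    spacing: int = 2,
    targets: Sequence[str] | None = None,
) -> tuple[OrdinanceSpec, DemandLevers]:
    """Build the numeric ordinance for a named preset.

    Qualitative levels map onto the shared unit scale (low/moderate/high
    stock -> 2/5/10 units; enforcement -> 0.2/0.6/1.0) and each food's
    activation week follows the standard phase-in schedule (one new food
    every ``spacing`` weeks from ``start_step``).  Returns the ordinance
    and the demand lever settings the scenario is run under.
    """
    cfg = _read_preset_file(str(name))
    return build_ordinance(
        cfg, catalog, start_step=start_step, spacing=spacing, targets=targets
    )


def run_preset(
    name: str,
    catalog: Sequence[FoodSpec],
    params: Mapping[str, FoodParameters],
    store: StoreAttributes = StoreAttributes(),
    config: SimulationConfig = SimulationConfig(),
    *,
    targets: Sequence[str] | None = None,
) -> SimulationResult:
    """Run the full simulation for one named preset."""
    ordinance, levers = load_preset(
        name, catalog, start_step=config.start_step, spacing=config.spacing,
        targets=targets,
    )
    config = replace(
        config,
        convenience=levers.convenience,
        taste=levers.taste,
        healthiness=levers.healthiness,
    )
    return run_simulation(catalog, params, ordinance, store, config)


def compare_scenarios(
    presets: Sequence[str],
    catalog: Sequence[FoodSpec],
    params: Mapping[str, FoodParameters],
    store: StoreAttributes = StoreAttributes(),
    config: SimulationConfig = SimulationConfig(),
) -> pd.DataFrame:
    """Run each preset and tabulate the outcomes side by side.

    The comparison reports, per scenario, the final simulated week's
    store-wide weekly profit, stock and waste (the equilibrium values),
    counts of foods with positive / negative final-week profit, and the
    cumulative profit and waste over the whole horizon.
    """
    rows = []
    for name in presets:
        result = run_preset(name, catalog, params, store, config)
        final = result.final_week()
        rows.append(
            {
                "scenario": name,
                "final_week_profit": float(final["m_profit"].sum()),
                "final_week_stock": float(final["y_actual"].sum()),
                "final_week_waste": float(final["y_waste"].sum()),
                "foods_positive_profit": int((final["m_profit"] > 0).sum()),
                "foods_negative_profit": int((final["m_profit"] < 0).sum()),
                "cumulative_profit": float(result.panel["m_profit"].sum()),
                "cumulative_waste": float(result.panel["y_waste"].sum()),
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
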