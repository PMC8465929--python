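"""Weekly stock-and-flow simulation of the corner store.

Each simulated week, for each food, the store:

1. determines the stock the ordinance requires (enforcement fraction
   times the minimum stock, once the food's activation week has passed);
2. prices the food by profit maximization over the price grid, given its
   unit costs this week (wholesale + delivery + storage, where storage
   includes a congestion term in the store-wide stock held last week);
3. purchases from the wholesaler the difference between the quantity it
   needs — the maximum of the required stock and last week's demand —
   and what is left over from last week, with a minimum of zero;
4. sells the minimum of what is stocked and what is demanded, oldest
   inventory first; inventory then ages one week and anything reaching
   the food's shelf life spoils and is wasted;
5. books the money flows: revenue on sales, wholesale and delivery cost
   on purchases, storage cost on everything held, and their balance as
   the weekly profit.

A store facing no requirement for a food stocks it voluntarily only
while pricing can turn a profit.  The simulation starts from an empty
store (all flows and stocks zero, no minimum requirements) and phases
the ordinance in one food at a time on a fixed schedule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import FoodParameters
from .domain import FoodOrdinance, FoodSpec, OrdinanceSpec, StoreAttributes
from .economics import (
    DEFAULT_GRID_RESOLUTION,
    DemandLevers,
    PriceGrid,
    UnitCosts,
    base_demand,
    demand_at_price,
    optimize_price,
)

__all__ = [
    "InventoryCohorts",
    "FoodWeekState",
    "SimulationConfig",
    "SimulationResult",
    "ConfigurationError",
    "ordinance_schedule",
    "required_stock",
    "step_food",
    "run_simulation",
]


class ConfigurationError(ValueError):
    """Raised when a simulation is configured inconsistently."""


class InventoryCohorts:
    """Age-stratified inventory of one food.

    Cohorts are (age in weeks, quantity) pairs; sales always draw from
    the oldest cohort first (FIFO), and a cohort reaching the food's
    shelf life spoils in full.  After each completed step every remaining
    cohort is younger than the shelf life.
    """

    def __init__(self, cohorts: Sequence[tuple[int, float]] = ()) -> None:
        self._cohorts: list[list[float]] = []
        for age, qty in cohorts:
            if qty < 0:
                raise AssertionError("cohort quantities must be >= 0")
            if qty > 0:
                self._cohorts.append([int(age), float(qty)])
        self._cohorts.sort(key=lambda c: -c[0])  # oldest first

    def total(self) -> float:
        return float(sum(q for _, q in self._cohorts))

    def cohorts(self) -> list[tuple[int, float]]:
        return [(int(a), float(q)) for a, q in self._cohorts]

    def add_fresh(self, qty: float) -> None:
        if qty < 0:
            raise AssertionError("cannot add negative stock")
        if qty > 0:
            self._cohorts.append([0, float(qty)])
            self._cohorts.sort(key=lambda c: -c[0])

    def sell_fifo(self, qty: float) -> float:
        """Remove up to ``qty`` units, oldest first; returns units sold."""
        if qty < 0:
            raise AssertionError("cannot sell negative quantity")
        remaining = qty
        for cohort in self._cohorts:
            if remaining <= 0:
                break
            take = min(cohort[1], remaining)
            cohort[1] -= take
            remaining -= take
        self._cohorts = [c for c in self._cohorts if c[1] > 0]
        return qty - remaining

    def age_and_spoil(self, shelf_life_weeks: int) -> float:
        """Age every cohort one week; returns the quantity that spoiled."""
        waste = 0.0
        kept = []
        for age, qty in self._cohorts:
            age += 1
            if age >= shelf_life_weeks:
                waste += qty
            else:
                kept.append([age, qty])
        self._cohorts = kept
        return waste

    def copy(self) -> "InventoryCohorts":
        return InventoryCohorts(self.cohorts())


@dataclass(frozen=True)
class FoodWeekState:
    """All flow, cost and money variables for one food in one week."""

    week: int
    food_id: str
    y_supply: float        # units bought from the wholesaler
    y_actual: float        # units on the shelf this week
    y_demand: float        # units demanded at the chosen price
    y_cust: float          # units sold
    y_waste: float         # units spoiled
    y_actual_end: float    # leftover units carried to next week
    c_delivery: float      # unit delivery cost
    c_storage: float       # unit storage cost
    c_total: float         # total unit cost
    c_cust: float          # retail price chosen
    m_supply: float        # wholesale spending
    m_delivery: float      # delivery spending
    m_storage: float       # storage spending
    m_cust: float          # sales revenue
    m_profit: float        # weekly profit


@dataclass(frozen=True)
class SimulationConfig:
    """Engine-level knobs.

    horizon : simulated weeks (default 60); the simulation starts at
    ``start_step`` (default week 3, after the model's two-step spin-up
    convention) and phases one food in every ``spacing`` weeks.
    ``kappa`` is the storage congestion cost in dollars per unit of
    store-wide stock; ``gamma`` / ``s_ref`` parameterize the variety
    demand factor; ``convenience`` / ``taste`` / ``healthiness`` are the
    perceived-quality sliders applied to every food.
    """

    horizon: int = 60
    start_step: int = 3
    spacing: int = 2
    grid_resolution: int = DEFAULT_GRID_RESOLUTION
    kappa: float = 0.001
    gamma: float = 0.0
    s_ref: float = 100.0
    convenience: float = 5.0
    taste: float = 5.0
    healthiness: float = 5.0

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1")
        if self.spacing < 1:
            raise ConfigurationError("spacing must be >= 1")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def ordinance_schedule(
    catalog: Sequence[FoodSpec], start_step: int = 3, spacing: int = 2
) -> dict[str, int]:
    """Activation week per food: one new food required every ``spacing`` weeks.

    Food ``k`` (in catalog order, 1-based) activates at
    ``start_step + spacing * (k - 1)``.
    """
    if spacing < 1:
        raise ConfigurationError("spacing must be >= 1")
    return {
        spec.food_id: start_step + spacing * k for k, spec in enumerate(catalog)
    }


def required_stock(ordinance: FoodOrdinance, t: int) -> float:
    """Effective minimum stock at week ``t``: enforcement x min_stock once active."""
    if t < ordinance.activation_time:
        return 0.0
    return ordinance.enforcement * ordinance.min_stock


def step_food(
    carryover: InventoryCohorts,
    prev_demand: float,
    params: FoodParameters,
    ordinance: FoodOrdinance,
    store: StoreAttributes,
    t: int,
    food: FoodSpec,
    *,
    total_stock_prev: float = 0.0,
    config: SimulationConfig = SimulationConfig(),
) -> tuple[FoodWeekState, InventoryCohorts]:
    """Advance one food one week; returns the week's state and new inventory.

    ``total_stock_prev`` is the store-wide stock held the previous week;
    using last week's total keeps the per-food updates within a week
    independent of the order foods are processed in.
    """
    if carryover.total() < 0:  # pragma: no cover - InventoryCohorts guards this
        raise AssertionError("negative carryover inventory")

    req = required_stock(ordinance, t)
    active = t >= ordinance.activation_time
    levers = DemandLevers(
        training=ordinance.training if active else 1.0,
        signage=ordinance.signage if active else 1.0,
        convenience=config.convenience,
        taste=config.taste,
        healthiness=config.healthiness,
    )

    c_delivery = max(0.0, params.p10 + params.p11 * food.ease_of_delivery)
    c_storage = max(
        0.0,
        params.p12
        + params.p13 * store.infrastructure_capacity
        + config.kappa * total_stock_prev,
    )
    costs = UnitCosts(params.c_store, c_delivery, c_storage)

    base = base_demand(
        params, levers, total_stock_prev, gamma=config.gamma, s_ref=config.s_ref
    )
    grid = PriceGrid.linspace(params.c_max, config.grid_resolution)
    decision = optimize_price(
        params, base, costs, req, grid, shelf_life_weeks=food.shelf_life_weeks
    )
    c_cust = decision.price
    y_demand = demand_at_price(base, params.p7, c_cust)

    if req == 0.0 and decision.stock_if_voluntary == 0.0:
        needed = 0.0  # store declines an unprofitable, unrequired food
    else:
        needed = max(req, prev_demand)

    leftover = carryover.total()
    y_supply = max(0.0, needed - leftover)
    y_actual = y_supply + leftover

    inventory = carryover.copy()
    inventory.add_fresh(y_supply)
    y_cust = inventory.sell_fifo(min(y_actual, y_demand))
    y_waste = inventory.age_and_spoil(food.shelf_life_weeks)
    y_actual_end = y_actual - y_cust - y_waste

    m_supply = params.c_store * y_supply
    m_storage = c_storage * y_actual
    m_delivery = c_delivery * y_supply
    m_cust = c_cust * y_cust
    m_profit = m_cust - m_supply - m_delivery - m_storage

    state = FoodWeekState(
        week=t,
        food_id=food.food_id,
        y_supply=y_supply,
        y_actual=y_actual,
        y_demand=y_demand,
        y_cust=y_cust,
        y_waste=y_waste,
        y_actual_end=y_actual_end,
        c_delivery=c_delivery,
        c_storage=c_storage,
        c_total=costs.total,
        c_cust=c_cust,
        m_supply=m_supply,
        m_delivery=m_delivery,
        m_storage=m_storage,
        m_cust=m_cust,
        m_profit=m_profit,
    )
    return state, inventory


@dataclass
class SimulationResult:
    """Time x food panel of weekly states plus store-level aggregates."""

    panel: pd.DataFrame          # one row per (week, food) with all state fields
    store_totals: pd.DataFrame   # per-week totals across foods
    metadata: dict = field(default_factory=dict)

    def final_week(self) -> pd.DataFrame:
        last = self.panel["week"].max()
        return self.panel[self.panel["week"] == last].set_index("food_id")

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long format: week, food_id, variable, value."""
        return self.panel.melt(
            id_vars=["week", "food_id"], var_name="variable", value_name="value"
        ).sort_values(["week", "food_id", "variable"], kind="stable", ignore_index=True)

    def write_csv(self, path: str | Path) -> None:
        self.to_tidy_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        final = self.final_week()
        totals = self.store_totals
        return {
            "metadata": self.metadata,
            "final_week": int(self.panel["week"].max()),
            "final_week_total_profit": float(final["m_profit"].sum()),
            "final_week_total_stock": float(final["y_actual"].sum()),
            "final_week_total_waste": float(final["y_waste"].sum()),
            "cumulative_profit": float(self.panel["m_profit"].sum()),
            "cumulative_waste": float(self.panel["y_waste"].sum()),
            "per_food_final_week": {
                fid: {
                    k: float(v)
                    for k, v in row.items()
                    if k not in ("week",)
                }
                for fid, row in final.drop(columns=[], errors="ignore")
                .to_dict(orient="index")
                .items()
            },
            "weekly_totals": {
                str(int(r.week)): {
                    "y_actual_all": float(r.y_actual_all),
                    "m_profit": float(r.m_profit),
                }
                for r in totals.itertuples(index=False)
            },
        }

    def write_summary_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2, sort_keys=True))


def run_simulation(
    catalog: Sequence[FoodSpec],
    params: Mapping[str, FoodParameters],
    ordinance: OrdinanceSpec,
    store: StoreAttributes = StoreAttributes(),
    config: SimulationConfig = SimulationConfig(),
) -> SimulationResult:
    """Run the full weekly simulation over the configured horizon.

    The store starts empty: every flow and stock is zero and no minimum
    requirements are in force until each food's activation week.  Last
    week's demand per food and last week's store-wide stock feed forward
    into the current week's purchasing and pricing.
    """
    missing = [f.food_id for f in catalog if f.food_id not in params]
    if missing:
        raise ConfigurationError(f"no calibrated parameters for food(s): {missing}")

    inventories = {f.food_id: InventoryCohorts() for f in catalog}
    prev_demand = {f.food_id: 0.0 for f in catalog}
    total_stock_prev = 0.0

    rows: list[FoodWeekState] = []
    totals: list[dict] = []
    weeks = range(config.start_step, config.start_step + config.horizon)
    for t in weeks:
        week_actual = 0.0
        week_profit = 0.0
        new_prev = {}
        for spec in catalog:
            state, inv = step_food(
                inventories[spec.food_id],
                prev_demand[spec.food_id],
                params[spec.food_id],
                ordinance.for_food(spec.food_id),
                store,
                t,
                spec,
                total_stock_prev=total_stock_prev,
                config=config,
            )
            inventories[spec.food_id] = inv
            new_prev[spec.food_id] = state.y_demand
            week_actual += state.y_actual
            week_profit += state.m_profit
            rows.append(state)
        prev_demand = new_prev
        total_stock_prev = week_actual
        totals.append({"week": t, "y_actual_all": week_actual, "m_profit": week_profit})

    panel = pd.DataFrame([asdict(r) for r in rows])
    store_totals = pd.DataFrame(totals)
    metadata = {
        "horizon": config.horizon,
        "start_step": config.start_step,
        "spacing": config.spacing,
        "config_hash": config.hash(),
        "n_foods": len(catalog),
    }
    return SimulationResult(panel=panel, store_totals=store_totals, metadata=metadata)
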