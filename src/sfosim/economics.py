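"""Demand-price economics and the weekly price decision.

The store faces a linear demand curve per food (law of demand): demand
at price zero equals a base level set by promotion and quality levers,
and falls by p7 units per dollar until it reaches zero at the maximum
price c_max.  Each week the store picks the retail price that maximizes
its expected weekly profit over a discrete price grid on [0, c_max],
given its unit costs, the stock the ordinance requires it to hold, and
the food's shelf life.

Expected profit at a candidate price uses the steady-state weekly
accounting: the store holds ``q = max(required stock, demand)`` units,
sells ``demand`` of them, and — because food older than its shelf life
spoils — wastes ``max(0, q - shelf_life * demand)`` units per week on
average, which it must repurchase.  Revenue is price times sales; costs
are the wholesale and delivery cost on everything purchased plus the
storage cost on everything held.

Quantities are real-valued weekly rates; nothing is rounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .calibration import FoodParameters

__all__ = [
    "PriceGrid",
    "PriceDecision",
    "UnitCosts",
    "DemandLevers",
    "base_demand",
    "demand_at_price",
    "expected_weekly_profit",
    "optimize_price",
    "DEFAULT_GRID_RESOLUTION",
]

DEFAULT_GRID_RESOLUTION = 201


@dataclass(frozen=True)
class DemandLevers:
    """Demand-side input levers, all on the Likert 1-5 scale.

    training and signage are ordinance promotion intensities;
    convenience, taste and healthiness are the perceived food qualities.
    """

    training: float = 1.0
    signage: float = 1.0
    convenience: float = 5.0
    taste: float = 5.0
    healthiness: float = 5.0

    def vector(self) -> np.ndarray:
        return np.array(
            [1.0, self.training, self.signage, self.convenience, self.taste, self.healthiness]
        )


@dataclass(frozen=True)
class UnitCosts:
    """Per-unit weekly costs: wholesale, delivery, storage (dollars/unit)."""

    c_store: float
    c_delivery: float
    c_storage: float

    @property
    def total(self) -> float:
        return self.c_store + self.c_delivery + self.c_storage


@dataclass(frozen=True)
class PriceGrid:
    """Ascending candidate prices from 0 to c_max inclusive."""

    prices: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.prices, dtype=float)
        if p.size == 0:
            raise ValueError("price grid is empty")
        if p[0] != 0.0:
            raise ValueError("price grid must start at 0")
        if p.size > 1 and not np.all(np.diff(p) > 0):
            raise ValueError("price grid must be strictly increasing")
        object.__setattr__(self, "prices", p)

    @classmethod
    def linspace(cls, c_max: float, resolution: int = DEFAULT_GRID_RESOLUTION) -> "PriceGrid":
        if c_max <= 0:
            raise ValueError("c_max must be > 0")
        if resolution < 2:
            raise ValueError("resolution must be >= 2")
        return cls(np.linspace(0.0, c_max, resolution))

    @property
    def spacing(self) -> float:
        return float(np.max(np.diff(self.prices))) if self.prices.size > 1 else 0.0


@dataclass(frozen=True)
class PriceDecision:
    """Outcome of the weekly price optimization.

    ``price`` is the chosen retail price (ties broken toward the lower
    price), ``expected_demand`` the demand at that price,
    ``expected_profit`` the maximal steady-state weekly profit over the
    grid, and ``stock_if_voluntary`` the stock the store would hold of
    its own accord: zero when nothing is required and no price is
    profitable (the store declines to stock the food).
    """

    price: float
    expected_demand: float
    expected_profit: float
    stock_if_voluntary: float


def variety_factor(total_stock: float, gamma: float = 0.0, s_ref: float = 100.0) -> float:
    """Demand multiplier for store-level variety.

    A store with a wide variety of foods attracts more customers; the
    multiplier grows linearly in total stock up to a reference level
    ``s_ref`` and saturates at ``1 + gamma``.  Off by default
    (``gamma = 0``) because the survey data carry no information on its
    magnitude.
    """
    if total_stock < 0:
        raise ValueError("total_stock must be >= 0")
    return 1.0 + gamma * min(total_stock / s_ref, 1.0)


def base_demand(
    params: FoodParameters,
    levers: DemandLevers,
    total_stock: float = 0.0,
    *,
    gamma: float = 0.0,
    s_ref: float = 100.0,
) -> float:
    """Zero-price demand in units/week for the given lever settings.

    The additive linear score p1 + p2*training + ... + p6*healthiness,
    scaled by the variety factor and clipped to [0, d_max].
    """
    b = float(params.demand_coefficients @ levers.vector())
    b *= variety_factor(total_stock, gamma, s_ref)
    return float(np.clip(b, 0.0, params.d_max))


def demand_at_price(base: float, p7: float, price: float) -> float:
    """Demand on the linear demand-price curve: max(0, base - p7 * price)."""
    if price < 0:
        raise ValueError("price must be >= 0")
    return max(0.0, base - p7 * price)


def expected_weekly_profit(
    price: float,
    base: float,
    p7: float,
    costs: UnitCosts,
    required_stock: float,
    shelf_life_weeks: int,
) -> float:
    """Steady-state expected weekly profit at one candidate price."""
    d = demand_at_price(base, p7, price)
    q = max(required_stock, d)
    waste = max(0.0, q - shelf_life_weeks * d)
    supply = d + waste
    return (
        price * d
        - costs.c_store * supply
        - costs.c_delivery * supply
        - costs.c_storage * q
    )


def optimize_price(
    params: FoodParameters,
    base: float,
    costs: UnitCosts,
    required_stock: float,
    grid: PriceGrid,
    shelf_life_weeks: int = 1,
) -> PriceDecision:
    """Profit-maximizing price over the grid.

    Evaluates the steady-state expected weekly profit at every grid
    price and returns the argmax; at ties the lowest price wins.  When
    nothing is required and the best attainable profit is non-positive,
    the store declines to stock the food (``stock_if_voluntary = 0``).
    """
    if required_stock < 0:
        raise ValueError("required_stock must be >= 0")
    prices = grid.prices
    d = np.maximum(0.0, base - params.p7 * prices)
    q = np.maximum(required_stock, d)
    waste = np.maximum(0.0, q - shelf_life_weeks * d)
    supply = d + waste
    profit = (
        prices * d
        - costs.c_store * supply
        - costs.c_delivery * supply
        - costs.c_storage * q
    )
    i = int(np.argmax(profit))  # first max = lowest price on ties
    best = float(profit[i])
    stock = float(q[i])
    if required_stock == 0.0 and best <= 0.0:
        stock = 0.0
    return PriceDecision(
        price=float(prices[i]),
        expected_demand=float(d[i]),
        expected_profit=best,
        stock_if_voluntary=stock,
    )
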