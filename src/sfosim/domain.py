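"""Core domain types for the corner-store staple-food-ordinance model.

The model describes one urban corner store stocking a catalog of healthy
staple foods under a Staple Food Ordinance (SFO): a policy that requires
the store to keep a minimum depth of stock of each food, with a given
level of enforcement and optional promotion campaigns (owner training and
consumer signage).  This module holds the static descriptions shared by
every other module: the food catalog, the store's attributes, the policy
lever set, and the deterministic conversions between ordinal survey
ratings / qualitative policy levels and the numeric unit scale the
simulation runs on.

Units and scales
----------------
* quantities are weekly flows in "units" of food (real-valued rates);
* money is generic dollars per unit or dollars per week;
* time advances one week per simulation step;
* all perception variables are Likert ratings on the ordinal 1-5 scale.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FoodGroup",
    "FoodSpec",
    "StoreAttributes",
    "FoodOrdinance",
    "OrdinanceSpec",
    "StockLevel",
    "EnforcementLevel",
    "default_catalog",
    "read_catalog",
    "write_catalog",
    "score_to_quantity",
    "units_to_score",
    "level_to_min_stock",
    "level_to_enforcement",
    "LIKERT_MIN",
    "LIKERT_MAX",
]

LIKERT_MIN = 1
LIKERT_MAX = 5

#: Ordinal survey score -> desired weekly stock in units.  The survey
#: instrument binned quantities ("1-3 units", "4-6", "7-9", "10 or more");
#: ranges are fixed at their midpoints and the open top bin at its lower
#: bound so the conversion is a deterministic function.
_SCORE_TO_UNITS = {1: 0, 2: 2, 3: 5, 4: 8, 5: 10}

#: Bin edges used to map a continuous quantity back onto the 1-5 score
#: scale (inverse of the table above; nearest-bin rule).
_UNITS_TO_SCORE_EDGES = (0.5, 3.5, 6.5, 9.5)


class FoodGroup(str, enum.Enum):
    GRAINS = "grains"
    FRUITS = "fruits"
    VEGETABLES = "vegetables"
    DAIRY = "dairy"
    PROTEIN = "protein"


class StockLevel(str, enum.Enum):
    """Qualitative minimum-stock level of an ordinance design."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class EnforcementLevel(str, enum.Enum):
    """Qualitative stringency with which the minimum stock is imposed."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


#: Qualitative levels -> numbers, on the same unit scale as the survey
#: conversion table (low/moderate/high anchored to its 2/5/10 bins) and a
#: compliance fraction for enforcement.
_LEVEL_TO_MIN_STOCK = {StockLevel.LOW: 2.0, StockLevel.MODERATE: 5.0, StockLevel.HIGH: 10.0}
_LEVEL_TO_ENFORCEMENT = {
    EnforcementLevel.LOW: 0.2,
    EnforcementLevel.MODERATE: 0.6,
    EnforcementLevel.HIGH: 1.0,
}


def _check_likert(value: float, name: str) -> None:
    if not (LIKERT_MIN <= value <= LIKERT_MAX):
        raise ValueError(f"{name} must lie in [{LIKERT_MIN}, {LIKERT_MAX}], got {value!r}")


@dataclass(frozen=True)
class FoodSpec:
    """Static description of one staple food in the catalog.

    Parameters
    ----------
    food_id : str
        Short unique key.
    name : str
        Human-readable name.
    group : FoodGroup
        One of the five staple food groups.
    shelf_life_weeks : int
        Weeks a unit remains sellable before it spoils (>= 1).
    c_store : float
        Wholesale unit cost the store pays, dollars per unit.
    ease_of_delivery : float
        Likert 1-5 rating of how easily the food is delivered.
    mean_price : float
        Mean surveyed retail price, dollars per unit.
    """

    food_id: str
    name: str
    group: FoodGroup
    shelf_life_weeks: int
    c_store: float
    ease_of_delivery: float
    mean_price: float

    def __post_init__(self) -> None:
        if self.shelf_life_weeks < 1:
            raise ValueError(f"{self.food_id}: shelf_life_weeks must be >= 1")
        if self.c_store < 0:
            raise ValueError(f"{self.food_id}: c_store must be >= 0")
        if self.mean_price <= 0:
            raise ValueError(f"{self.food_id}: mean_price must be > 0")
        _check_likert(self.ease_of_delivery, f"{self.food_id}: ease_of_delivery")


@dataclass(frozen=True)
class StoreAttributes:
    """Attributes of the simulated corner store itself."""

    infrastructure_capacity: float = 3.0

    def __post_init__(self) -> None:
        _check_likert(self.infrastructure_capacity, "infrastructure_capacity")


@dataclass(frozen=True)
class FoodOrdinance:
    """Ordinance terms applying to a single food.

    min_stock is the required depth of stock in units per week,
    enforcement the compliance fraction in [0, 1]; training and signage
    are the promotion intensities (Likert 1-5) directed at the store owner
    and at consumers respectively; activation_time is the week at which
    the requirement (and the promotions) switch on.
    """

    min_stock: float
    enforcement: float
    training: float = 1.0
    signage: float = 1.0
    activation_time: int = 0

    def __post_init__(self) -> None:
        if self.min_stock < 0:
            raise ValueError("min_stock must be >= 0")
        if not (0.0 <= self.enforcement <= 1.0):
            raise ValueError("enforcement must lie in [0, 1]")
        _check_likert(self.training, "training")
        _check_likert(self.signage, "signage")


@dataclass
class OrdinanceSpec:
    """Per-food ordinance terms: the full policy lever set.

    A mapping from food_id to :class:`FoodOrdinance`.  Foods absent from
    the mapping are treated as unregulated (min_stock 0, enforcement 0,
    no promotions).
    """

    foods: dict[str, FoodOrdinance] = field(default_factory=dict)

    def for_food(self, food_id: str) -> FoodOrdinance:
        try:
            return self.foods[food_id]
        except KeyError:
            return FoodOrdinance(min_stock=0.0, enforcement=0.0)

    def __iter__(self):
        return iter(self.foods.items())


def score_to_quantity(score: int) -> int:
    """Convert a 1-5 desired-stock survey score to units per week.

    Mapping: 1 -> 0, 2 -> 2, 3 -> 5, 4 -> 8, 5 -> 10 (bin midpoints, the
    open "10 or more" bin at its lower bound).

    Raises
    ------
    ValueError
        If ``score`` is not one of 1..5.
    """
    try:
        key = int(score)
        if key != score:
            raise ValueError
        return _SCORE_TO_UNITS[key]
    except (KeyError, ValueError, TypeError):
        raise ValueError(f"Likert score must be an integer in 1..5, got {score!r}") from None


def units_to_score(units: float) -> int:
    """Inverse of :func:`score_to_quantity`: nearest survey bin for a quantity."""
    if units < 0:
        raise ValueError(f"units must be >= 0, got {units!r}")
    score = 1
    for edge in _UNITS_TO_SCORE_EDGES:
        if units >= edge:
            score += 1
    return score


def level_to_min_stock(level: StockLevel | str) -> float:
    """Numeric minimum stock (units/week) for a qualitative ordinance level."""
    return _LEVEL_TO_MIN_STOCK[StockLevel(level)]


def level_to_enforcement(level: EnforcementLevel | str) -> float:
    """Compliance fraction in [0, 1] for a qualitative enforcement level."""
    return _LEVEL_TO_ENFORCEMENT[EnforcementLevel(level)]


# ---------------------------------------------------------------------------
# Catalog I/O

_CATALOG_COLUMNS = [
    "food_id",
    "name",
    "group",
    "shelf_life_weeks",
    "c_store",
    "ease_of_delivery",
    "mean_price",
]


def _catalog_from_frame(df: pd.DataFrame, source: str) -> list[FoodSpec]:
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: catalog is missing columns {missing}")
    foods = [
        FoodSpec(
            food_id=str(row.food_id),
            name=str(row.name),
            group=FoodGroup(row.group),
            shelf_life_weeks=int(row.shelf_life_weeks),
            c_store=float(row.c_store),
            ease_of_delivery=float(row.ease_of_delivery),
            mean_price=float(row.mean_price),
        )
        for row in df.itertuples(index=False)
    ]
    ids = [f.food_id for f in foods]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{source}: duplicate food_id values {dupes}")
    return foods


def read_catalog(path: str | Path) -> list[FoodSpec]:
    """Read a food catalog from a CSV file with the standard header."""
    return _catalog_from_frame(pd.read_csv(path), str(path))


def write_catalog(catalog: Iterable[FoodSpec], path: str | Path) -> None:
    """Write a catalog to CSV (inverse of :func:`read_catalog`)."""
    rows = [
        {
            "food_id": f.food_id,
            "name": f.name,
            "group": f.group.value,
            "shelf_life_weeks": f.shelf_life_weeks,
            "c_store": f.c_store,
            "ease_of_delivery": f.ease_of_delivery,
            "mean_price": f.mean_price,
        }
        for f in catalog
    ]
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, index=False)


def default_catalog() -> list[FoodSpec]:
    """The packaged 22-food catalog.

    The study the model emulates surveyed 22 healthy staple foods across
    the five food groups but does not identify them, so the shipped
    catalog is synthetic: plausible corner-store items with realistic
    prices, wholesale costs and shelf lives (1-week fresh produce through
    52-week shelf-stable dry goods).  It is a plain CSV data file so users
    can replace it with their own.
    """
    ref = importlib.resources.files("sfosim.data").joinpath("default_catalog.csv")
    with importlib.resources.as_file(ref) as path:
        return read_catalog(path)


def catalog_index(catalog: Iterable[FoodSpec]) -> Mapping[str, FoodSpec]:
    """Food_id -> FoodSpec mapping for a catalog."""
    return {f.food_id: f for f in catalog}
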