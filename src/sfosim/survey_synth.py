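"""Synthetic owner and consumer survey data with known ground truth.

The calibration pipeline was designed for two small survey tables: one
from corner-store owners (perceived demand, preferred stock, logistics
ratings, prices, per store x per food) and one from regular customers
(taste / healthiness / convenience / purchase-likelihood ratings, per
respondent x per food).  Original field-survey tables are not packaged,
so this module generates surveys with the same schema and the statistical
structure the calibration assumes, while recording the generating
coefficients so recovery can be tested.

Generating scheme
-----------------
*Stores.*  Each store has a latent logistics quality ``l`` on the 1-5
scale that drives both its ease-of-delivery and infrastructure-capacity
ratings.  Surveyed prices carry a logistics premium: hard-to-reach stores
charge more, so price is linear in ``l`` with a small negative slope plus
Gaussian noise.  Preferred stock is rated at the top of
the scale by most owners (as observed in the field), which is why the
calibration takes the minimum of preferred stock and perceived demand.

*Consumers.*  Each food has latent taste / healthiness / convenience
levels; a respondent's ratings are the latent level plus personal noise,
rounded onto the 1-5 scale.  Weekly demand in units is an exact linear
function of the respondent's attribute ratings (the ground-truth
regression) plus noise, then binned onto the 1-5 purchase-likelihood
scale.  Promotion exposure (owner training, consumer signage) is absent
from the survey setting, so the true promotion coefficients are zero and
the baseline exposure level 1 is absorbed by the intercept.

``noise_scale`` scales the measurement and response noises only;
between-respondent and between-store heterogeneity of the predictors is
population structure and always present.  With ``discretize=False`` and
``noise_scale=0`` the generator emits the latent continuous values with
responses exactly on the generating lines; ordinary least squares then
recovers the ground-truth coefficients exactly, which pins down the
correctness of the calibration fits before any Likert coarsening.

Missingness is completely at random and applied only to the fields that
were incomplete in the field data: owner prices and perceived demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .domain import (
    LIKERT_MAX,
    LIKERT_MIN,
    FoodSpec,
    units_to_score,
)

__all__ = [
    "SynthTruth",
    "FoodTruth",
    "make_truth",
    "generate_owner_surveys",
    "generate_consumer_surveys",
    "read_owner_surveys",
    "read_consumer_surveys",
    "write_surveys",
    "OWNER_COLUMNS",
    "CONSUMER_COLUMNS",
]

OWNER_COLUMNS = [
    "store_id",
    "food_id",
    "preferred_stock",
    "perceived_demand",
    "ease_of_delivery",
    "infrastructure_capacity",
    "shelf_life_rating",
    "price",
]

CONSUMER_COLUMNS = [
    "respondent_id",
    "food_id",
    "taste",
    "healthiness",
    "convenience",
    "demand",
    "price_opinion",
]

#: Owner fields that may legitimately be missing (incomplete surveys).
_OWNER_MISSABLE = ("price", "perceived_demand")

# Default ranges for the ground-truth demand regression, chosen so that
# mean weekly demand per food lands in the 0-10 unit range of the survey
# conversion table, with clear variation across foods, and describes a
# population for which healthy staples are economically viable at
# moderate demand (positive margin at the optimal price for every food).
_INTERCEPT_RANGE = (0.3, 0.8)
_SLOPE_RANGE = (0.6, 0.9)
_ATTRIBUTE_RANGE = (2.5, 3.6)
_PRICE_SLOPE_FRAC = -0.04  # price premium per logistics point, x mean price


@dataclass(frozen=True)
class FoodTruth:
    """Ground-truth generating coefficients for one food."""

    #: Demand regression coefficients in the predictor order
    #: (intercept, training, signage, convenience, taste, healthiness);
    #: units per Likert point.
    beta: tuple[float, float, float, float, float, float]
    #: Latent attribute levels (convenience, taste, healthiness).
    attributes: tuple[float, float, float]
    #: Price model: price = price_intercept + price_slope * logistics.
    price_intercept: float
    price_slope: float
    #: Implied cost-regression truths (delivery = 5%, storage = 10% of price).
    delivery_intercept: float
    delivery_slope: float
    storage_intercept: float
    storage_slope: float
    #: Mean weekly demand in units at the latent attribute levels.
    mean_demand_units: float


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth recorded alongside every generated survey set."""

    foods: dict[str, FoodTruth]
    attribute_sd: float
    demand_sd: float
    price_sd: float
    rating_sd: float
    seed: int

    def beta_frame(self) -> pd.DataFrame:
        """True demand coefficients as a tidy frame (one row per food)."""
        cols = ["intercept", "training", "signage", "convenience", "taste", "healthiness"]
        return pd.DataFrame(
            {fid: dict(zip(cols, t.beta)) for fid, t in self.foods.items()}
        ).T.rename_axis("food_id")


def _shelf_life_rating(weeks: int) -> int:
    if weeks <= 1:
        return 1
    if weeks <= 3:
        return 2
    if weeks <= 8:
        return 3
    if weeks <= 26:
        return 4
    return 5


def make_truth(
    catalog: Sequence[FoodSpec],
    seed: int,
    *,
    attribute_sd: float = 1.1,
    demand_sd: float = 0.6,
    price_sd: float = 0.04,
    rating_sd: float = 0.5,
) -> SynthTruth:
    """Draw the per-food ground-truth coefficients for a survey set.

    The same ``(catalog, seed)`` pair always produces the same truth, so
    owner and consumer surveys generated with the same seed share one
    consistent population.
    """
    if not catalog:
        raise ValueError("catalog must contain at least one food")
    rng = np.random.default_rng([int(seed), 0])
    foods: dict[str, FoodTruth] = {}
    for spec in catalog:
        conv, taste, health = rng.uniform(*_ATTRIBUTE_RANGE, size=3)
        b0 = rng.uniform(*_INTERCEPT_RANGE)
        bc, bt, bh = rng.uniform(*_SLOPE_RANGE, size=3)
        beta = (b0, 0.0, 0.0, bc, bt, bh)
        price_slope = _PRICE_SLOPE_FRAC * spec.mean_price
        # price = mean_price at logistics 3: intercept absorbs the offset
        price_intercept = spec.mean_price - 3.0 * price_slope
        mean_demand = b0 + bc * conv + bt * taste + bh * health
        foods[spec.food_id] = FoodTruth(
            beta=beta,
            attributes=(conv, taste, health),
            price_intercept=price_intercept,
            price_slope=price_slope,
            delivery_intercept=0.05 * price_intercept,
            delivery_slope=0.05 * price_slope,
            storage_intercept=0.10 * price_intercept,
            storage_slope=0.10 * price_slope,
            mean_demand_units=mean_demand,
        )
    return SynthTruth(
        foods=foods,
        attribute_sd=attribute_sd,
        demand_sd=demand_sd,
        price_sd=price_sd,
        rating_sd=rating_sd,
        seed=int(seed),
    )


def _likert_round(values: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(values), LIKERT_MIN, LIKERT_MAX).astype(int)


def generate_owner_surveys(
    n_stores: int,
    catalog: Sequence[FoodSpec],
    seed: int,
    missingness_rate: float = 0.1,
    *,
    truth: SynthTruth | None = None,
    discretize: bool = True,
    noise_scale: float = 1.0,
) -> tuple[pd.DataFrame, SynthTruth]:
    """Generate the owner survey table (one row per store x food).

    Parameters
    ----------
    n_stores : int
        Number of surveyed store owners (the field study had 25).
    catalog : sequence of FoodSpec
        Foods every owner is asked about.
    seed : int
        Seed for all randomness; identical seeds give identical tables.
    missingness_rate : float
        Probability, per cell, that a price or perceived-demand entry is
        missing (completely at random).  Must lie in [0, 1).
    truth : SynthTruth, optional
        Reuse an existing ground truth (to pair with consumer surveys
        generated separately).  Defaults to ``make_truth(catalog, seed)``.
    discretize : bool
        If False, emit latent continuous ratings and prices instead of
        Likert-rounded values (for calibration diagnostics only; such
        tables are not valid survey CSVs).
    noise_scale : float
        Multiplier on every noise standard deviation; 0 gives exact
        latent-model output.

    Returns
    -------
    (DataFrame, SynthTruth)
        The survey table with the standard owner columns, and the ground
        truth that generated it.
    """
    if n_stores < 1:
        raise ValueError("n_stores must be >= 1")
    if not catalog:
        raise ValueError("catalog must contain at least one food")
    if not (0.0 <= missingness_rate < 1.0):
        raise ValueError("missingness_rate must lie in [0, 1)")
    if truth is None:
        truth = make_truth(catalog, seed)
    rng = np.random.default_rng([int(seed), 1])

    logistics = rng.uniform(1.2, 4.8, size=n_stores)
    infra_noise = rng.normal(0.0, truth.rating_sd * noise_scale, size=n_stores)
    rows: list[dict] = []
    for i in range(n_stores):
        store_id = f"store_{i + 1:02d}"
        ease_lat = logistics[i]
        infra_lat = logistics[i] + infra_noise[i]
        for spec in catalog:
            t = truth.foods[spec.food_id]
            price = t.price_intercept + t.price_slope * ease_lat
            price += rng.normal(0.0, truth.price_sd * spec.mean_price * noise_scale)
            demand_units = t.mean_demand_units + rng.normal(
                0.0, truth.demand_sd * noise_scale
            )
            ease_noisy = ease_lat + rng.normal(0.0, truth.rating_sd * noise_scale)
            preferred = 5 if rng.random() < 0.8 else 4
            if discretize:
                ease = int(_likert_round(np.array([ease_noisy]))[0])
                infra = int(_likert_round(np.array([infra_lat]))[0])
                perceived = units_to_score(max(0.0, demand_units))
            else:
                ease = ease_lat
                infra = infra_lat
                perceived = max(0.0, demand_units)
            rows.append(
                {
                    "store_id": store_id,
                    "food_id": spec.food_id,
                    "preferred_stock": preferred,
                    "perceived_demand": perceived,
                    "ease_of_delivery": ease,
                    "infrastructure_capacity": infra,
                    "shelf_life_rating": _shelf_life_rating(spec.shelf_life_weeks),
                    "price": max(0.01, price),
                }
            )
    df = pd.DataFrame(rows, columns=OWNER_COLUMNS)

    if missingness_rate > 0:
        for col in _OWNER_MISSABLE:
            mask = rng.random(len(df)) < missingness_rate
            df.loc[mask, col] = np.nan
    return df, truth


def generate_consumer_surveys(
    n_consumers: int,
    catalog: Sequence[FoodSpec],
    seed: int,
    *,
    truth: SynthTruth | None = None,
    discretize: bool = True,
    noise_scale: float = 1.0,
) -> tuple[pd.DataFrame, SynthTruth]:
    """Generate the consumer survey table (one row per respondent x food).

    The field study interviewed 23 regular customers.  Same conventions
    as :func:`generate_owner_surveys`, without prices or missingness.
    """
    if n_consumers < 1:
        raise ValueError("n_consumers must be >= 1")
    if not catalog:
        raise ValueError("catalog must contain at least one food")
    if truth is None:
        truth = make_truth(catalog, seed)
    rng = np.random.default_rng([int(seed), 2])

    rows: list[dict] = []
    for j in range(n_consumers):
        respondent_id = f"resp_{j + 1:02d}"
        for spec in catalog:
            t = truth.foods[spec.food_id]
            # attribute dispersion is respondent heterogeneity (design
            # variation), deliberately not scaled by noise_scale
            conv_lat, taste_lat, health_lat = (
                np.array(t.attributes)
                + rng.normal(0.0, truth.attribute_sd, size=3)
            )
            if discretize:
                conv, taste, health = _likert_round(
                    np.array([conv_lat, taste_lat, health_lat])
                )
            else:
                conv, taste, health = conv_lat, taste_lat, health_lat
            b0, _, _, bc, bt, bh = t.beta
            demand_units = (
                b0
                + bc * conv
                + bt * taste
                + bh * health
                + rng.normal(0.0, truth.demand_sd * noise_scale)
            )
            # cheaper foods rate better on price opinion
            opinion_lat = 6.0 - 1.2 * spec.mean_price + rng.normal(
                0.0, truth.rating_sd * noise_scale
            )
            if discretize:
                demand = units_to_score(max(0.0, demand_units))
                opinion = int(_likert_round(np.array([opinion_lat]))[0])
            else:
                demand = max(0.0, demand_units)
                opinion = opinion_lat
            rows.append(
                {
                    "respondent_id": respondent_id,
                    "food_id": spec.food_id,
                    "taste": taste,
                    "healthiness": health,
                    "convenience": conv,
                    "demand": demand,
                    "price_opinion": opinion,
                }
            )
    return pd.DataFrame(rows, columns=CONSUMER_COLUMNS), truth


# ---------------------------------------------------------------------------
# Survey CSV I/O with validation


class SurveyFormatError(ValueError):
    """Raised when a survey CSV does not conform to the declared schema."""


def _validate_surveys(
    df: pd.DataFrame,
    columns: Sequence[str],
    likert_columns: Sequence[str],
    missable: Sequence[str],
    source: str,
) -> pd.DataFrame:
    unknown = [c for c in df.columns if c not in columns]
    if unknown:
        raise SurveyFormatError(f"{source}: unknown column(s) {unknown}")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"{source}: missing column(s) {missing}")
    if len(df) == 0:
        raise SurveyFormatError(f"{source}: no records")
    for col in likert_columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad_numeric = df[col].notna() & values.isna()
        if bad_numeric.any():
            row = int(df.index[bad_numeric][0])
            raise SurveyFormatError(
                f"{source}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        na = values.isna()
        if na.any() and col not in missable:
            row = int(df.index[na][0])
            raise SurveyFormatError(f"{source}: missing value in column {col!r}, row {row}")
        out_of_range = values.notna() & ((values < LIKERT_MIN) | (values > LIKERT_MAX))
        if out_of_range.any():
            row = int(df.index[out_of_range][0])
            raise SurveyFormatError(
                f"{source}: Likert value {values.iloc[row]} out of range 1-5 "
                f"in column {col!r}, row {row}"
            )
        df[col] = values
    return df[list(columns)]


def read_owner_surveys(path: str | Path) -> pd.DataFrame:
    """Read and validate an owner survey CSV (empty cell = missing)."""
    df = pd.read_csv(path)
    df = _validate_surveys(
        df,
        OWNER_COLUMNS,
        likert_columns=[
            "preferred_stock",
            "perceived_demand",
            "ease_of_delivery",
            "infrastructure_capacity",
            "shelf_life_rating",
        ],
        missable=["perceived_demand"],
        source=str(path),
    )
    price = pd.to_numeric(df["price"], errors="coerce")
    bad = df["price"].notna() & price.isna()
    if bad.any():
        row = int(df.index[bad][0])
        raise SurveyFormatError(
            f"{path}: non-numeric price {df['price'].iloc[row]!r} in row {row}"
        )
    nonpos = price.notna() & (price <= 0)
    if nonpos.any():
        row = int(df.index[nonpos][0])
        raise SurveyFormatError(f"{path}: price must be > 0 in row {row}")
    df["price"] = price
    return df


def read_consumer_surveys(path: str | Path) -> pd.DataFrame:
    """Read and validate a consumer survey CSV."""
    return _validate_surveys(
        pd.read_csv(path),
        CONSUMER_COLUMNS,
        likert_columns=["taste", "healthiness", "convenience", "demand", "price_opinion"],
        missable=[],
        source=str(path),
    )


def write_surveys(records: pd.DataFrame, path: str | Path) -> None:
    """Write a survey table to CSV; round-trips with the readers."""
    records.to_csv(path, index=False)
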