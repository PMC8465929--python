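"""Survey-to-parameter calibration.

Turns the owner and consumer survey tables into the per-food coefficient
set the simulation runs on:

* two simple cost regressions — unit delivery cost (assumed 5% of the
  surveyed price) on the ease-of-delivery rating, and unit storage cost
  (assumed 10% of the price) on the infrastructure-capacity rating;
* a demand projection that imputes per-respondent weekly demand in units
  by combining owner and consumer data: each owner's desired stock is the
  minimum of their preferred stock and their perceived customer demand
  (preferred stock is nearly constant at the top of the scale, so the
  minimum carries the information), converted to units via the survey
  conversion table; consumer demand ratings are converted the same way
  and rescaled by the ratio of the owner demand mean to the consumer
  demand mean;
* a multi-predictor demand regression of the projected demand on
  promotion and quality covariates (training, signage, convenience,
  taste, healthiness), giving coefficients p1..p6 in units per Likert
  point;
* the demand-price line: maximum demand d_max is the regression
  evaluated with every predictor at the scale maximum of 5 (all six
  coefficients multiplied by five and summed), the maximum price c_max is
  200% of the mean price (the price at which demand reaches zero), and
  the slope p7 = d_max / c_max.

Every fit is repeated independently for each food.  Missing survey
entries are removed listwise per fit; degenerate fits (a single usable
row, or a predictor with no variance) return slope zero and an intercept
at the mean response so that every food stays simulable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domain import FoodSpec, score_to_quantity

__all__ = [
    "CalibrationError",
    "FoodParameters",
    "DemandProjection",
    "fit_linear_cost",
    "project_demand",
    "fit_demand_params",
    "derive_price_curve",
    "calibrate_all",
    "save_parameters",
    "load_parameters",
    "DELIVERY_COST_FRACTION",
    "STORAGE_COST_FRACTION",
    "MAX_PRICE_MULTIPLIER",
]

#: Unit delivery cost is assumed to be 5% of the retail price.
DELIVERY_COST_FRACTION = 0.05
#: Unit storage cost is assumed to be 10% of the retail price.
STORAGE_COST_FRACTION = 0.10
#: The maximum price (zero-demand price) is 200% of the mean price.
MAX_PRICE_MULTIPLIER = 2.0


class CalibrationError(ValueError):
    """Raised when a fit has no usable data or an undefined quantity."""


@dataclass(frozen=True)
class FoodParameters:
    """Calibrated coefficients for one food.

    p1..p6 are the demand regression intercept and slopes (units per
    Likert point of training, signage, convenience, taste, healthiness);
    p7 is the demand-price slope in units per dollar; p10/p11 and
    p12/p13 are the intercept/slope pairs of the delivery-cost and
    storage-cost regressions; d_max and c_max are the demand and price
    axis intercepts of the demand-price line; c_store is the wholesale
    unit cost.  Parameter indices 8 and 9 are not part of this set.
    """

    food_id: str
    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    p10: float
    p11: float
    p12: float
    p13: float
    d_max: float
    c_max: float
    c_store: float

    def __post_init__(self) -> None:
        if self.c_max <= 0:
            raise ValueError(f"{self.food_id}: c_max must be > 0")
        if self.p7 < 0:
            raise ValueError(f"{self.food_id}: p7 must be >= 0")

    @property
    def demand_coefficients(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4, self.p5, self.p6])


@dataclass
class DemandProjection:
    """Projected per-respondent demand for one food.

    ``r_desired`` is each owner's desired-stock rating (minimum of
    preferred stock and perceived demand) and ``desired_units`` its unit
    conversion; ``mu_owner`` / ``mu_consumer`` are the owner and consumer
    demand means in units; ``projected_y`` is the consumer demand vector
    rescaled by ``mu_owner / mu_consumer``, aligned with
    ``consumer_rows`` (the covariate rows used downstream).
    """

    food_id: str
    r_desired: pd.Series
    desired_units: pd.Series
    mu_owner: float
    mu_consumer: float
    projected_y: np.ndarray
    consumer_rows: pd.DataFrame
    owner_mean_fallback: bool = False


def fit_linear_cost(
    x: Sequence[float], prices: Sequence[float], fraction: float
) -> tuple[float, float]:
    """Least-squares line of ``fraction * price`` on a Likert predictor.

    Parameters are paired vectors with missing rows already removed.
    Returns ``(intercept, slope)``.  With one usable row or a
    zero-variance predictor the slope is 0 and the intercept is the mean
    response; with zero rows a :class:`CalibrationError` is raised.
    """
    x = np.asarray(x, dtype=float)
    y = fraction * np.asarray(prices, dtype=float)
    if x.shape != y.shape:
        raise CalibrationError(
            f"predictor and price vectors differ in length ({x.size} vs {y.size})"
        )
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise CalibrationError("no usable rows for cost regression")
    if x.size == 1 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float(np.mean(y)), 0.0
    xbar, ybar = x.mean(), y.mean()
    slope = float(np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2))
    return float(ybar - slope * xbar), slope


def project_demand(
    owners: pd.DataFrame,
    consumers: pd.DataFrame,
    food_id: str,
) -> DemandProjection:
    """Project per-respondent weekly demand in units for one food.

    Combines the two surveys: owner desired stock (minimum of preferred
    stock and perceived demand, converted to units) sets the demand
    level; consumer demand ratings set its variation.  Each consumer's
    converted demand is multiplied by the ratio of the owner demand mean
    to the consumer demand mean.  For a food with no usable owner demand
    data, the owner mean is replaced by the average of the owner demand
    means of all other foods.
    """
    cons = consumers[consumers["food_id"] == food_id]
    if len(cons) == 0:
        raise CalibrationError(f"{food_id}: no consumer survey rows")
    cons = cons.dropna(subset=["demand"])
    if len(cons) == 0:
        raise CalibrationError(f"{food_id}: no consumer demand ratings")

    def _owner_units(rows: pd.DataFrame) -> pd.DataFrame:
        rows = rows.dropna(subset=["perceived_demand", "preferred_stock"])
        if len(rows) == 0:
            return rows.assign(r_desired=pd.Series(dtype=float), desired_units=pd.Series(dtype=float))
        r = np.minimum(rows["preferred_stock"], rows["perceived_demand"]).astype(int)
        units = r.map(score_to_quantity)
        return rows.assign(r_desired=r, desired_units=units)

    own_food = _owner_units(owners[owners["food_id"] == food_id])
    fallback = False
    if len(own_food) > 0:
        mu_owner = float(own_food["desired_units"].mean())
        r_desired = own_food.set_index("store_id")["r_desired"]
        desired_units = own_food.set_index("store_id")["desired_units"]
    else:
        # across-food average of the per-food owner demand means
        other_means = []
        for fid, rows in owners[owners["food_id"] != food_id].groupby("food_id"):
            units = _owner_units(rows)
            if len(units) > 0:
                other_means.append(float(units["desired_units"].mean()))
        if not other_means:
            raise CalibrationError(f"{food_id}: no owner demand data for any food")
        mu_owner = float(np.mean(other_means))
        fallback = True
        r_desired = pd.Series(dtype=int)
        desired_units = pd.Series(dtype=int)

    consumer_units = cons["demand"].astype(int).map(score_to_quantity).astype(float)
    mu_consumer = float(consumer_units.mean())
    if mu_consumer == 0.0:
        raise CalibrationError(
            f"{food_id}: consumer demand mean is zero, projection ratio undefined"
        )
    projected = consumer_units.to_numpy() * (mu_owner / mu_consumer)
    return DemandProjection(
        food_id=food_id,
        r_desired=r_desired,
        desired_units=desired_units,
        mu_owner=mu_owner,
        mu_consumer=mu_consumer,
        projected_y=projected,
        consumer_rows=cons.reset_index(drop=True),
        owner_mean_fallback=fallback,
    )


def fit_demand_params(y: Sequence[float], x: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Least-squares demand regression coefficients p1..p6.

    ``x`` has five columns in the fixed predictor order (training,
    signage, convenience, taste, healthiness); an intercept is added.
    Rows with missing values are removed; at least six complete rows are
    required.  A predictor with no variance gets coefficient 0 and its
    constant effect is absorbed by the intercept; a genuinely
    rank-deficient design falls back to the minimum-norm solution with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 5:
        raise CalibrationError(f"X must have 5 columns, got shape {x.shape}")
    if y.shape[0] != x.shape[0]:
        raise CalibrationError(
            f"Y length {y.shape[0]} does not match X rows {x.shape[0]}"
        )
    keep = ~(np.isnan(y) | np.isnan(x).any(axis=1))
    y, x = y[keep], x[keep]
    if y.shape[0] < 6:
        raise CalibrationError(
            f"need at least 6 complete rows for the demand regression, got {y.shape[0]}"
        )
    constant = np.ptp(x, axis=0) == 0.0
    design = np.column_stack([np.ones(len(y)), x[:, ~constant]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient demand design; using minimum-norm least squares",
            stacklevel=2,
        )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    params = np.zeros(6)
    params[0] = coef[0]
    params[np.flatnonzero(~constant) + 1] = coef[1:]
    return params


def derive_price_curve(
    params: Sequence[float], mean_price: float
) -> tuple[float, float, float]:
    """Demand-price line from the regression coefficients.

    d_max evaluates the demand regression with every predictor at the
    scale maximum (all six coefficients times five, summed), clipped at
    zero; c_max is 200% of the mean price; p7 = d_max / c_max.
    Returns ``(d_max, c_max, p7)``.
    """
    if mean_price <= 0:
        raise CalibrationError(f"mean_price must be > 0, got {mean_price}")
    params = np.asarray(params, dtype=float)
    if params.size != 6:
        raise CalibrationError(f"expected 6 demand coefficients, got {params.size}")
    d_max = max(0.0, 5.0 * float(params.sum()))
    c_max = MAX_PRICE_MULTIPLIER * float(mean_price)
    return d_max, c_max, d_max / c_max


def calibrate_all(
    owners: pd.DataFrame,
    consumers: pd.DataFrame,
    catalog: Sequence[FoodSpec],
    *,
    baseline_training: float = 1.0,
    baseline_signage: float = 1.0,
) -> dict[str, FoodParameters]:
    """Run the full calibration for every food in the catalog.

    Per food: the delivery and storage cost fits, the demand projection,
    the demand regression (with promotion covariates at their survey
    baseline, absorbed by the intercept), and the demand-price line.
    The price entering c_max is the higher of the mean surveyed price
    and the catalog price; with no surveyed prices the catalog price
    stands in.  A food with no usable survey rows raises a
    :class:`CalibrationError` naming it.
    """
    out: dict[str, FoodParameters] = {}
    for spec in catalog:
        fid = spec.food_id
        try:
            own = owners[owners["food_id"] == fid]
            if len(own) == 0 and len(consumers[consumers["food_id"] == fid]) == 0:
                raise CalibrationError(f"{fid}: no survey rows for this food")

            prices = own["price"] if "price" in own else pd.Series(dtype=float)
            usable_prices = prices.dropna()
            if len(usable_prices) > 0:
                mean_price = max(float(usable_prices.mean()), spec.mean_price)
            else:
                mean_price = spec.mean_price

            if len(usable_prices) > 0:
                p10, p11 = fit_linear_cost(
                    own["ease_of_delivery"], own["price"], DELIVERY_COST_FRACTION
                )
                p12, p13 = fit_linear_cost(
                    own["infrastructure_capacity"], own["price"], STORAGE_COST_FRACTION
                )
            else:
                # no surveyed prices at all: flat cost at the fallback price
                p10, p11 = DELIVERY_COST_FRACTION * mean_price, 0.0
                p12, p13 = STORAGE_COST_FRACTION * mean_price, 0.0

            projection = project_demand(owners, consumers, fid)
            rows = projection.consumer_rows
            x = np.column_stack(
                [
                    np.full(len(rows), baseline_training),
                    np.full(len(rows), baseline_signage),
                    rows["convenience"].to_numpy(dtype=float),
                    rows["taste"].to_numpy(dtype=float),
                    rows["healthiness"].to_numpy(dtype=float),
                ]
            )
            p = fit_demand_params(projection.projected_y, x)
            d_max, c_max, p7 = derive_price_curve(p, mean_price)
        except CalibrationError as err:
            if str(err).startswith(f"{fid}:"):
                raise
            raise CalibrationError(f"{fid}: {err}") from err

        out[fid] = FoodParameters(
            food_id=fid,
            p1=float(p[0]),
            p2=float(p[1]),
            p3=float(p[2]),
            p4=float(p[3]),
            p5=float(p[4]),
            p6=float(p[5]),
            p7=p7,
            p10=p10,
            p11=p11,
            p12=p12,
            p13=p13,
            d_max=d_max,
            c_max=c_max,
            c_store=spec.c_store,
        )
    return out


def save_parameters(params: Mapping[str, FoodParameters], path: str | Path) -> None:
    """Serialize a calibrated parameter set to JSON keyed by food_id."""
    payload = {fid: asdict(p) for fid, p in params.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_parameters(path: str | Path) -> dict[str, FoodParameters]:
    """Load a parameter set written by :func:`save_parameters`."""
    payload = json.loads(Path(path).read_text())
    return {fid: FoodParameters(**vals) for fid, vals in payload.items()}
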