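"""The shipped default calibration.

A complete, deterministic parameter set obtained by generating the
default synthetic surveys (25 store owners, 23 consumers, the packaged
22-food catalog) and running the full calibration on them.  This is the
calibration the scenario regression suite and the packaged examples run
against; it stands in for a calibration of real survey data.
"""

from __future__ import annotations

from .calibration import FoodParameters, calibrate_all
from .domain import FoodSpec, default_catalog
from .survey_synth import generate_consumer_surveys, generate_owner_surveys

__all__ = ["DEFAULT_SEED", "default_calibration"]

#: Seed of the shipped default synthetic survey set.
DEFAULT_SEED = 2021


def default_calibration(
    seed: int = DEFAULT_SEED,
    n_stores: int = 25,
    n_consumers: int = 23,
    missingness_rate: float = 0.1,
) -> tuple[list[FoodSpec], dict[str, FoodParameters]]:
    """Catalog plus calibrated parameters from default synthetic surveys."""
    catalog = default_catalog()
    owners, truth = generate_owner_surveys(
        n_stores, catalog, seed, missingness_rate=missingness_rate
    )
    consumers, _ = generate_consumer_surveys(n_consumers, catalog, seed, truth=truth)
    return catalog, calibrate_all(owners, consumers, catalog)
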