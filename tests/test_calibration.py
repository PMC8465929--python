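import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sfosim.calibration import (
    CalibrationError,
    calibrate_all,
    derive_price_curve,
    fit_demand_params,
    fit_linear_cost,
    load_parameters,
    project_demand,
    save_parameters,
)
from sfosim.survey_synth import generate_consumer_surveys, generate_owner_surveys


def owner_frame(rows):
    cols = [
        "store_id", "food_id", "preferred_stock", "perceived_demand",
        "ease_of_delivery", "infrastructure_capacity", "shelf_life_rating", "price",
    ]
    return pd.DataFrame(rows, columns=cols)


def consumer_frame(rows):
    cols = [
        "respondent_id", "food_id", "taste", "healthiness", "convenience",
        "demand", "price_opinion",
    ]
    return pd.DataFrame(rows, columns=cols)


class TestFitLinearCost:
    def test_closed_form_example(self):
        # slope = sum((x-xbar)(y-ybar)) / sum((x-xbar)^2) on 5% of price
        intercept, slope = fit_linear_cost([1, 3, 5], [1, 2, 3], 0.05)
        assert intercept == pytest.approx(0.025, abs=1e-12)
        assert slope == pytest.approx(0.025, abs=1e-12)

    def test_constant_prices_give_flat_line(self):
        intercept, slope = fit_linear_cost([1, 2, 5], [2, 2, 2], 0.05)
        assert (intercept, slope) == (pytest.approx(0.1), 0.0)

    def test_all_missing_raises(self):
        with pytest.raises(CalibrationError, match="no usable rows"):
            fit_linear_cost([1, 2], [np.nan, np.nan], 0.05)

    def test_single_row_degenerates_to_mean(self):
        assert fit_linear_cost([4], [3.0], 0.10) == (pytest.approx(0.3), 0.0)

    def test_zero_variance_predictor_degenerates_to_mean(self):
        intercept, slope = fit_linear_cost([3, 3, 3], [1.0, 2.0, 3.0], 0.10)
        assert (intercept, slope) == (pytest.approx(0.2), 0.0)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        x = rng.integers(1, 6, size=n).astype(float)
        prices = rng.uniform(0.5, 5.0, size=n)
        if np.ptp(x) == 0:
            x[0] += 1
        intercept, slope = fit_linear_cost(x, prices, 0.05)
        design = np.column_stack([np.ones(n), x])
        oracle = np.linalg.solve(design.T @ design, design.T @ (0.05 * prices))
        assert np.allclose([intercept, slope], oracle, atol=1e-8)


class TestProjectDemand:
    def test_desired_stock_is_min_of_preferred_and_perceived(self):
        owners = owner_frame([["s1", "f", 5, 3, 3, 3, 2, 1.0]])
        consumers = consumer_frame([["r1", "f", 3, 3, 3, 2, 3]])
        proj = project_demand(owners, consumers, "f")
        assert proj.r_desired.loc["s1"] == 3
        assert proj.desired_units.loc["s1"] == 5

    def test_projection_scales_by_owner_consumer_ratio(self):
        # owner desired units {2, 10} -> mu_owner 6; consumer units {5, 2}
        owners = owner_frame(
            [["s1", "f", 2, 2, 3, 3, 2, 1.0], ["s2", "f", 5, 5, 3, 3, 2, 1.0]]
        )
        consumers = consumer_frame(
            [["r1", "f", 3, 3, 3, 3, 3], ["r2", "f", 3, 3, 3, 2, 3]]
        )
        proj = project_demand(owners, consumers, "f")
        assert proj.mu_owner == pytest.approx(6.0)
        assert proj.mu_consumer == pytest.approx(3.5)
        assert proj.projected_y == pytest.approx([5 * 6 / 3.5, 2 * 6 / 3.5])

    def test_missing_owner_data_falls_back_to_cross_food_mean(self):
        # food a: units {0, 8} -> mean 4; food b: units {2, 10} -> mean 6
        owners = owner_frame(
            [
                ["s1", "a", 1, 1, 3, 3, 2, 1.0], ["s2", "a", 4, 4, 3, 3, 2, 1.0],
                ["s1", "b", 2, 2, 3, 3, 2, 1.0], ["s2", "b", 5, 5, 3, 3, 2, 1.0],
            ]
        )
        consumers = consumer_frame([["r1", "c", 3, 3, 3, 3, 3]])
        proj = project_demand(owners, consumers, "c")
        assert proj.mu_owner == pytest.approx(5.0)
        assert proj.owner_mean_fallback

    def test_zero_consumer_demand_mean_is_undefined(self):
        owners = owner_frame([["s1", "f", 5, 3, 3, 3, 2, 1.0]])
        consumers = consumer_frame([["r1", "f", 3, 3, 3, 1, 3]])  # score 1 -> 0 units
        with pytest.raises(CalibrationError, match="ratio undefined"):
            project_demand(owners, consumers, "f")

    def test_unknown_food_raises(self):
        owners = owner_frame([["s1", "f", 5, 3, 3, 3, 2, 1.0]])
        consumers = consumer_frame([["r1", "f", 3, 3, 3, 2, 3]])
        with pytest.raises(CalibrationError, match="no consumer survey rows"):
            project_demand(owners, consumers, "ghost")


class TestFitDemandParams:
    def test_recovers_exact_linear_combination(self):
        rng = np.random.default_rng(0)
        beta = np.array([1.0, 0.5, 0.5, 1.0, 2.0, 3.0])
        x = rng.uniform(1, 5, size=(40, 5))
        y = beta[0] + x @ beta[1:]
        fitted = fit_demand_params(y, x)
        assert np.allclose(fitted, beta, atol=1e-8)

    def test_constant_design_reproduces_constant_response(self):
        x = np.full((10, 5), 5.0)
        y = np.full(10, 7.25)
        p = fit_demand_params(y, x)
        assert p[0] + 5 * p[1:].sum() == pytest.approx(7.25)

    def test_shape_mismatch_raises(self):
        with pytest.raises(CalibrationError, match="does not match"):
            fit_demand_params(np.ones(4), np.ones((5, 5)))

    def test_too_few_rows_raises(self):
        with pytest.raises(CalibrationError, match="at least 6"):
            fit_demand_params(np.ones(5), np.ones((5, 5)) * np.arange(5)[:, None])

    def test_rank_deficient_design_warns_and_solves(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 5, size=(20, 5))
        x[:, 1] = x[:, 2]  # duplicated varying column
        y = 1.0 + x.sum(axis=1)
        with pytest.warns(UserWarning, match="rank-deficient"):
            fitted = fit_demand_params(y, x)
        design = np.column_stack([np.ones(20), x])
        assert np.allclose(design @ np.concatenate([[fitted[0]], fitted[1:]]), y, atol=1e-8)

    def test_missing_rows_dropped_listwise(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 5, size=(12, 5))
        y = 2.0 + x @ np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        x_nan = np.vstack([x, np.full((1, 5), np.nan)])
        y_nan = np.append(y, 99.0)
        assert np.allclose(fit_demand_params(y_nan, x_nan), fit_demand_params(y, x))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 40)
        x = rng.uniform(1, 5, size=(n, 5))
        y = rng.normal(size=n)
        fitted = fit_demand_params(y, x)
        design = np.column_stack([np.ones(n), x])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(fitted, oracle, atol=1e-8)


class TestPriceCurve:
    def test_worked_example(self):
        d_max, c_max, p7 = derive_price_curve([1, 1, 1, 1, 1, 1], 2.0)
        assert (d_max, c_max, p7) == (30.0, 4.0, 7.5)

    def test_max_price_is_double_the_mean(self):
        assert derive_price_curve([0.5] * 6, 2.0)[1] == 4.0

    def test_zero_coefficients_give_degenerate_curve(self):
        d_max, _, p7 = derive_price_curve([0] * 6, 2.0)
        assert d_max == 0.0 and p7 == 0.0

    def test_negative_demand_clipped_at_zero(self):
        d_max, _, p7 = derive_price_curve([-1, 0, 0, 0, 0, 0], 2.0)
        assert d_max == 0.0 and p7 == 0.0

    def test_slope_scales_with_demand_and_inversely_with_price(self):
        _, _, p7 = derive_price_curve([1] * 6, 2.0)
        _, _, p7_double_demand = derive_price_curve([2] * 6, 2.0)
        _, _, p7_double_price = derive_price_curve([1] * 6, 4.0)
        assert p7_double_demand == pytest.approx(2 * p7)
        assert p7_double_price == pytest.approx(p7 / 2)


class TestCalibrateAll:
    def test_full_catalog_yields_22_parameter_sets(self, catalog):
        owners, truth = generate_owner_surveys(25, catalog, 6)
        consumers, _ = generate_consumer_surveys(23, catalog, 6, truth=truth)
        params = calibrate_all(owners, consumers, catalog)
        assert len(params) == 22
        for p in params.values():
            assert p.c_max > 0
            if p.d_max > 0:
                assert p.p7 == pytest.approx(p.d_max / p.c_max)

    def test_food_missing_from_surveys_is_named(self, catalog):
        owners, truth = generate_owner_surveys(10, catalog, 6)
        consumers, _ = generate_consumer_surveys(10, catalog, 6, truth=truth)
        fid = catalog[0].food_id
        owners = owners[owners["food_id"] != fid]
        consumers = consumers[consumers["food_id"] != fid]
        with pytest.raises(CalibrationError, match=fid):
            calibrate_all(owners, consumers, catalog)

    def test_parameters_roundtrip_through_json(self, catalog, tmp_path):
        owners, truth = generate_owner_surveys(10, catalog, 6)
        consumers, _ = generate_consumer_surveys(10, catalog, 6, truth=truth)
        params = calibrate_all(owners, consumers, catalog)
        path = tmp_path / "params.json"
        save_parameters(params, path)
        assert load_parameters(path) == params
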