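import numpy as np
import pandas as pd
import pytest

from sfosim.domain import (
    FoodGroup,
    FoodOrdinance,
    FoodSpec,
    OrdinanceSpec,
    StoreAttributes,
)
from sfosim.engine import (
    ConfigurationError,
    InventoryCohorts,
    SimulationConfig,
    ordinance_schedule,
    required_stock,
    run_simulation,
    step_food,
)


def food(fid="tomato", shelf=100, ease=3.0, price=1.0, c_store=0.5):
    return FoodSpec(fid, fid.title(), FoodGroup.VEGETABLES, shelf, c_store, ease, price)


def ordinance(min_stock=0.0, enforcement=0.0, activation=3, training=5, signage=5):
    return FoodOrdinance(
        min_stock=min_stock, enforcement=enforcement,
        training=training, signage=signage, activation_time=activation,
    )


class TestSchedule:
    def test_first_food_activates_at_start_step(self, catalog):
        sched = ordinance_schedule(catalog)
        assert sched[catalog[0].food_id] == 3

    def test_one_new_food_every_two_weeks(self, catalog):
        sched = ordinance_schedule(catalog)
        times = [sched[f.food_id] for f in catalog]
        assert np.all(np.diff(times) == 2)

    def test_spacing_one_ends_at_arithmetic_bound(self, catalog):
        sched = ordinance_schedule(catalog, start_step=3, spacing=1)
        assert max(sched.values()) == 3 + 21


class TestRequiredStock:
    def test_zero_before_activation(self):
        assert required_stock(ordinance(10, 1.0, activation=5), 4) == 0.0

    def test_full_enforcement_requires_full_minimum(self):
        assert required_stock(ordinance(10, 1.0, activation=5), 5) == 10.0

    def test_partial_enforcement_scales_requirement(self):
        assert required_stock(ordinance(10, 0.2, activation=5), 9) == pytest.approx(2.0)


class TestInventoryCohorts:
    def test_sells_oldest_first(self):
        inv = InventoryCohorts([(2, 3.0), (0, 4.0)])
        sold = inv.sell_fifo(5.0)
        assert sold == 5.0
        assert inv.cohorts() == [(0, 2.0)]

    def test_aging_spoils_cohorts_at_shelf_life(self):
        inv = InventoryCohorts([(2, 3.0), (0, 4.0)])
        waste = inv.age_and_spoil(3)
        assert waste == 3.0
        assert inv.cohorts() == [(1, 4.0)]
        assert all(age < 3 for age, _ in inv.cohorts())

    def test_rejects_negative_quantities(self):
        with pytest.raises(AssertionError):
            InventoryCohorts([(0, -1.0)])


class TestStepFood:
    def test_conservation_with_long_shelf_life(self, params_factory):
        # stock 10, demand 4 -> sell 4, no spoilage, 6 left over
        p = params_factory(p1=4.0, p4=0, p5=0, p6=0, p7=0.0, d_max=20.0)
        state, inv = step_food(
            InventoryCohorts(), 0.0, p, ordinance(10, 1.0, activation=0),
            StoreAttributes(), 3, food(shelf=100),
        )
        assert state.y_actual == 10.0
        assert state.y_cust == 4.0
        assert state.y_waste == 0.0
        assert state.y_actual_end == 6.0
        assert inv.total() == 6.0

    def test_full_spoilage_of_one_week_shelf_life(self, params_factory):
        p = params_factory(p1=0, p4=0, p5=0, p6=0, p7=0.0, d_max=0.0)
        state, inv = step_food(
            InventoryCohorts(), 0.0, p, ordinance(7, 1.0, activation=0),
            StoreAttributes(), 3, food(shelf=1),
        )
        assert state.y_supply == 7.0
        assert state.y_waste == 7.0
        assert state.y_actual_end == 0.0
        assert inv.total() == 0.0

    def test_sales_clamped_by_stock(self, params_factory):
        p = params_factory(p1=12.0, p4=0, p5=0, p6=0, p7=0.0, d_max=20.0)
        state, _ = step_food(
            InventoryCohorts(), 0.0, p, ordinance(10, 1.0, activation=0),
            StoreAttributes(), 3, food(shelf=100),
        )
        assert state.y_demand == 12.0
        assert state.y_cust == 10.0

    def test_mass_balance_and_accounting_on_random_states(self, params_factory):
        rng = np.random.default_rng(123)
        for _ in range(200):
            shelf = int(rng.integers(1, 9))
            d_max = rng.uniform(0, 15)
            c_max = rng.uniform(0.5, 5)
            p = params_factory(
                p1=rng.uniform(0, 3), p4=rng.uniform(0, 1), p5=rng.uniform(0, 1),
                p6=rng.uniform(0, 1), p7=d_max / c_max, d_max=d_max, c_max=c_max,
                p10=rng.uniform(0, 0.2), p11=rng.uniform(-0.02, 0.02),
                p12=rng.uniform(0, 0.3), p13=rng.uniform(-0.03, 0.03),
                c_store=rng.uniform(0.1, 2),
            )
            ages = rng.integers(0, shelf, size=3)
            carry = InventoryCohorts([(int(a), float(q)) for a, q in
                                      zip(ages, rng.uniform(0, 4, size=3))])
            leftover = carry.total()
            ordn = ordinance(
                min_stock=float(rng.uniform(0, 12)), enforcement=float(rng.uniform(0, 1)),
                activation=int(rng.integers(0, 8)),
            )
            state, inv = step_food(
                carry, float(rng.uniform(0, 12)), p, ordn,
                StoreAttributes(float(rng.uniform(1, 5))), int(rng.integers(3, 12)),
                food(shelf=shelf), total_stock_prev=float(rng.uniform(0, 150)),
            )
            assert state.y_supply >= 0 and state.y_waste >= 0 and state.y_cust >= 0
            assert state.y_actual == pytest.approx(state.y_supply + leftover, abs=1e-9)
            assert state.y_actual == pytest.approx(
                state.y_cust + state.y_waste + state.y_actual_end, abs=1e-9
            )
            assert state.y_cust == pytest.approx(
                min(state.y_actual, state.y_demand), abs=1e-9
            )
            assert state.m_profit == pytest.approx(
                state.m_cust - state.m_supply - state.m_delivery - state.m_storage,
                abs=1e-9,
            )
            assert inv.total() == pytest.approx(state.y_actual_end, abs=1e-9)
            assert all(age < shelf for age, _ in inv.cohorts())


class TestRunSimulation:
    def one_food_setup(self, params_factory, *, min_stock=10.0, enforcement=0.6,
                       shelf=8, activation=3):
        f = food(shelf=shelf)
        p = params_factory()
        ordn = OrdinanceSpec({f.food_id: ordinance(min_stock, enforcement,
                                                   activation=activation)})
        return f, p, ordn

    def test_records_sixty_weeks_by_default(self, params_factory):
        f, p, ordn = self.one_food_setup(params_factory)
        res = run_simulation([f], {f.food_id: p}, ordn)
        assert sorted(res.panel["week"].unique()) == list(range(3, 63))
        assert len(res.store_totals) == 60

    def test_constant_inputs_reach_fixed_point_within_two_steps(self, params_factory):
        f, p, ordn = self.one_food_setup(params_factory)
        res = run_simulation([f], {f.food_id: p}, ordn)
        panel = res.panel.set_index("week").drop(columns=["food_id"])
        ref = panel.loc[5]  # activation week 3 + 2
        drift = (panel.loc[5:] - ref).abs().to_numpy().max()
        assert drift <= 1e-9

    def test_unprofitable_voluntary_food_is_never_stocked(self, params_factory):
        # wholesale cost above the choke price: no price can earn a margin
        f = food(shelf=4)
        p = params_factory(p1=2.0, p4=0, p5=0, p6=0, p7=1.0, d_max=2.0,
                           c_max=2.0, c_store=5.0)
        ordn = OrdinanceSpec({f.food_id: ordinance(0.0, 0.0, activation=3)})
        res = run_simulation([f], {f.food_id: p}, ordn)
        assert (res.store_totals["m_profit"] == 0).all()
        assert (res.store_totals["y_actual_all"] == 0).all()

    def test_overstocking_never_raises_equilibrium_profit(self, params_factory):
        f = food(shelf=2)
        p = params_factory()
        demand_driven = OrdinanceSpec({f.food_id: ordinance(0.0, 0.0, activation=3)})
        forced = OrdinanceSpec({f.food_id: ordinance(12.0, 1.0, activation=3)})
        res_low = run_simulation([f], {f.food_id: p}, demand_driven)
        res_high = run_simulation([f], {f.food_id: p}, forced)
        assert (
            res_high.final_week()["m_profit"].iloc[0]
            <= res_low.final_week()["m_profit"].iloc[0]
        )

    def test_no_waste_when_supply_tracks_demand(self, params_factory):
        f = food(shelf=100)
        p = params_factory()
        ordn = OrdinanceSpec({f.food_id: ordinance(1.0, 0.2, activation=3)})
        res = run_simulation([f], {f.food_id: p}, ordn)
        assert res.panel["y_waste"].sum() == 0.0

    def test_store_totals_match_panel_sums(self, default_cal):
        catalog, params = default_cal
        from sfosim.scenarios import load_preset

        ordn, _ = load_preset("snap_minimum", catalog)
        res = run_simulation(catalog, params, ordn)
        summed = res.panel.groupby("week")[["y_actual", "m_profit"]].sum()
        assert np.allclose(summed["y_actual"], res.store_totals["y_actual_all"])
        assert np.allclose(summed["m_profit"], res.store_totals["m_profit"])

    def test_accounting_identity_over_whole_run(self, params_factory):
        f, p, ordn = self.one_food_setup(params_factory, shelf=2)
        res = run_simulation([f], {f.food_id: p}, ordn)
        total = res.panel
        assert total["m_profit"].sum() == pytest.approx(
            total["m_cust"].sum() - total["m_supply"].sum()
            - total["m_delivery"].sum() - total["m_storage"].sum(), abs=1e-9
        )

    def test_missing_parameters_raise_configuration_error(self, params_factory):
        f = food()
        other = params_factory("other")
        with pytest.raises(ConfigurationError, match=f.food_id):
            run_simulation([f], {"other": other}, OrdinanceSpec())

    def test_tidy_csv_roundtrip(self, params_factory, tmp_path):
        from sfosim.report import load_tidy_results

        f, p, ordn = self.one_food_setup(params_factory)
        res = run_simulation([f], {f.food_id: p}, ordn,
                             config=SimulationConfig(horizon=10))
        path = tmp_path / "results.csv"
        res.write_csv(path)
        panel = load_tidy_results(path)
        merged = panel.set_index(["week", "food_id"])
        orig = res.panel.set_index(["week", "food_id"])[merged.columns]
        pd.testing.assert_frame_equal(merged, orig, check_like=True)
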