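"""Weekly dynamics of one food under an enforced minimum stock.

Runs the simulation for a single food and prints the first weeks of the
stock-and-flow panel: the state converges to its equilibrium within two
steps of the ordinance activating.
"""

from sfosim import FoodOrdinance, OrdinanceSpec, default_calibration, run_simulation

catalog, params = default_calibration()
food = next(f for f in catalog if f.food_id == "eggs")
ordinance = OrdinanceSpec({
    food.food_id: FoodOrdinance(
        min_stock=10, enforcement=0.6, training=5, signage=5, activation_time=5
    )
})

result = run_simulation([food], {food.food_id: params[food.food_id]}, ordinance)
cols = ["week", "y_supply", "y_actual", "y_demand", "y_cust", "y_waste", "c_cust", "m_profit"]
print(result.panel[cols].head(8).to_string(index=False,
      float_format=lambda v: f"{v:7.2f}"))
print("\nBefore week 5 the store stocks eggs voluntarily at last week's")
print("demand; from activation the effective minimum (0.6 x 10 = 6 units)")
print("binds, and all variables settle at their equilibrium by week 7.")
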