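"""The weekly price decision for a single food.

Sweeps the price grid for one calibrated food and shows the
profit-maximizing price, the demand it induces, and how a required
minimum stock changes the picture for a perishable food.
"""

from sfosim import default_calibration
from sfosim.economics import DemandLevers, PriceGrid, UnitCosts, base_demand, optimize_price

catalog, params = default_calibration()
food = next(f for f in catalog if f.food_id == "tomato")
p = params[food.food_id]

levers = DemandLevers(training=5, signage=5)  # promotions and quality at maximum
base = base_demand(p, levers)
costs = UnitCosts(
    c_store=p.c_store,
    c_delivery=p.p10 + p.p11 * food.ease_of_delivery,
    c_storage=p.p12 + p.p13 * 3.0,
)
grid = PriceGrid.linspace(p.c_max)

print(f"{food.name}: base demand {base:.1f} units/wk at price 0, "
      f"unit cost ${costs.total:.2f}, shelf life {food.shelf_life_weeks} wk")
for required in (0.0, 10.0):
    d = optimize_price(p, base, costs, required, grid, food.shelf_life_weeks)
    print(f"  required stock {required:>4.1f}: best price ${d.price:.2f} -> "
          f"demand {d.expected_demand:.2f} units/wk, "
          f"expected profit ${d.expected_profit:.2f}/wk")
print("\nForcing stock above demand on a 1-week-shelf-life food turns the")
print("unsold depth into weekly spoilage the store must keep repurchasing.")
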