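# sfosim — simulating staple food ordinances in corner stores

In many low-income urban neighborhoods, corner stores are the main food
source but rarely carry a full range of affordable healthy staples.  A
*staple food ordinance* (SFO) is a policy that requires retail food
stores to stock a minimum variety and depth of healthy foods.  Whether
such an ordinance helps depends on a tight economic loop: required stock
that outruns customer demand spoils on the shelf and costs the store
money, which undermines compliance; requirements that track demand can
expand the healthy-food market while keeping stores profitable.

`sfosim` is a weekly system-dynamics simulator of that loop for a single
corner store, built for policy analysts and modelers who want to compare
ordinance designs before they are enacted.  It is a Python library with
a thin command-line interface on top.

## The model

For each staple food, each simulated week:

- **Food flow.** The store needs `max(required stock, last week's
  demand)` units.  It purchases `y_supply = max(0, needed − leftover)`
  from the wholesaler, holds `y_actual = y_supply + leftover` on the
  shelf, sells `y_cust = min(y_actual, y_demand)` (oldest stock first),
  and wastes `y_waste`, the stock that reaches the food's shelf life.
- **Demand and price.** Customers follow a linear demand curve
  `y_demand = b − p7·c_cust`, where the base demand `b` is a calibrated
  linear score of promotion and quality levers (owner training, consumer
  signage, convenience, taste, healthiness, each rated 1–5) and `p7` is
  the demand–price slope.  The store picks `c_cust` each week by profit
  maximization over a price grid on `[0, c_max]`.
- **Money flow.** Unit costs are the wholesale cost `c_store`, a
  delivery cost `p10 + p11·ease_of_delivery` (≈5% of price), and a
  storage cost `p12 + p13·infrastructure + κ·total_stock` (≈10% of
  price).  Weekly profit is revenue minus wholesale, delivery and
  storage spending:
  `m_profit = c_cust·y_cust − c_store·y_supply − c_delivery·y_supply − c_storage·y_actual`.
- **Policy levers.** An ordinance sets, per food, a minimum stock
  `s_min`, an enforcement (compliance) fraction `e`, promotion
  intensities, and an activation week; the effective requirement is
  `e·s_min` once active.  Foods phase in on a schedule (one new food
  every 2 weeks from week 3) and the simulation runs 60 weeks, long
  enough for every food to reach its equilibrium.

Parameters are calibrated from two small Likert surveys (store owners
and consumers) via ordinary least squares, a demand projection that
combines owner and consumer ratings, and a demand–price line anchored at
the maximum demand (all predictors at 5) and a maximum price of 200% of
the mean price.  The package ships a synthetic survey generator with
known ground truth in place of the original field data.

## Worked example

```sh
python examples/04_compare_ordinances.py
```

runs the four shipped ordinance presets on the default synthetic
calibration and prints:

```
              final_week_profit  final_week_stock  final_week_waste  foods_positive_profit  foods_negative_profit
scenario
snap_minimum              73.52             73.09              0.00                     22                      0
snap_depth               -18.85            220.00             23.37                      5                     17
minneapolis               73.52             73.09              0.00                     22                      0
wic                       32.56            165.09              0.54                     16                      6
```

Final-week values are the equilibrium weekly outcomes.  The low-stock
designs (SNAP Minimum, Minneapolis-style) let stocking follow demand:
no waste, highest weekly profit (\$73.52/week), but also the smallest
healthy-food stock.  The deep-stock fully-enforced design (SNAP Depth)
forces 220 units onto the shelves against far less demand, spoils 23
units of perishables every week and loses \$18.85/week overall.  The
mixed WIC-style design roughly doubles the stock held while staying
profitable (\$32.56/week), with six individually loss-making foods
cross-subsidized by the rest.

The other examples show each capability in isolation: survey generation
and calibration (`01`), the weekly price decision (`02`), and the
single-food dynamics converging two steps after activation (`03`).  The
same workflows are available from the shell:

```sh
sfosim synth --seed 2021 --out-dir run/
sfosim calibrate --owners run/owner_surveys.csv --consumers run/consumer_surveys.csv --out run/params.json
sfosim compare --params run/params.json --out run/comparison.csv
sfosim scenario wic --params run/params.json --out-dir run/
sfosim report --results run/wic_results.csv --out-dir run/report --plots
```

## Layout

- `src/sfosim/domain.py` — core types, the 22-food catalog, scale mappings
- `src/sfosim/survey_synth.py` — synthetic surveys with known ground truth
- `src/sfosim/calibration.py` — surveys → per-food parameters
- `src/sfosim/economics.py` — demand–price curve and price optimization
- `src/sfosim/engine.py` — weekly simulation with FIFO perishable inventory
- `src/sfosim/scenarios.py` — ordinance presets and comparison harness
- `src/sfosim/cli.py`, `config.py`, `report.py` — CLI, run config, reports
- `docs/methods.md` — full model and methods description
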