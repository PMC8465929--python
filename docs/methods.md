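# Model and methods

`sfosim` simulates one urban corner store stocking a catalog of healthy
staple foods under a staple food ordinance (SFO).  The model is a
discrete-time stock-and-flow system: one week per step, with a food flow
(wholesaler → shelf → customers or waste) and a money flow (revenue in,
wholesale/delivery/storage costs out) per food, coupled across foods
only through the store-wide stock level.  This note documents the model,
its calibration, the synthetic data it ships with, and the numerical and
design choices behind both.

## 1. The weekly update

All quantities are real-valued weekly rates; `y` denotes food flows
(units/week), `c` unit costs and prices ($/unit), `m` money flows
($/week).  For each food, week `t`:

1. **Requirement.** The effective required stock is
   `req = e · s_min` once the ordinance has activated for this food
   (week ≥ `t_ordinance`), else 0.  `e ∈ [0,1]` is the enforcement
   (compliance) fraction; modeling partial enforcement as a continuous
   fraction of the minimum is a deliberate simplification that
   reproduces the qualitative behavior of lightly-enforced ordinances
   (stocking stays demand-driven).
2. **Unit costs.**
   `c_delivery = p10 + p11 · ease_of_delivery`,
   `c_storage = p12 + p13 · infrastructure + κ · A(t−1)`, where
   `A(t−1)` is last week's store-wide stock; both are clipped at 0.
   `c_total = c_store + c_delivery + c_storage`.
3. **Demand and price.** Base demand
   `b = p1 + p2·training + p3·signage + p4·convenience + p5·taste + p6·healthiness`,
   multiplied by the variety factor `v = 1 + γ·min(A(t−1)/S_ref, 1)`
   and clipped to `[0, d_max]`.  Demand at price `c` is
   `d(c) = max(0, b − p7·c)`.  The store chooses the price `c_cust`
   maximizing steady-state expected weekly profit over a grid on
   `[0, c_max]` (§3); `y_demand = d(c_cust)`.
4. **Purchasing.**  `needed = max(req, y_demand(t−1))`;
   `y_supply = max(0, needed − leftover)`; `y_actual = y_supply +
   leftover`.  When nothing is required and no price is profitable the
   store declines to stock the food entirely (`needed = 0`): voluntary
   stocking happens only while it pays.
5. **Sales, aging, spoilage.**  `y_cust = min(y_actual, y_demand)`,
   drawn from the oldest inventory cohorts first (FIFO — older food is
   always sold before newer food).  Cohorts then age one week, and any
   cohort reaching the food's shelf life spoils:
   `y_waste` is its total.  `y_actual_end = y_actual − y_cust − y_waste`
   carries to next week.
6. **Money.**  `m_supply = c_store·y_supply`, `m_delivery =
   c_delivery·y_supply`, `m_storage = c_storage·y_actual`, `m_cust =
   c_cust·y_cust`, and
   `m_profit = m_cust − m_supply − m_delivery − m_storage`.

Two exact invariants hold at every step and are enforced by tests:
mass balance `y_supply + leftover = y_cust + y_waste + y_actual_end`,
and the profit accounting identity above.

The simulation starts at week 3 from an all-zero state (empty store, no
requirements) and runs 60 weeks.  Ordinance requirements phase in one
food every 2 weeks from week 3, so all 22 foods are active by week 45
and at equilibrium well before week 60.  Last week's demand and last
week's store-wide stock feed forward into this week's purchasing and
pricing; using the previous week's total stock keeps the per-food
updates order-independent within a week.

With time-invariant inputs a single food reaches an exact fixed point
within two steps of its activation: the activation week itself uses the
pre-activation demand and stock totals, the next week sees the new
constant environment, and from the second week on every variable
repeats exactly.  This two-step spin-up is also why the simulation
clock starts at step 3.

## 2. Calibration from surveys

Calibration turns two Likert-survey tables — store owners and consumers
rating every food on 1–5 scales — into the per-food coefficients
`p1..p7, p10..p13`.  Every fit is run separately per food.  Three fixed
assumptions anchor the cost and price scales: unit delivery cost is 5%
of the retail price, unit storage cost is 10% of the retail price, and
the zero-demand (maximum) price is 200% of the mean price.

- **Cost regressions.**  `p10, p11` are the OLS intercept/slope of
  `0.05 × price` on the ease-of-delivery rating across stores; `p12,
  p13` the same for `0.10 × price` on infrastructure capacity.  The
  store-wide stock term `κ·A` enters storage cost at simulation time,
  not in the regression — the survey has no stock-level covariate.
- **Demand projection.**  Owners' preferred stock is nearly constant at
  the top of the scale, so each owner's desired stock is the *minimum*
  of preferred stock and perceived customer demand, converted to units
  by the survey conversion table (1→0, 2→2, 3→5, 4→8, 5→10 units; bin
  midpoints, open top bin at its lower bound).  Consumer demand ratings
  are converted the same way and rescaled by the ratio of the owner
  demand mean to the consumer demand mean, giving a projected demand
  vector over consumers.  A food with no usable owner demand falls back
  to the across-food average of the other foods' owner means.
- **Demand regression.**  Projected demand is regressed on the five
  predictors (training, signage, convenience, taste, healthiness) plus
  an intercept.  The surveys carry no variation in promotion exposure,
  so those two columns sit at their baseline level 1: a zero-variance
  predictor receives coefficient 0 and its constant effect is absorbed
  by the intercept (a genuinely rank-deficient varying design falls
  back to the minimum-norm solution with a warning).  At least six
  complete rows are required; missing data are removed listwise per
  fit.  Degenerate cost fits (one row, or no variance in predictor or
  response) return a flat line at the mean response, so every food
  remains simulable.
- **Demand–price line.**  `d_max` evaluates the regression with every
  predictor at the scale maximum: all six coefficients (including the
  intercept) are multiplied by five and summed, then clipped at 0.
  `c_max = 2 × mean price` — the mean surveyed price, or the catalog
  price when no prices were surveyed, taking the higher of the two when
  both exist (corner-store prices run above database references).
  `p7 = d_max / c_max`.  Multiplying the intercept by five alongside
  the slopes is kept exactly as specified by the source procedure even
  though it is unusual; its effect is absorbed into `p7`.

Parameter indices 8 and 9 are not part of this set; the numbering
follows the source equation set, which skips them.

## 3. The price decision

Each week the store prices each food by maximizing steady-state expected
weekly profit over a grid of 201 evenly spaced prices on `[0, c_max]`
(resolution configurable).  At a candidate price `c` with demand `d(c)`,
required stock `req` and shelf life `L`:

    q = max(req, d)                  stock held
    w = max(0, q − L·d)              steady-state weekly spoilage
    s = d + w                        steady-state weekly repurchase
    profit = c·d − (c_store + c_delivery)·s − c_storage·q

`w` is the store's planning model of spoilage: with stock `q` turning
over at `d` units/week under FIFO, units deeper than `L·d` in the queue
expire before they can be sold.  For 1-week shelf lives this matches the
simulated spoilage exactly; for deeper overstock at longer shelf lives
the simulated FIFO cohorts can cycle around this average with a period
up to `L` rather than sit exactly on it, so the planning profit is an
approximation there — conservative in the sense that overstocked
regimes remain unattractive.  Ties in the grid argmax break toward the
lower price (consumer-favourable and deterministic).  With no
requirement the store can always retreat to the zero-demand price, so
the reported best voluntary profit is never negative; if it is not
strictly positive the store declines to stock.

The closed-form check: with no costs and no requirement the profit
`c·(b − p7·c)` peaks at `c* = b/(2·p7)`; the grid optimum lands within
one grid spacing of it.

## 4. Synthetic surveys and ground truth

The original survey tables are not packaged, so `survey_synth` generates
tables with the same schema and the statistical structure the
calibration assumes, recording the generating coefficients
(`SynthTruth`) for recovery testing.  Defaults mirror the field study's
scale: 25 owners, 23 consumers, 22 foods, with 10% of owner prices and
perceived-demand cells missing completely at random (the fields that
were incomplete in the field).

- Each store has a latent logistics quality on the 1–5 scale driving
  both its ease-of-delivery and infrastructure ratings; surveyed prices
  are linear in it (hard-to-reach stores charge ~4% more per logistics
  point) plus noise.  This single-latent design makes both cost
  regressions well-posed with known true coefficients.
- Each food has latent convenience/taste/healthiness levels (drawn
  U[2.5, 3.6]); a respondent's rating adds personal dispersion
  (sd 1.1) and rounds onto the 1–5 scale.  Weekly demand in units is
  exactly linear in the realized ratings — intercept U[0.3, 0.8] and
  attribute slopes U[0.6, 0.9] units per point — plus noise (sd 0.6),
  then binned onto the purchase-likelihood scale.  True promotion
  coefficients are zero (no exposure variation in a survey setting).

The coefficient ranges were chosen once to describe a population for
which healthy staples are economically viable at moderate demand: mean
weekly demand per food in the mid range of the 0–10 unit survey scale,
every food carrying a positive margin at its optimal price, with clear
heterogeneity across foods.  This is the regime in which comparing
ordinance designs is meaningful (a store for which no healthy food is
viable fails under every design), and the regression suite asserts the
qualitative scenario ordering on exactly this shipped population.

Recovery guarantees, enforced by tests: with discretization off and
response noise zero, OLS recovers all generating coefficients to 1e-8;
with Likert discretization at the study sample sizes, across 20 survey
draws, attribute slopes are recovered within ±1.2 units/point, mean
demand at the population attribute point within ±2.0 units, and
delivery-cost coefficients within ±0.05 $/unit.  The dominant error
source is the 5× extrapolation in the `d_max` derivation, which
amplifies small-sample slope noise — a real feature of the calibration
procedure at n≈23, not of the generator.

What the generator does *not* emulate: ordinal response styles
(acquiescence, central tendency), correlated missingness (dropout is
MCAR here), cross-food correlation within a respondent, seasonal price
variation, and any promotion-exposure variation.  Passing recovery
tests therefore validate the calibration pipeline's correctness, not
its field accuracy under those complications.

## 5. Ordinance presets

Qualitative policy levels map onto the survey unit scale:
low/moderate/high stock → 2/5/10 units; low/moderate/high enforcement →
0.2/0.6/1.0.  The four shipped presets are snap_minimum (low, moderate),
snap_depth (high, high), minneapolis (moderate, low) and wic (moderate
to high, high).  All are run with every demand-side slider at the scale
maximum.

The WIC-style design varies depth of stock per food.  The targeted
foods that carry the high requirement default to the *longest*
shelf-life half of the catalog: a design that places its deepest
requirements on foods that can hold them without spoiling, which is
what lets a mixed ordinance expand stock while remaining profitable and
nearly waste-free.  (Targeting the most perishable foods instead simply
reproduces the deep-stock failure mode.)  The subset is configurable
per preset file or call.

Promotion levers (training, signage) take effect from each food's
activation week; before activation the store faces baseline exposure 1.

## 6. Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| horizon | 60 weeks | simulation length |
| start_step | 3 | first simulated week (two-step spin-up convention) |
| spacing | 2 weeks | ordinance phase-in interval per food |
| grid resolution | 201 | price grid points on [0, c_max] |
| κ (kappa) | 0.001 $/unit² | storage congestion per unit of store-wide stock |
| γ (gamma) | 0 | variety demand factor (off: no magnitude data) |
| S_ref | 100 units | variety saturation stock |
| missingness | 0.10 | owner price/perceived-demand MCAR rate |
| n_stores / n_consumers | 25 / 23 | survey sample sizes |
| default seed | 2021 | shipped synthetic population |

Other conventions: quantities are never rounded (weekly flows are
rates); `d_max` is clipped at 0 so a pathological fit cannot produce
negative maximum demand; unit costs are clipped at 0; inventory cohort
ages are always strictly below the shelf life after a completed step;
equality ties and degenerate fits resolve deterministically, so every
run is bit-reproducible from its configuration and seed.

## 7. Known limitations

- One store, no competition, no consumer heterogeneity or stochastic
  demand shocks; cross-price effects between foods are absent (foods
  couple only through the storage congestion and variety terms).
- Enforcement as a multiplicative compliance fraction is the simplest
  reading of partial enforcement; it cannot express, e.g., audit
  frequency or fines.
- The steady-state spoilage model inside the price optimizer is exact
  for 1-week shelf lives and an average for deep overstock at longer
  shelf lives (§3).
- The calibration inherits the small-sample instability of its source
  procedure: with ~23 respondents the extrapolated `d_max` is noisy,
  and individual foods can calibrate to implausibly low or high demand
  on unlucky draws.
- Scenario conclusions are statements about the shipped synthetic
  population, not about any particular city's data.
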