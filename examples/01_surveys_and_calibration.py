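"""Generate synthetic surveys and calibrate per-food model parameters.

Builds the two survey tables the model is calibrated from (25 store
owners and 23 consumers rating 22 staple foods on 1-5 scales), runs the
full calibration, and prints the coefficient set for one food.
"""

from sfosim import calibrate_all, default_catalog
from sfosim.survey_synth import generate_consumer_surveys, generate_owner_surveys

catalog = default_catalog()
owners, truth = generate_owner_surveys(25, catalog, seed=2021, missingness_rate=0.1)
consumers, _ = generate_consumer_surveys(23, catalog, seed=2021, truth=truth)
print(f"owner survey rows:    {len(owners)} (25 stores x 22 foods)")
print(f"consumer survey rows: {len(consumers)} (23 respondents x 22 foods)")
print(f"missing prices:       {int(owners['price'].isna().sum())} cells\n")

params = calibrate_all(owners, consumers, catalog)
p = params["tomato"]
print("calibrated parameters for tomatoes:")
print(f"  demand intercept p1 = {p.p1:.2f} units; attribute slopes "
      f"p4..p6 = {p.p4:.2f}, {p.p5:.2f}, {p.p6:.2f} units per Likert point")
print(f"  demand-price slope p7 = {p.p7:.2f} units/$ "
      f"(max demand {p.d_max:.1f} units at price 0, zero demand at ${p.c_max:.2f})")
print(f"  delivery cost = {p.p10:.3f} + {p.p11:.3f} x ease-of-delivery $/unit")
print(f"  storage  cost = {p.p12:.3f} + {p.p13:.3f} x infrastructure $/unit")
print("\nThe demand line says how many units/week customers would buy at a")
print("given price; the cost lines feed the store's weekly unit economics.")
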