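"""From feeding-watch photos to a diet composition table.

Simulates bill-load observations, filters blurry / low-certainty
records, converts pixel measurements to prey lengths via the bill
ratio, lengths to masses via allometry, and prints the composition
table (FO = frequency of occurrence, NA = numerical abundance).
"""

from colonyforage.diet import (
    AllometricModel,
    build_diet_records,
    diet_table,
    filter_observations,
)
from colonyforage.synthetic import DEFAULT_BILL_LENGTHS_MM, simulate_diet

obs = simulate_diet(400, seed=3)
kept = filter_observations(obs)
print(f"observations: {len(obs)} taken, {len(kept)} kept after certainty/blur filter")

models = {k: AllometricModel(k, 2.7e-5, 2.76)
          for k in ["capelin", "sandlance", "herring", "gadid", "other"]}
records = build_diet_records(kept, DEFAULT_BILL_LENGTHS_MM, models)
table = diet_table(records, with_totals=False)

cols = ["bird_species", "prey_species", "fo", "fo_pct", "na", "na_pct", "mass_g", "mass_pct"]
print(table[cols].round(2).to_string(index=False))
print()
print("capelin of 100 mm weighs %.2f g under the default allometry" % models["capelin"].mass_g(100.0))
# Percent columns sum to 100 within each bird species; murres always
# carry exactly one prey item (single-prey loaders).
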