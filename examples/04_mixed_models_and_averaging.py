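"""Mixed categorical regression and AICc multimodel averaging.

Fits every nested model of ground plan (rounded vs angular) on a synthetic
world — composites, polygyny, borrowing, language-family random effect —
combines them by Akaike weights and prints the relative importance of each
predictor next to the averaged model's predictive accuracy and its chance
and modal baselines.
"""

import numpy as np

from domus.io_dplace import recode_table
from domus.multimodel import (ModelSpec, average_model, complete_cases,
                              enumerate_models, fit_candidates)
from domus.spatial import borrowing_fraction, nearest_neighbors
from domus.world import WorldConfig, generate_world

import pandas as pd

world = generate_world(WorldConfig(n_societies=300, n_families=20,
                                   n_years=10, missing_rate=0.0), seed=5)
df = pd.concat([recode_table(world.records).reset_index(drop=True),
                world.scores.reset_index(drop=True)], axis=1)
nbrs = nearest_neighbors(df, k=10)
df["borrowing"] = borrowing_fraction(df["ground_plan"].tolist(), nbrs)

full = ModelSpec("ground_plan",
                 ("temperature_harshness", "xeric_harshness", "polygyny",
                  "borrowing"),
                 random_effect=True, ref_category="rounded")
cc = complete_cases(df, full)
specs = enumerate_models(full)
print(f"{len(specs)} nested models on n = {len(cc)} societies")

fits = fit_candidates(specs, cc, categories=["rounded", "angular"],
                      var_tol=2e-2)
avg = average_model(fits, cc, full)

print(f"\nconverged models: {len(avg.weights)}; "
      f"top model weight {avg.weights.max():.3f}")
print("\nrelative importance (summed Akaike weight of containing models):")
for term, imp in sorted(avg.importance.items(), key=lambda kv: -kv[1]):
    print(f"  {term:<22}{imp:6.3f}")
print(f"\naccuracy of averaged model {avg.accuracy:.3f} vs modal baseline "
      f"{avg.modal:.3f} and chance {avg.chance:.3f}")
print("an importance near 1 marks a predictor the data cannot do without;"
      "\naccuracy above the modal share shows real predictive signal.")
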