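"""The full analysis pipeline on a synthetic world.

Generates a 120-society world, runs recoding, climate composites, neighbour
borrowing, per-feature mixed models, Moran residual diagnostics, nested
enumeration and AICc averaging, and writes a CSV/JSON report bundle; the
printed table mirrors the accuracy/importance summary of the analysis.
"""

import pandas as pd

from domus.pipeline import RunConfig, run_pipeline
from domus.world import WorldConfig

cfg = RunConfig(
    synthetic=WorldConfig(n_societies=120, n_families=12, n_years=10,
                          missing_rate=0.03),
    seed=20240301,
    output_dir="example_bundle",
    predictors=("temperature_harshness", "xeric_harshness", "polygyny",
                "borrowing"),
    var_tol=2e-2,
)
bundle = run_pipeline(cfg)
print(f"report bundle written to {bundle.output_dir}/\n")

summary = pd.read_csv(bundle.output_dir / "summary.csv")
cols = ["response", "n", "chance", "modal", "average_model_accuracy"]
print(summary[cols].round(3).to_string(index=False))
print("\nEvery response should beat both baselines: chance = 1/J and the"
      "\nmodal share (always guessing the most common category).  The"
      "\nper-response CSVs hold full-model coefficients, averaged models,"
      "\nMoran correlograms of the residuals and effect-profile curves.")
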