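"""Colwell's predictability of a monthly climate series.

Builds three 10-year monthly temperature series — perfectly periodic, noisy
seasonal, and pure noise — and decomposes each into predictability (P),
constancy (C) and contingency (M).  P = C + M: constancy measures how
uniform the state is overall, contingency how tightly the state follows the
calendar.  A strict seasonal cycle gives P = 1; white noise drives P
towards 0.
"""

import numpy as np

from domus.climate import colwell, discretize_series

rng = np.random.default_rng(0)
season = 12.0 * np.sin(2 * np.pi * np.arange(12) / 12)

series = {
    "strict seasonal cycle": np.tile(season, (10, 1)),
    "seasonal + noise": np.tile(season, (10, 1)) + rng.normal(0, 6, (10, 12)),
    "pure noise": rng.normal(15, 8, (10, 12)),
}

print(f"{'series':<24}{'P':>8}{'C':>8}{'M':>8}")
for name, x in series.items():
    p, c, m = colwell(discretize_series(x, n_states=10))
    print(f"{name:<24}{p:8.3f}{c:8.3f}{m:8.3f}")

print("\nP is the month-conditional predictability of the climate state;"
      "\nM > C marks a seasonal rhythm rather than overall uniformity."
      "\nNoise scores lowest (finite samples keep estimated P above 0;"
      "\nP reaches its bounds exactly only in the limiting tables).")
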