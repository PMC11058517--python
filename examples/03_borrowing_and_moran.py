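"""Neighbour borrowing fractions and a Moran's I correlogram.

On a 200-society world with neighbour contagion switched on, computes each
society's borrowing fraction — the share of its 10 nearest neighbours with
the same ground plan — and contrasts the Moran's I correlogram of a raw
spatially structured variable with that of white noise.
"""

import numpy as np

from domus.io_dplace import recode_table
from domus.spatial import (borrowing_fraction, morans_correlogram,
                           nearest_neighbors)
from domus.world import WorldConfig, generate_world

world = generate_world(WorldConfig(n_societies=200, n_families=20,
                                   n_years=10, missing_rate=0.0), seed=4)
df = recode_table(world.records)
nbrs = nearest_neighbors(df, k=10)
frac = borrowing_fraction(df["ground_plan"].tolist(), nbrs)
print(f"borrowing fraction (ground plan): mean {np.nanmean(frac):.3f}, "
      f"range {np.nanmin(frac):.2f}-{np.nanmax(frac):.2f}")
print("values near 1 mean a society's neighbours overwhelmingly share its"
      " ground plan — the signature of horizontal transmission.\n")

scores = world.scores["temperature_harshness"].to_numpy()
cg = morans_correlogram(scores, df, n_classes=12)
noise = morans_correlogram(np.random.default_rng(0).normal(size=len(df)),
                           df, n_classes=12)
print(f"{'class mid (km)':>15}{'I (composite)':>15}{'I (noise)':>12}")
mids = 0.5 * (cg.class_edges[:-1] + cg.class_edges[1:])
for i in range(12):
    print(f"{mids[i]:15.0f}{cg.i_per_class[i]:15.3f}"
          f"{noise.i_per_class[i]:12.3f}")
print(f"\nnull expectation E[I] = {cg.expected_i:.4f}; the composite shows"
      "\npositive I at short range (spatial clustering) and again near the"
      "\nantipodes (the latitudinal gradient is symmetric in |lat|), while"
      "\nthe noise hovers around the null in every distance class.")
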