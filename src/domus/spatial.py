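"""Great-circle geometry, neighbour tables, borrowing and Moran's I.

Horizontal cultural transmission is proxied by the *borrowing fraction*:
the share of a society's 10 nearest neighbours exhibiting the same category
of a house trait as the focal society.  Residual spatial structure after
modelling is screened with a Moran's I autocorrelogram over 12 equal-width
great-circle distance classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088


@dataclass
class NeighborTable:
    """Per-society ordered nearest neighbours (ascending distance)."""

    society_ids: list
    neighbor_index: np.ndarray   # n x k integer positions into society_ids
    distances_km: np.ndarray     # n x k

    @property
    def k(self) -> int:
        return self.neighbor_index.shape[1]

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.society_ids, dtype=object)
        rows = []
        for i, sid in enumerate(ids):
            for rank in range(self.k):
                rows.append((sid, rank + 1,
                             ids[self.neighbor_index[i, rank]],
                             self.distances_km[i, rank]))
        return pd.DataFrame(rows, columns=["society_id", "rank",
                                           "neighbor_id", "distance_km"])


@dataclass
class MoranCorrelogram:
    class_edges: np.ndarray       # n_classes + 1 ascending distances (km)
    i_per_class: np.ndarray       # n_classes
    pair_count_per_class: np.ndarray
    expected_i: float
    unreliable: np.ndarray = field(default=None)  # classes with < 30 pairs
    perm_low: Optional[np.ndarray] = None
    perm_high: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.unreliable is None:
            self.unreliable = self.pair_count_per_class < 30

    def to_frame(self) -> pd.DataFrame:
        mid = 0.5 * (self.class_edges[:-1] + self.class_edges[1:])
        df = pd.DataFrame({
            "class_low_km": self.class_edges[:-1],
            "class_high_km": self.class_edges[1:],
            "class_mid_km": mid,
            "morans_i": self.i_per_class,
            "n_pairs": self.pair_count_per_class,
            "expected_i": self.expected_i,
            "unreliable": self.unreliable,
        })
        if self.perm_low is not None:
            df["perm_low"] = self.perm_low
            df["perm_high"] = self.perm_high
        return df


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = (np.sin(dlat / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_distances_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Full n x n haversine distance matrix."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def nearest_neighbors(records, k: int = 10,
                      dist: Optional[np.ndarray] = None) -> NeighborTable:
    """k nearest neighbours of every society by great-circle distance.

    ``records`` is a DataFrame with society_id/lon/lat columns.  Distance
    ties are broken by society_id lexicographic order so the neighbour
    relation is deterministic given coordinates and ids.
    """
    ids = [str(s) for s in records["society_id"]]
    n = len(ids)
    if k >= n:
        raise ValueError("k must be < n")
    if k < 1:
        raise ValueError("k must be >= 1")
    if dist is None:
        dist = pairwise_distances_km(records["lon"].to_numpy(),
                                     records["lat"].to_numpy())
    id_rank = np.argsort(np.argsort(np.asarray(ids, dtype=object)))
    nbr = np.empty((n, k), dtype=int)
    d = np.empty((n, k), dtype=float)
    for i in range(n):
        row = dist[i].copy()
        row[i] = np.inf
        order = np.lexsort((id_rank, row))[:k]
        nbr[i] = order
        d[i] = dist[i, order]
    return NeighborTable(ids, nbr, d)


def borrowing_fraction(trait: Sequence, nbrs: NeighborTable,
                       missing_as_mismatch: bool = False) -> np.ndarray:
    """Fraction of a society's neighbours sharing its trait category.

    Neighbours with a missing trait are excluded from the denominator by
    default (``missing_as_mismatch=True`` counts them as non-matches).
    Societies whose own trait is missing, or with no usable neighbour,
    get NaN.
    """
    vals = np.asarray([None if pd.isna(v) or v in ("missing", "excluded")
                       else v for v in trait], dtype=object)
    n, k = nbrs.neighbor_index.shape
    if len(vals) != n:
        raise ValueError("trait not aligned with neighbour table")
    out = np.full(n, np.nan)
    for i in range(n):
        if vals[i] is None:
            continue
        nv = vals[nbrs.neighbor_index[i]]
        usable = np.array([v is not None for v in nv])
        denom = k if missing_as_mismatch else int(usable.sum())
        if denom == 0:
            continue
        match = sum(1 for v in nv[usable] if v == vals[i])
        out[i] = match / denom
    return out


def morans_correlogram(values: Sequence[float], records=None,
                       n_classes: int = 12,
                       dist: Optional[np.ndarray] = None,
                       permutations: int = 0,
                       seed: Optional[int] = None) -> MoranCorrelogram:
    """Moran's I per equal-width great-circle distance class.

    Classes are equal-width bins of pairwise distance over (0, max];
    weights are binary within a class.  Under no spatial autocorrelation
    E[I] = -1/(n-1).  With ``permutations > 0`` a seeded permutation null
    band (2.5th/97.5th percentile) is attached per class.
    """
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 10:
        raise ValueError("need at least 10 values")
    if np.isnan(z).any():
        raise ValueError("values contain NaN")
    if np.ptp(z) == 0:
        raise ValueError("zero variance")
    if dist is None:
        dist = pairwise_distances_km(records["lon"].to_numpy(),
                                     records["lat"].to_numpy())
    iu, ju = np.triu_indices(n, k=1)
    d = dist[iu, ju]
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("all points coincide")
    edges = np.linspace(0.0, dmax, n_classes + 1)
    # classes span (0, dmax]: zero-distance pairs fall in no class
    cls = np.searchsorted(edges[1:], d, side="left")
    cls[d == 0] = -1
    cls[cls >= n_classes] = n_classes - 1

    zc = z - z.mean()
    denom = (zc ** 2).sum()
    cross = zc[iu] * zc[ju]
    i_vals = np.full(n_classes, np.nan)
    counts = np.zeros(n_classes, dtype=int)
    for c in range(n_classes):
        sel = cls == c
        npairs = int(sel.sum())
        counts[c] = 2 * npairs  # ordered pairs (symmetric weights)
        if npairs > 0:
            s0 = 2.0 * npairs
            i_vals[c] = (n / s0) * (2.0 * cross[sel].sum()) / denom

    expected = -1.0 / (n - 1)
    low = high = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        sims = np.full((permutations, n_classes), np.nan)
        sel_by_class = [np.where(cls == c)[0] for c in range(n_classes)]
        for p in range(permutations):
            zp = zc[rng.permutation(n)]
            crossp = zp[iu] * zp[ju]
            for c in range(n_classes):
                sel = sel_by_class[c]
                if len(sel):
                    sims[p, c] = (n / (2.0 * len(sel))) * (
                        2.0 * crossp[sel].sum()) / denom
        low = np.nanpercentile(sims, 2.5, axis=0)
        high = np.nanpercentile(sims, 97.5, axis=0)
    return MoranCorrelogram(edges, i_vals, counts, expected,
                            perm_low=low, perm_high=high)


def categorical_residual_correlograms(y: Sequence, prob: np.ndarray,
                                      categories: Sequence, records=None,
                                      dist: Optional[np.ndarray] = None,
                                      n_classes: int = 12,
                                      permutations: int = 0,
                                      seed: Optional[int] = None) -> dict:
    """Moran correlograms of Pearson residuals, one per response category.

    For a categorical response the residual fed to Moran's I is the Pearson
    residual of the indicator of each category, (1[y=j] - p_j)/sqrt(p_j(1-p_j));
    downstream screening uses the maximum |I| across categories.
    """
    y = np.asarray(y, dtype=object)
    prob = np.asarray(prob, dtype=float)
    out = {}
    for j, cat in enumerate(categories):
        pj = np.clip(prob[:, j], 1e-9, 1 - 1e-9)
        resid = ((y == cat).astype(float) - pj) / np.sqrt(pj * (1 - pj))
        out[cat] = morans_correlogram(resid, records=records, dist=dist,
                                      n_classes=n_classes,
                                      permutations=permutations, seed=seed)
    return out
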