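"""Climate summaries and environmental composites.

Per-society monthly temperature and precipitation series are summarised by
their mean, variance and Colwell's predictability index P, which decomposes
into constancy (C, the state is always the same) and contingency (M, the
state is a fixed function of the month): P = C + M, all on [0, 1].

The normalised (Box-Cox) environmental variables — climate summaries plus
elevation and slope — are reduced by principal components analysis with a
normalised varimax rotation to three composites: *temperature harshness*
(cold, variable, unpredictable temperature scores high), *mountain dwelling*
(high, steep terrain scores high) and *xeric harshness* (little,
unpredictable precipitation scores high).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "StateMatrix", "ClimateSummary", "EnvComposite",
    "discretize_series", "colwell", "summarize_climate",
    "box_cox_normalize", "varimax_pca", "environmental_composites",
    "DEFAULT_PCA_VARIABLES",
]

#: default variable set entering the composite PCA
DEFAULT_PCA_VARIABLES = (
    "temp_mean", "temp_var", "temp_p",
    "precip_mean", "precip_var", "precip_p",
    "elevation_m", "slope_deg",
)

COMPONENT_NAMES = ("temperature_harshness", "mountain_dwelling",
                   "xeric_harshness")


@dataclass
class StateMatrix:
    """Month x state frequency table underlying Colwell's index.

    ``counts[m, k]`` is the number of years in which month ``m`` fell in
    discrete state ``k``; every row sums to the number of years observed.
    """

    counts: np.ndarray
    n_years: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-d matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("counts must have a positive grand total")


@dataclass
class ClimateSummary:
    temp_mean: float
    temp_var: float
    temp_p: float
    temp_c: float
    temp_m: float
    precip_mean: float
    precip_var: float
    precip_p: float
    precip_c: float
    precip_m: float
    elevation_m: Optional[float] = None
    slope_deg: Optional[float] = None
    missing: bool = False


@dataclass
class EnvComposite:
    """Varimax-rotated composite scores and their loadings.

    ``loadings`` has one row per component, in the order temperature
    harshness, mountain dwelling, xeric harshness; ``scores`` is an
    n x 3 DataFrame of standardized per-society scores.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray
    boxcox_lambdas: Optional[pd.Series] = None


def discretize_series(monthly: np.ndarray, n_states: int = 10,
                      scheme: str = "equal_width") -> StateMatrix:
    """Bin a years x 12 series into a month x state frequency table.

    ``equal_width`` bins span the observed range of the whole matrix;
    ``log_equal_width`` bins log(1 + x) the same way (precipitation-style,
    requires x >= 0).  A constant series occupies a single state.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    x = np.asarray(monthly, dtype=float)
    if x.ndim != 2 or x.shape[1] != 12:
        raise ValueError("monthly must be a years x 12 matrix")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 years")
    if np.isnan(x).any():
        raise ValueError("monthly contains missing cells")
    if scheme == "log_equal_width":
        if (x < 0).any():
            raise ValueError("log_equal_width requires non-negative values")
        x = np.log1p(x)
    elif scheme != "equal_width":
        raise ValueError(f"unknown scheme {scheme!r}")
    lo, hi = float(x.min()), float(x.max())
    n_years = x.shape[0]
    if hi == lo:
        counts = np.zeros((12, n_states), dtype=int)
        counts[:, 0] = n_years
        return StateMatrix(counts, n_years)
    edges = np.linspace(lo, hi, n_states + 1)
    # interior edges only; values == hi fall in the last state
    states = np.digitize(x, edges[1:-1], right=False)
    counts = np.zeros((12, n_states), dtype=int)
    for m in range(12):
        counts[m] = np.bincount(states[:, m], minlength=n_states)
    return StateMatrix(counts, n_years)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0*log 0 = 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def colwell(sm: StateMatrix) -> tuple[float, float, float]:
    """Colwell's predictability decomposition (P, C, M) of a state matrix.

    With row (month) totals X, column (state) totals Y and grand total N:

        H(X)  = -sum X_m/N log X_m/N
        H(Y)  = -sum Y_k/N log Y_k/N
        H(XY) = -sum n_mk/N log n_mk/N
        C = 1 - H(Y)/log s,  M = (H(X) + H(Y) - H(XY))/log s,  P = C + M

    P ranges from 0 (completely unpredictable: every state equally likely
    in every month) to 1 (fully predictable: each month always in one state).
    """
    counts = np.asarray(sm.counts, dtype=float)
    s = counts.shape[1]
    if s < 2:
        raise ValueError("degenerate state space: need >= 2 states")
    N = counts.sum()
    hx = _entropy(counts.sum(axis=1) / N)
    hy = _entropy(counts.sum(axis=0) / N)
    hxy = _entropy(counts.ravel() / N)
    logs = np.log(s)
    c = 1.0 - hy / logs
    m = (hx + hy - hxy) / logs
    p = c + m

    def _clip(v: float) -> float:
        if -1e-12 < v < 0.0:
            return 0.0
        return v
    return _clip(p), _clip(c), _clip(m)


def summarize_climate(record, n_states: int = 10,
                      temp_scheme: str = "equal_width",
                      precip_scheme: str = "log_equal_width") -> ClimateSummary:
    """Summarise one society's monthly series into means, variances and P.

    Returns a summary flagged ``missing`` when either series is absent;
    such societies are later dropped from any model needing composites.
    """
    temp = getattr(record, "temp_monthly", None)
    precip = getattr(record, "precip_monthly", None)
    elev = getattr(record, "elevation_m", None)
    slope = getattr(record, "slope_deg", None)
    if temp is None or precip is None:
        return ClimateSummary(*(np.nan,) * 10, elevation_m=elev,
                              slope_deg=slope, missing=True)
    temp = np.asarray(temp, float)
    precip = np.asarray(precip, float)
    tp, tc, tm = colwell(discretize_series(temp, n_states, temp_scheme))
    pp, pc, pm = colwell(discretize_series(precip, n_states, precip_scheme))
    return ClimateSummary(
        temp_mean=float(temp.mean()), temp_var=float(temp.var(ddof=1)),
        temp_p=tp, temp_c=tc, temp_m=tm,
        precip_mean=float(precip.mean()), precip_var=float(precip.var(ddof=1)),
        precip_p=pp, precip_c=pc, precip_m=pm,
        elevation_m=elev, slope_deg=slope,
    )


class BoxCoxResult(NamedTuple):
    y: np.ndarray
    lam: float
    shift: float


def box_cox_normalize(x: np.ndarray, shift: str = "auto",
                      grid: tuple[float, float] = (-5.0, 5.0)) -> BoxCoxResult:
    """Box-Cox transform with lambda chosen by profile log-likelihood.

    The profile likelihood is evaluated on a grid over ``grid`` and the
    best point refined by bounded minimisation.  When ``shift='auto'`` and
    min(x) <= 0, the series is shifted by 1 - min(x) first (precipitation
    and slope contain zeros); the shift is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("x contains missing values")
    if np.ptp(x) == 0:
        raise ValueError("no variance: constant vector")
    offset = 0.0
    if x.min() <= 0:
        if shift != "auto":
            raise ValueError("x must be positive when shift is off")
        offset = 1.0 - float(x.min())
    xs = x + offset
    lo, hi = grid
    lams = np.linspace(lo, hi, 101)
    llf = np.array([stats.boxcox_llf(l, xs) for l in lams])
    i = int(np.argmax(llf))
    a, b = lams[max(i - 1, 0)], lams[min(i + 1, len(lams) - 1)]
    res = optimize.minimize_scalar(lambda l: -stats.boxcox_llf(l, xs),
                                   bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-6})
    lam = float(res.x)
    return BoxCoxResult(special.boxcox(xs, lam), lam, offset)


def _varimax_rotation(loadings: np.ndarray, normalize: bool = True,
                      tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Return the orthonormal varimax rotation matrix for p x k loadings."""
    L = loadings.copy()
    p, k = L.shape
    if normalize:
        comm = np.sqrt((L ** 2).sum(axis=1))
        comm[comm == 0] = 1.0
        L = L / comm[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p))
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return R


def varimax_pca(X: np.ndarray, k: int = 3,
                var_names: Optional[Sequence[str]] = None,
                standardize: bool = True) -> EnvComposite:
    """Top-k PCA with normalised varimax rotation and oriented components.

    Components are identified by their loadings: the component loading most
    heavily on temperature variables is *temperature harshness* (oriented so
    the mean-temperature loading is negative — cold sites score high), the
    one loading most on elevation/slope is *mountain dwelling* (oriented
    positive on elevation), and the remainder is *xeric harshness* (oriented
    so the precipitation-mean loading is negative).  When variable names do
    not carry these roles the components keep their post-rotation order with
    a deterministic sign convention.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < k:
        raise ValueError(f"need at least k={k} variables, got {p}")
    if np.isnan(X).any():
        raise ValueError("X contains missing cells")
    if var_names is None:
        var_names = [f"v{i}" for i in range(p)]
    var_names = list(var_names)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant column in X")
        Z = (X - mu) / sd
    else:
        Z = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    # deterministic SVD sign: largest-|.| element of each axis positive
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    load = vt[:k].T * np.sqrt(eigvals[:k])       # p x k, correlation scale
    R = _varimax_rotation(load)
    load_rot = load @ R                          # p x k rotated loadings
    raw_scores = u[:, :k] * np.sqrt(n - 1)       # standardized PC scores
    scores = raw_scores @ R
    ss = (load_rot ** 2).sum(axis=0)             # variance per rotated comp

    order, signs, names = _identify_components(load_rot, var_names)
    load_rot = load_rot[:, order] * signs
    scores = scores[:, order] * signs
    ss = ss[order]
    # re-standardize scores (rotation of standardized PCs is unit-variance,
    # but enforce exactly)
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=0)

    loadings = pd.DataFrame(load_rot.T, index=names, columns=var_names)
    score_df = pd.DataFrame(scores, columns=names)
    return EnvComposite(loadings=loadings, scores=score_df,
                        variance_explained=ss / p)


def _identify_components(load: np.ndarray, var_names: Sequence[str]):
    """Map rotated components to named composites and fix their signs."""
    k = load.shape[1]
    temp_ix = [i for i, v in enumerate(var_names) if v.startswith("temp")]
    terr_ix = [i for i, v in enumerate(var_names)
               if v.startswith(("elev", "slope"))]
    prec_ix = [i for i, v in enumerate(var_names) if v.startswith("precip")]
    tmean = next((i for i, v in enumerate(var_names) if v == "temp_mean"), None)
    pmean = next((i for i, v in enumerate(var_names) if v == "precip_mean"), None)
    elev = next((i for i, v in enumerate(var_names)
                 if v.startswith("elev")), None)
    if k != 3 or not temp_ix or not terr_ix or not prec_ix:
        # role-free fallback: keep order, sign by largest-|.| loading
        signs = np.ones(k)
        for j in range(k):
            i = int(np.argmax(np.abs(load[:, j])))
            signs[j] = 1.0 if load[i, j] >= 0 else -1.0
        return list(range(k)), signs, [f"component_{j+1}" for j in range(k)]
    strength = np.zeros((3, k))
    for j in range(k):
        strength[0, j] = np.abs(load[temp_ix, j]).sum()
        strength[1, j] = np.abs(load[terr_ix, j]).sum()
        strength[2, j] = np.abs(load[prec_ix, j]).sum()
    order = [-1, -1, -1]
    taken: set[int] = set()
    # greedy assignment, strongest claim first
    for _ in range(3):
        rel = strength.copy()
        for r, c in enumerate(order):
            if c >= 0:
                rel[r, :] = -np.inf
        for c in taken:
            rel[:, c] = -np.inf
        r, c = np.unravel_index(int(np.argmax(rel)), rel.shape)
        order[r] = int(c)
        taken.add(int(c))
    signs = np.ones(3)
    if tmean is not None and load[tmean, order[0]] > 0:
        signs[0] = -1.0
    if elev is not None and load[elev, order[1]] < 0:
        signs[1] = -1.0
    if pmean is not None and load[pmean, order[2]] > 0:
        signs[2] = -1.0
    return order, signs, list(COMPONENT_NAMES)


def environmental_composites(summaries: pd.DataFrame,
                             variables: Sequence[str] = DEFAULT_PCA_VARIABLES,
                             k: int = 3) -> EnvComposite:
    """Box-Cox normalise climate/terrain summaries and extract composites.

    ``summaries`` has one row per society and must contain ``variables``;
    rows with any missing variable must be dropped by the caller.  Constant
    variables (e.g. predictability exactly 1 everywhere in a perfectly
    periodic climate) carry no information and are dropped with a warning.
    """
    import warnings as _warnings

    kept = []
    lambdas = {}
    cols = []
    for v in variables:
        col = summaries[v].to_numpy(float)
        if np.ptp(col) == 0:
            _warnings.warn(f"dropping constant variable {v!r} from PCA")
            continue
        y, lam, _ = box_cox_normalize(col)
        cols.append(y)
        lambdas[v] = lam
        kept.append(v)
    if len(kept) < k:
        raise ValueError(f"fewer than k={k} non-constant variables")
    X = np.column_stack(cols)
    comp = varimax_pca(X, k=k, var_names=kept)
    comp.boxcox_lambdas = pd.Series(lambdas)
    comp.scores.index = summaries.index
    return comp
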