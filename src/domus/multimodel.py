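"""AICc multimodel inference over nested categorical regressions.

For each house feature the full model contains the three environmental
composites, the social traits, an optional temperature-harshness x
political-complexity interaction, the neighbour borrowing fraction and the
language-family random effect.  All nested models (every admissible subset
of toggleable terms, intercept always present, interactions only with both
mains) are fitted on a common complete-case dataset, non-converged fits are
excluded, and the remainder combined by Akaike weights w_i =
exp(-Delta_i/2) / sum exp(-Delta_j/2).

Model-averaged coefficients use zero-method (shrinkage) averaging: a
coefficient absent from a model contributes zero with that model's weight.
Unconditional standard errors combine within-model variance with
between-model spread.  The relative importance of a predictor is the summed
weight of the models containing it, on [0, 1].
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from domus.models import (FittedModel, classification_metrics,
                          fit_mixed_multinomial, fit_multinomial,
                          predict_prob)

logger = logging.getLogger(__name__)

RANDOM_EFFECT_TERM = "language_family"

#: categorical predictors and their dummy encodings (reference level first)
CATEGORICAL_TERMS = {
    "polygyny": ("none", "occasional", "frequent"),
    "settlement": ("sedentary", "nomadic"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, fixed terms, random effect."""

    response: str
    predictors: tuple = ()
    random_effect: bool = False
    ref_category: Optional[str] = None

    def __post_init__(self):
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("duplicate predictors")
        for t in self.predictors:
            if ":" in t:
                a, b = t.split(":")
                if a not in self.predictors or b not in self.predictors:
                    raise ValueError(
                        f"interaction {t} requires both main effects")


@dataclass
class AveragedModel:
    """AICc-weighted average over the converged candidate set."""

    response: str
    weights: np.ndarray
    specs: list
    avg_coef: pd.DataFrame          # (J-1) categories x full design columns
    uncond_se: pd.DataFrame
    importance: dict
    avg_prob: np.ndarray
    accuracy: float
    chance: float
    modal: float
    categories: tuple
    design_columns: tuple
    best_aicc: float = np.nan
    fits: list = field(default=None, repr=False)


def _dummy_columns(term: str) -> list[str]:
    levels = CATEGORICAL_TERMS.get(term)
    if levels is None:
        return [term]
    return [f"{term}[{lv}]" for lv in levels[1:]]


def design_columns(terms: Sequence[str]) -> list[str]:
    cols: list[str] = []
    for t in terms:
        cols.extend(_dummy_columns(t))
    return cols


def build_design(data: pd.DataFrame, terms: Sequence[str]):
    """Design matrix (no intercept) for the given terms.

    Numeric terms pass through; categorical terms expand to dummies against
    their declared reference; ``a:b`` multiplies two numeric columns.
    """
    cols = []
    names = []
    n = len(data)
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(data[a].to_numpy(float) * data[b].to_numpy(float))
            names.append(t)
        elif t in CATEGORICAL_TERMS:
            levels = CATEGORICAL_TERMS[t]
            vals = data[t].astype(object).to_numpy()
            for lv in levels[1:]:
                cols.append((vals == lv).astype(float))
                names.append(f"{t}[{lv}]")
        else:
            cols.append(data[t].to_numpy(float))
            names.append(t)
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, names


def enumerate_models(full: ModelSpec) -> list[ModelSpec]:
    """All nested models of a full specification, deterministic order.

    Every subset of the full model's terms is generated (intercept always
    included), subject to the hierarchy rule that an interaction appears
    only with both of its main effects; the random effect is a toggle too,
    so its relative importance is defined.
    """
    mains = [t for t in full.predictors if ":" not in t]
    inters = [t for t in full.predictors if ":" in t]
    re_options = [False, True] if full.random_effect else [False]
    specs = []
    seen = set()
    for r in range(len(mains) + 1):
        for sub in itertools.combinations(mains, r):
            valid_inters = [i for i in inters
                            if all(p in sub for p in i.split(":"))]
            for ri in range(len(valid_inters) + 1):
                for isub in itertools.combinations(valid_inters, ri):
                    terms = tuple(t for t in full.predictors
                                  if t in sub or t in isub)
                    for re in re_options:
                        key = (terms, re)
                        if key in seen:
                            continue
                        seen.add(key)
                        specs.append(replace(full, predictors=terms,
                                             random_effect=re))
    return specs


def complete_cases(data: pd.DataFrame, full: ModelSpec,
                   group_col: str = RANDOM_EFFECT_TERM) -> pd.DataFrame:
    """Rows usable by every nested model of the full specification."""
    needed = {full.response}
    for t in full.predictors:
        needed.update(t.split(":"))
    if full.random_effect:
        needed.add(group_col)
    sub = data.copy()
    for c in sorted(needed):
        col = sub[c]
        if col.dtype == object:
            sub = sub[col.notna() & ~col.isin(["missing", "excluded"])]
        else:
            sub = sub[col.notna()]
    return sub


def fit_candidates(specs: Sequence[ModelSpec], data: pd.DataFrame,
                   categories: Sequence, group_col: str = RANDOM_EFFECT_TERM,
                   var_tol: float = 1e-3) -> list[FittedModel]:
    """Fit every candidate on the common complete-case dataset.

    ``data`` must already be complete on all full-model variables so every
    fit uses the same n.  Fits that error (e.g. a predictor constant within
    the subset) or fail to converge are retained with ``converged=False``;
    if no fit converges a hard error is raised.
    """
    ref = specs[0].ref_category or categories[0]
    y = data[specs[0].response].to_numpy(object)
    fits: list[FittedModel] = []
    for spec in specs:
        X, names = build_design(data, spec.predictors)
        try:
            if spec.random_effect:
                fit = fit_mixed_multinomial(
                    X, y, data[group_col].to_numpy(object), ref=ref,
                    categories=categories, term_names=names, spec=spec,
                    var_tol=var_tol)
            else:
                fit = fit_multinomial(X, y, ref=ref, categories=categories,
                                      term_names=names, spec=spec)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.info("spec %s failed: %s", spec.predictors, exc)
            J = len(categories)
            fit = FittedModel(
                coef=np.full((J - 1, X.shape[1] + 1), np.nan),
                se=np.full((J - 1, X.shape[1] + 1), np.nan),
                re_var=np.zeros(J - 1), loglik=np.nan, k_params=0,
                n_obs=len(y), aicc=np.inf, converged=False,
                fitted_prob=np.full((len(y), J), np.nan),
                categories=tuple(categories),
                term_names=tuple(["intercept"] + names),
                has_random_effect=spec.random_effect, spec=spec)
        fits.append(fit)
    if not any(f.converged for f in fits):
        raise RuntimeError("no candidate model converged")
    return fits


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) normalised to sum 1."""
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0:
        raise ValueError("empty AICc vector")
    if not np.isfinite(a).all():
        raise ValueError("non-finite AICc")
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def average_model(fits: Sequence[FittedModel], data: pd.DataFrame,
                  full: ModelSpec,
                  weights: Optional[np.ndarray] = None) -> AveragedModel:
    """Zero-method AICc-weighted model average over converged fits.

    avg_coef = sum_i w_i beta_i (absent coefficients contribute 0);
    uncond_se = sqrt(sum_i w_i (SE_i^2 + (beta_i - avg)^2)), treating an
    absent coefficient as a zero estimate with zero variance; averaged
    probabilities are the weight-blend of each model's fitted probabilities,
    scored against the observed response.
    """
    conv = [f for f in fits if f.converged]
    if not conv:
        raise ValueError("no converged fits to average")
    if weights is None:
        weights = akaike_weights([f.aicc for f in conv])
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()

    cats = conv[0].categories
    J = len(cats)
    cols = ["intercept"] + design_columns(full.predictors)
    q_full = len(cols)
    col_ix = {c: i for i, c in enumerate(cols)}

    avg = np.zeros((J - 1, q_full))
    for w, f in zip(weights, conv):
        for t, j in zip(f.term_names, range(len(f.term_names))):
            avg[:, col_ix[t]] += w * f.coef[:, j]
    var = np.zeros((J - 1, q_full))
    for w, f in zip(weights, conv):
        present = np.zeros(q_full, dtype=bool)
        for t, j in zip(f.term_names, range(len(f.term_names))):
            i = col_ix[t]
            present[i] = True
            dev = f.coef[:, j] - avg[:, i]
            var[:, i] += w * (np.nan_to_num(f.se[:, j]) ** 2 + dev ** 2)
        # absent terms: estimate 0, variance 0, deviation (0 - avg)
        for i in np.where(~present)[0]:
            var[:, i] += w * avg[:, i] ** 2

    avg_prob = np.zeros_like(conv[0].fitted_prob)
    for w, f in zip(weights, conv):
        avg_prob += w * f.fitted_prob
    y = data[full.response].to_numpy(object)
    accuracy, chance, modal = classification_metrics(avg_prob, y, cats)

    all_terms = set(full.predictors)
    if full.random_effect:
        all_terms.add(RANDOM_EFFECT_TERM)
    importance = relative_importance([f.spec for f in conv], weights,
                                     all_terms=all_terms)
    return AveragedModel(
        response=full.response, weights=weights, specs=[f.spec for f in conv],
        avg_coef=pd.DataFrame(avg, index=list(cats[1:]), columns=cols),
        uncond_se=pd.DataFrame(np.sqrt(var), index=list(cats[1:]),
                               columns=cols),
        importance=importance, avg_prob=avg_prob, accuracy=accuracy,
        chance=chance, modal=modal, categories=cats,
        design_columns=tuple(cols),
        best_aicc=float(min(f.aicc for f in conv)), fits=list(conv))


def relative_importance(specs: Sequence[ModelSpec],
                        weights: Sequence[float],
                        all_terms=None) -> dict:
    """Summed Akaike weight of the models containing each predictor.

    The random effect and the borrowing term count as predictors, so their
    importances are defined alongside the fixed terms.  ``all_terms`` fixes
    the reported term universe (a predictor present only in non-converged,
    hence excluded, models scores 0).
    """
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    terms = set(all_terms) if all_terms is not None else set()
    if all_terms is None:
        for s in specs:
            terms.update(s.predictors)
            if s.random_effect:
                terms.add(RANDOM_EFFECT_TERM)
    out = {}
    for t in sorted(terms):
        w = 0.0
        for s, wi in zip(specs, weights):
            if (t == RANDOM_EFFECT_TERM and s.random_effect) or \
               (t in s.predictors):
                w += wi
        out[t] = float(w)
    return out


def _averaged_probs_at(avg: AveragedModel, X: np.ndarray) -> np.ndarray:
    """Population-level averaged probabilities at new design rows."""
    n = X.shape[0]
    Xd = np.concatenate([np.ones((n, 1)), X], axis=1)
    eta = Xd @ avg.avg_coef.to_numpy().T
    full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    ex = np.exp(full)
    return ex / ex.sum(axis=1, keepdims=True)


def effect_profile(avg: AveragedModel, composite: str, grid: Sequence[float],
                   fixed: Optional[dict] = None,
                   by: Optional[str] = None,
                   by_levels: Sequence[float] = (1.0, 5.0)) -> pd.DataFrame:
    """Averaged probability curves along one composite.

    All other design columns are held at ``fixed`` values (default 0, i.e.
    composites at their mean and social dummies at their reference level).
    With ``by`` (e.g. political complexity) the curves are stratified at
    ``by_levels`` — the large-state vs acephalous contrast — and any
    interaction column involving both variables follows the product.
    """
    cols = [c for c in avg.design_columns if c != "intercept"]
    if composite not in cols:
        raise ValueError(f"unknown composite {composite!r}")
    grid = np.asarray(grid, dtype=float)
    fixed = dict(fixed or {})
    strata = list(by_levels) if by else [None]
    frames = []
    for level in strata:
        X = np.zeros((len(grid), len(cols)))
        for j, c in enumerate(cols):
            if c == composite:
                X[:, j] = grid
            elif by is not None and c == by:
                X[:, j] = level
            elif ":" in c:
                a, b = c.split(":")
                va = grid if a == composite else np.full(
                    len(grid), level if by is not None and a == by
                    else fixed.get(a, 0.0))
                vb = grid if b == composite else np.full(
                    len(grid), level if by is not None and b == by
                    else fixed.get(b, 0.0))
                X[:, j] = va * vb
            elif c in fixed:
                X[:, j] = fixed[c]
        probs = _averaged_probs_at(avg, X)
        df = pd.DataFrame(probs, columns=list(avg.categories))
        df.insert(0, composite, grid)
        if by is not None:
            df.insert(1, by, level)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def crosstab_percent(a: Sequence, b: Sequence,
                     a_levels: Optional[Sequence] = None,
                     b_levels: Optional[Sequence] = None):
    """Row-percentage cross-tabulation with raw counts.

    Missing values are dropped pairwise; categories absent from ``b`` are
    retained as 0% columns.  Returns (percent, counts) DataFrames; percent
    rows sum to 100.
    """
    s = pd.DataFrame({"a": pd.Series(a, dtype=object),
                      "b": pd.Series(b, dtype=object)})
    s = s[~s["a"].isin(["missing", "excluded"]) & s["a"].notna()
          & ~s["b"].isin(["missing", "excluded"]) & s["b"].notna()]
    if s.empty:
        raise ValueError("no complete pairs")
    counts = pd.crosstab(s["a"], s["b"])
    if a_levels is not None:
        counts = counts.reindex(index=[l for l in a_levels], fill_value=0)
        counts = counts.dropna(how="all")
    if b_levels is not None:
        counts = counts.reindex(columns=list(b_levels), fill_value=0)
    counts = counts.astype(int)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct, counts
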