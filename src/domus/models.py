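"""Binary/multinomial logistic regression with language-family random intercepts.

The response is a house feature with J categories; a baseline-category logit
assigns each non-reference category j a linear predictor eta_j = x'beta_j
(the reference category has eta = 0) and P(y = j) = softmax(eta)_j.  Vertical
cultural transmission is absorbed by a per-language-family random intercept
u_{g,j} ~ N(0, sigma_j^2), independent across categories and families
(diagonal structure, one variance per non-reference category).

Fixed-effect fits are exact Newton maximum likelihood.  Mixed fits maximise
the joint penalised log-likelihood over (beta, u) by Newton, with the
variances sigma_j^2 chosen to maximise the Laplace approximation of the
marginal likelihood.  Boundary estimates (sigma -> 0) are allowed and the
fit falls back smoothly to the fixed-effect model.

AICc = -2 logL + 2K + 2K(K+1)/(n - K - 1) with K counting all fixed
coefficients (including intercepts) plus one variance per non-reference
category when a random effect is present, and n the number of societies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

SEPARATION_BOUND = 15.0


@dataclass
class FittedModel:
    """One fitted (mixed) categorical regression."""

    coef: np.ndarray            # (J-1) x (q+1), column 0 = intercept
    se: np.ndarray              # same shape (conditional SEs)
    re_var: np.ndarray          # (J-1,) random-intercept variances
    loglik: float
    k_params: int
    n_obs: int
    aicc: float
    converged: bool
    fitted_prob: np.ndarray     # n x J, columns ordered as `categories`
    categories: tuple           # reference category first
    term_names: tuple           # ('intercept', ...predictor columns)
    has_random_effect: bool = False
    group_effects: Optional[dict] = None   # group label -> (J-1,) intercepts
    boundary: bool = False
    spec: object = None


def _encode_response(y: Sequence, ref, categories=None):
    y = np.asarray(y, dtype=object)
    if categories is None:
        cats = sorted(set(y), key=str)
    else:
        cats = [c for c in categories if c in set(y)]
    if ref not in cats:
        raise ValueError(f"reference category {ref!r} not observed")
    cats = [ref] + [c for c in cats if c != ref]
    if len(cats) < 2:
        raise ValueError("response has a single observed category")
    index = {c: i for i, c in enumerate(cats)}
    return np.array([index[v] for v in y], dtype=int), tuple(cats)


def _softmax_probs(eta: np.ndarray) -> np.ndarray:
    """n x (J-1) linear predictors -> n x J probabilities (ref first)."""
    n = eta.shape[0]
    full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    ex = np.exp(full)
    return ex / ex.sum(axis=1, keepdims=True)


def _loglik(P: np.ndarray, ycode: np.ndarray) -> float:
    return float(np.log(np.clip(P[np.arange(len(ycode)), ycode],
                                1e-300, None)).sum())


def _newton_multinomial(Xd: np.ndarray, ycode: np.ndarray, J: int,
                        penalty: Optional[np.ndarray] = None,
                        b0: Optional[np.ndarray] = None,
                        tol: float = 1e-6, max_iter: int = 200,
                        guard: Optional[int] = None):
    """Newton maximisation of the (penalised) multinomial log-likelihood.

    Parameters are the flattened (J-1) x p coefficient matrix over the
    design ``Xd``.  ``penalty`` is an optional per-parameter ridge vector
    (quadratic penalty b' diag(penalty) b / 2).  ``guard`` limits the
    separation check |coef| > bound to the first ``guard`` parameters of
    each category block (the fixed part of a mixed design).

    Returns (b, loglik_unpenalised, P, hessian, converged, separated).
    """
    n, p = Xd.shape
    npar = (J - 1) * p
    b = np.zeros(npar) if b0 is None else b0.copy()
    pen = np.zeros(npar) if penalty is None else penalty
    Y = np.zeros((n, J))
    Y[np.arange(n), ycode] = 1.0

    def objective(bvec):
        eta = Xd @ bvec.reshape(J - 1, p).T
        P = _softmax_probs(eta)
        return _loglik(P, ycode) - 0.5 * float(bvec @ (pen * bvec)), P

    def information(P):
        """Observed information (negative Hessian) of the penalised loglik."""
        H = np.empty((npar, npar))
        for j in range(J - 1):
            pj = P[:, j + 1]
            for l in range(j, J - 1):
                pl = P[:, l + 1]
                w = pj * ((1.0 if j == l else 0.0) - pl)
                blk = Xd.T @ (Xd * w[:, None])
                H[j * p:(j + 1) * p, l * p:(l + 1) * p] = blk
                if l != j:
                    H[l * p:(l + 1) * p, j * p:(j + 1) * p] = blk
        H[np.diag_indices_from(H)] += pen
        return H

    obj, P = objective(b)
    converged = False
    separated = False
    for _ in range(max_iter):
        resid = Y[:, 1:] - P[:, 1:]              # n x (J-1)
        grad = (Xd.T @ resid).T.ravel() - pen * b
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        H = information(P)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving
        t = 1.0
        for _ in range(30):
            b_new = b + t * step
            obj_new, P_new = objective(b_new)
            if obj_new >= obj - 1e-12:
                break
            t *= 0.5
        b, obj, P = b_new, obj_new, P_new
        check = b.reshape(J - 1, p)[:, :guard] if guard else b
        if np.max(np.abs(check)) > SEPARATION_BOUND:
            separated = True
            break
    H = information(P)
    ll = _loglik(P, ycode)
    return b, ll, P, H, converged and not separated, separated


def _check_design(Xd: np.ndarray) -> None:
    if np.isnan(Xd).any():
        raise ValueError("design matrix contains missing values")
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")


def fit_multinomial(X: np.ndarray, y: Sequence, ref,
                    categories: Optional[Sequence] = None,
                    term_names: Optional[Sequence[str]] = None,
                    spec=None) -> FittedModel:
    """Maximum-likelihood baseline-category logit (binary is J = 2).

    ``X`` holds the predictor columns only; an intercept is prepended.
    Perfect separation (any |coef| > 15 during fitting) marks the fit
    non-converged but retains it.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0 or (X.ndim == 2 and X.shape[1] == 0):
        X = X.reshape(len(y), 0)
    ycode, cats = _encode_response(y, ref, categories)
    n = len(ycode)
    J = len(cats)
    Xd = np.concatenate([np.ones((n, 1)), X], axis=1)
    _check_design(Xd)
    q = X.shape[1]
    b, ll, P, H, ok, separated = _newton_multinomial(Xd, ycode, J)
    K = (J - 1) * (q + 1)
    se = _safe_se(H).reshape(J - 1, q + 1)
    names = tuple(["intercept"] + (list(term_names) if term_names
                                   else [f"x{i+1}" for i in range(q)]))
    return FittedModel(
        coef=b.reshape(J - 1, q + 1), se=se, re_var=np.zeros(J - 1),
        loglik=ll, k_params=K, n_obs=n,
        aicc=aicc(ll, K, n) if n > K + 1 else np.inf,
        converged=ok, fitted_prob=P, categories=cats, term_names=names,
        has_random_effect=False, spec=spec)


def _safe_se(H: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        d = np.full(H.shape[0], np.nan)
    d[d < 0] = np.nan
    return np.sqrt(d)


def fit_mixed_multinomial(X: np.ndarray, y: Sequence, groups: Sequence,
                          ref, categories: Optional[Sequence] = None,
                          term_names: Optional[Sequence[str]] = None,
                          spec=None, var_tol: float = 1e-3,
                          fix_var: Optional[Sequence[float]] = None) -> FittedModel:
    """Baseline-category logit with per-group random intercepts (Laplace).

    For each non-reference category j the linear predictor gains a group
    intercept u_{g,j} ~ N(0, sigma_j^2).  For fixed variances, (beta, u)
    maximise the joint penalised log-likelihood by Newton; the variances
    maximise the Laplace-approximate marginal log-likelihood, which is what
    ``loglik``/AICc report.  A single group falls back to the fixed fit
    with a warning and re_var = 0.

    ``fix_var`` holds the variances fixed (one per non-reference category)
    instead of estimating them; zeros give the fixed-effect limit.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0 or (X.ndim == 2 and X.shape[1] == 0):
        X = X.reshape(len(y), 0)
    ycode, cats = _encode_response(y, ref, categories)
    n, q = len(ycode), X.shape[1]
    J = len(cats)
    glabels = np.asarray([str(g) for g in groups], dtype=object)
    ug, gcode = np.unique(glabels, return_inverse=True)
    G = len(ug)
    if G < 2:
        warnings.warn("single group: falling back to fixed-effect fit")
        fit = fit_multinomial(X, y, ref, categories, term_names, spec=spec)
        fit.has_random_effect = False
        return fit

    Xfix = np.concatenate([np.ones((n, 1)), X], axis=1)
    _check_design(Xfix)
    Z = np.zeros((n, G))
    Z[np.arange(n), gcode] = 1.0
    Xd = np.concatenate([Xfix, Z], axis=1)
    pfix = q + 1
    p = pfix + G
    npar = (J - 1) * p
    u_slice = [np.arange(j * p + pfix, (j + 1) * p) for j in range(J - 1)]
    u_ix = np.concatenate(u_slice)

    state = {"b": np.zeros(npar)}

    def fit_given(logv: np.ndarray):
        """Joint Newton at variances exp(logv); Laplace marginal loglik."""
        v = np.exp(np.clip(logv, -30.0, 5.0))
        pen = np.zeros(npar)
        for j in range(J - 1):
            pen[u_slice[j]] = 1.0 / v[j]
        b, ll, P, H, ok, sep = _newton_multinomial(
            Xd, ycode, J, penalty=pen, b0=state["b"], guard=pfix)
        state["b"] = b
        quad = sum(float(b[u_slice[j]] @ b[u_slice[j]]) / v[j]
                   for j in range(J - 1))
        # H is the penalised Hessian; its u-block equals H_uu + D^{-1}
        Huu = H[np.ix_(u_ix, u_ix)]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            logdet = np.inf
        # the (2 pi)^{m/2} factors of the Gaussian prior and of the Laplace
        # integral cancel exactly, so no 2 pi constant appears
        lap = (ll - 0.5 * quad - 0.5 * G * float(np.log(v).sum())
               - 0.5 * logdet)
        return lap, (b, ll, P, H, ok, sep, v)

    def neg_marginal(logv):
        return -fit_given(np.atleast_1d(logv))[0]

    if fix_var is not None:
        fv = np.broadcast_to(np.asarray(fix_var, float), (J - 1,))
        # sigma^2 = 0 is the fixed-effect limit; floor keeps the penalised
        # system finite while making the Laplace correction negligible
        logv_hat = np.log(np.maximum(fv, np.exp(-25.0)))
    elif J == 2:
        res = optimize.minimize_scalar(neg_marginal, bounds=(-10.0, 4.0),
                                       method="bounded",
                                       options={"xatol": var_tol})
        logv_hat = np.array([res.x])
    else:
        res = optimize.minimize(neg_marginal, np.zeros(J - 1),
                                method="Nelder-Mead",
                                options={"xatol": var_tol, "fatol": 1e-4,
                                         "maxfev": 120 * (J - 1)})
        logv_hat = np.asarray(res.x, dtype=float)
    lap, (b, ll_cond, P, H, ok, sep, v) = fit_given(logv_hat)

    boundary = bool((logv_hat <= -6.0).any())
    re_var = np.where(logv_hat <= -6.0, 0.0, v)
    K = (J - 1) * (q + 1) + (J - 1)
    se_all = _safe_se(H)
    fix_ix = np.concatenate([np.arange(j * p, j * p + pfix)
                             for j in range(J - 1)])
    coef = b[fix_ix].reshape(J - 1, pfix)
    se = se_all[fix_ix].reshape(J - 1, pfix)
    geff = {ug[g]: np.array([b[u_slice[j][g]] for j in range(J - 1)])
            for g in range(G)}
    names = tuple(["intercept"] + (list(term_names) if term_names
                                   else [f"x{i+1}" for i in range(q)]))
    return FittedModel(
        coef=coef, se=se, re_var=re_var, loglik=float(lap),
        k_params=K, n_obs=n,
        aicc=aicc(float(lap), K, n) if n > K + 1 else np.inf,
        converged=ok and not sep, fitted_prob=P, categories=cats,
        term_names=names, has_random_effect=True, group_effects=geff,
        boundary=boundary, spec=spec)


def aicc(loglik: float, K: int, n: int) -> float:
    """Finite-sample corrected Akaike information criterion."""
    if n <= K + 1:
        raise ValueError("AICc undefined: n must exceed K + 1")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def predict_prob(fit: FittedModel, Xnew: np.ndarray,
                 groups: Optional[Sequence] = None) -> np.ndarray:
    """Predicted category probabilities at new covariate rows.

    Group labels seen in fitting use their estimated intercepts; unseen or
    omitted groups predict at the population level (u = 0).  Rows always
    sum to one.
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[0] == 0 or (Xnew.ndim == 2 and Xnew.shape[1] == 0):
        Xnew = Xnew.reshape(-1, 0)
    q = fit.coef.shape[1] - 1
    if Xnew.shape[1] != q:
        raise ValueError(f"expected {q} predictor columns, got {Xnew.shape[1]}")
    n = Xnew.shape[0]
    Xd = np.concatenate([np.ones((n, 1)), Xnew], axis=1)
    eta = Xd @ fit.coef.T
    if groups is not None and fit.group_effects:
        for i, g in enumerate(groups):
            u = fit.group_effects.get(str(g))
            if u is not None:
                eta[i] += u
    return _softmax_probs(eta)


def classification_metrics(prob: np.ndarray, y: Sequence,
                           categories: Sequence) -> tuple[float, float, float]:
    """(accuracy, chance, modal) baselines of a probabilistic classifier.

    accuracy: share of rows whose argmax category (ties resolved to the
    first category in declared order) equals the observation; chance = 1/J;
    modal: relative abundance of the most common observed category.
    """
    prob = np.asarray(prob, dtype=float)
    y = np.asarray(y, dtype=object)
    if prob.shape[0] != len(y):
        raise ValueError("probability rows not aligned with y")
    cats = list(categories)
    pred = np.asarray(cats, dtype=object)[prob.argmax(axis=1)]
    accuracy = float((pred == y).mean())
    chance = 1.0 / len(cats)
    counts = np.array([(y == c).sum() for c in cats], dtype=float)
    modal = float(counts.max() / counts.sum())
    return accuracy, chance, modal
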