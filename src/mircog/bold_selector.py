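"""Dantzig-type LP variable selection for supersaturated binary designs.

The selector screens p >> n standardized features against a centered binary
response by solving, for each value of a tuning parameter delta on a grid,

    min ||beta||_1   subject to   ||X^T (Yc - X beta)||_inf <= delta ,

a linear program (variables split into positive/negative parts, solved with
HiGHS). At ``delta >= delta_max = max_j |X_j^T Yc|`` the solution is exactly
zero, so the grid spans (0, delta_max] with uniformly spaced cut-points.
delta is tuned by stratified 5-fold cross-validation: per fold and per
delta, features with nonzero coefficients are refit in a (ridge-stabilised)
logistic classifier and scored by test-fold AUC; the delta with the highest
mean AUC wins (ties toward the larger, i.e. sparser, delta). The final
full-data solution path over [best delta, delta_max] ranks candidates by
their shrink-to-zero order: the last coefficient to leave the active set as
delta grows is the most important.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from sklearn.model_selection import StratifiedKFold

from .predictive_models import ModelSpec, auc_score, fit_logistic

#: coefficients with |beta| below this (on standardized features) are inactive
ACTIVE_TOL = 1e-8

#: ridge used to stabilise the per-fold logistic refits (perfect separation
#: is common on small folds with selected features)
CV_RIDGE = 1e-6

N_GRID_POINTS = 15


class DantzigInfeasibleError(RuntimeError):
    def __init__(self, delta: float, message: str = ""):
        self.delta = delta
        super().__init__(f"Dantzig LP infeasible at delta={delta:g} {message}".rstrip())


@dataclass
class SelectorInput:
    """Standardized design and centered response for the selector."""

    X: np.ndarray  # samples x features, columns mean 0 / sd 1 (ddof=1)
    Y: np.ndarray  # binary 0/1
    Yc: np.ndarray  # Y - mean(Y)
    feature_ids: list[str]


@dataclass
class SelectorPath:
    delta_grid: np.ndarray
    delta_max: float
    coefs: pd.DataFrame  # features x grid points
    shrink_to_zero_delta: pd.Series  # NaN for features never active
    ranking: list[str]  # active features, most important first
    diagnostics: dict = field(default_factory=dict)


@dataclass
class CvTuning:
    fold_assignments: np.ndarray
    auc_table: pd.DataFrame  # delta x fold
    mean_auc: pd.Series
    best_delta: float


@dataclass
class FinalSelection:
    candidates: list[str]
    path: SelectorPath
    model: ModelSpec | None


def standardize(values: pd.DataFrame, labels: pd.Series) -> SelectorInput:
    """Standardize features (mean 0, sd 1, ddof=1) and center the response.

    ``values`` is feature x sample; ``labels`` maps the same samples to
    binary 0/1. Zero-variance features are dropped with a warning.
    """
    labels = labels.loc[values.columns]
    y = labels.to_numpy()
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    mat = values.to_numpy(dtype=float).T  # samples x features
    sd = mat.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(values.index, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}...")
    mat = mat[:, keep]
    sd = sd[keep]
    X = (mat - mat.mean(axis=0)) / sd
    return SelectorInput(
        X=X,
        Y=y.astype(float),
        Yc=y - y.mean(),
        feature_ids=[f for f, k in zip(values.index, keep) if k],
    )


def delta_max(inp: SelectorInput) -> float:
    return float(np.max(np.abs(inp.X.T @ inp.Yc)))


def delta_grid(inp: SelectorInput, n_points: int = N_GRID_POINTS) -> np.ndarray:
    """``delta_i = i * delta_max / n_points`` for i = 1..n_points."""
    dmax = delta_max(inp)
    if dmax <= 0:
        raise ValueError("response is orthogonal to every feature (delta_max = 0)")
    return dmax * np.arange(1, n_points + 1) / n_points


def dantzig_solve(
    X: np.ndarray, Yc: np.ndarray, delta: float
) -> np.ndarray:
    """Solve the Dantzig selector LP at one delta; returns beta (length p).

    Split formulation: beta = b+ - b-, minimise 1^T (b+ + b-) subject to
    -delta <= X^T Yc - X^T X beta <= delta, b+/- >= 0. An auxiliary
    fitted-value variable z = X beta keeps the constraint matrix sparse
    (O(n p) nonzeros rather than a dense p x p Gram block), which is what
    makes the supersaturated p >> n case fast.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    corr = X.T @ Yc
    xs = sparse.csr_matrix(X)
    xt = sparse.csr_matrix(X.T)
    zeros = sparse.csr_matrix((p, 2 * p))
    # variables: beta+ (p), beta- (p), z (n, free); X beta - z = 0
    a_eq = sparse.hstack([xs, -xs, -sparse.identity(n)], format="csr")
    a_ub = sparse.vstack(
        [sparse.hstack([zeros, -xt]), sparse.hstack([zeros, xt])], format="csr"
    )
    b_ub = np.concatenate([delta - corr, delta + corr])
    res = linprog(
        c=np.concatenate([np.ones(2 * p), np.zeros(n)]),
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=np.zeros(n),
        bounds=[(0, None)] * (2 * p) + [(None, None)] * n,
        method="highs",
    )
    if res.status == 2:
        raise DantzigInfeasibleError(delta)
    if res.status != 0:
        raise RuntimeError(f"LP solver failed at delta={delta:g}: {res.message}")
    beta = res.x[:p] - res.x[p : 2 * p]
    viol = float(np.max(np.abs(corr - X.T @ (X @ beta)))) - delta
    if viol > 1e-6:
        raise RuntimeError(f"LP solution violates the delta constraint by {viol:g}")
    return beta


def solution_path(
    inp: SelectorInput, grid: np.ndarray, tol: float = ACTIVE_TOL
) -> SelectorPath:
    """Coefficient path over the grid plus the shrink-to-zero ranking.

    Ranking sorts active features by the largest grid delta at which the
    coefficient is still nonzero (descending), breaking ties by |beta| at
    that delta, then by |X_j^T Yc|, then by feature order.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0) and grid.size > 1:
        raise ValueError("grid must be non-empty and strictly increasing")
    p = inp.X.shape[1]
    coefs = np.zeros((p, grid.size))
    for i, d in enumerate(grid):
        coefs[:, i] = dantzig_solve(inp.X, inp.Yc, d)

    corr = np.abs(inp.X.T @ inp.Yc)
    active_any = np.abs(coefs).max(axis=1) > tol
    shrink = np.full(p, np.nan)
    order_keys = []
    for j in np.flatnonzero(active_any):
        last = int(np.max(np.flatnonzero(np.abs(coefs[j]) > tol)))
        shrink[j] = grid[last]
        order_keys.append((grid[last], abs(coefs[j, last]), corr[j], -j))
    ranked = [
        inp.feature_ids[-key[3]]
        for key in sorted(order_keys, reverse=True)
    ]

    support = (np.abs(coefs) > tol).sum(axis=0)
    diagnostics = {"support_sizes": support.tolist(),
                   "monotone_support": bool(np.all(np.diff(support) <= 0))}
    return SelectorPath(
        delta_grid=grid,
        delta_max=float(np.max(np.abs(inp.X.T @ inp.Yc))),
        coefs=pd.DataFrame(coefs, index=inp.feature_ids, columns=grid),
        shrink_to_zero_delta=pd.Series(shrink, index=inp.feature_ids),
        ranking=ranked,
        diagnostics=diagnostics,
    )


def _fold_standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (train - mean) / sd, (test - mean) / sd


def cv_tune(
    inp: SelectorInput,
    grid: np.ndarray,
    k: int = 5,
    seed: int | None = None,
    tol: float = ACTIVE_TOL,
    ridge: float = CV_RIDGE,
) -> CvTuning:
    """Stratified k-fold tuning of delta by mean test-fold AUC.

    Folds are re-standardized on their training rows. Per delta and fold,
    the LP runs on the training rows; selected features feed a
    ridge-stabilised logistic classifier scored on the test rows (AUC 0.5
    by convention when nothing is selected). Ties in mean AUC resolve to
    the larger delta.
    """
    y = inp.Y.astype(int)
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class size ({counts.min()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(y), dtype=int)
    aucs = np.full((grid.size, k), 0.5)
    for fold, (tr, te) in enumerate(skf.split(inp.X, y)):
        fold_of[te] = fold
        x_tr, x_te = _fold_standardize(inp.X[tr], inp.X[te])
        yc_tr = y[tr] - y[tr].mean()
        for i, d in enumerate(grid):
            beta = dantzig_solve(x_tr, yc_tr, d)
            sel = np.flatnonzero(np.abs(beta) > tol)
            if sel.size == 0:
                aucs[i, fold] = 0.5
                continue
            model = fit_logistic(x_tr[:, sel], y[tr], ridge=ridge)
            scores = model.predict_proba(x_te[:, sel])
            aucs[i, fold] = auc_score(scores, y[te])

    table = pd.DataFrame(aucs, index=grid, columns=[f"fold{f}" for f in range(k)])
    mean_auc = table.mean(axis=1)
    best_idx = int(np.flatnonzero(mean_auc.to_numpy() == mean_auc.max())[-1])
    return CvTuning(
        fold_assignments=fold_of,
        auc_table=table,
        mean_auc=mean_auc,
        best_delta=float(grid[best_idx]),
    )


def final_selection(
    inp: SelectorInput,
    best_delta: float,
    grid: np.ndarray,
    tol: float = ACTIVE_TOL,
    ridge: float = CV_RIDGE,
) -> FinalSelection:
    """Full-data path on [best_delta, delta_max]; candidates ranked by
    shrink-to-zero order; a logistic model on the candidates is returned.

    Zero candidates at best_delta is a valid (empty) outcome.
    """
    sub_grid = np.asarray(grid)[np.asarray(grid) >= best_delta - 1e-12]
    path = solution_path(inp, sub_grid, tol=tol)
    at_best = path.coefs.iloc[:, 0]
    active = set(at_best.index[np.abs(at_best.to_numpy()) > tol])
    candidates = [f for f in path.ranking if f in active]
    if not candidates:
        warnings.warn(f"no candidate active at best delta {best_delta:g}")
        return FinalSelection([], path, None)
    idx = [inp.feature_ids.index(f) for f in candidates]
    model = fit_logistic(
        inp.X[:, idx], inp.Y.astype(int), ridge=ridge, predictors=candidates
    )
    return FinalSelection(candidates, path, model)
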