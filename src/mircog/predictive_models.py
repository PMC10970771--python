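"""Validation-phase predictive modelling.

Dichotomises Parkinson's disease dementia (PDD) as a total MoCA score <= 21,
fits multivariate logistic regressions by IRLS maximum likelihood, reduces
the candidate predictor set by exhaustive smallest-AIC search, splits the
cohort 70/30 with stratification, and evaluates ROC curves whose operating
point maximises sensitivity + specificity, with percentile bootstrap
confidence intervals (B = 2000, class-stratified resampling).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

#: candidate predictors of the full dementia model
CANDIDATE_PREDICTORS = ("age", "gender", "onset_age", "education", "updrs3", "ratio")

#: the seven predictor sets of the model-comparison table
COMPARISON_VARIABLE_SETS: tuple[tuple[str, ...], ...] = (
    ("ratio",),
    ("age",),
    ("updrs3",),
    ("ratio", "age"),
    ("ratio", "updrs3"),
    ("age", "updrs3"),
    ("ratio", "age", "updrs3"),
)

MOCA_DEMENTIA_CUTOFF = 21


class SeparationError(RuntimeError):
    """The likelihood is unbounded (perfectly separable classes)."""


@dataclass
class ModelSpec:
    """A fitted logistic model: predictors, coefficients, fit quality."""

    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    log_likelihood: float
    aic: float
    converged: bool
    n_iter: int
    ridge: float = 0.0

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.predictors)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        eta = np.clip(self.coefficients[0] + X @ self.coefficients[1:], -500, 500)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class RocResult:
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    auc_ci: tuple[float, float] | None = None
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None
    accuracy_ci: tuple[float, float] | None = None


def dementia_label(moca_total) -> np.ndarray | int:
    """1 iff the total MoCA score is <= 21 (the PDD band), else 0."""
    arr = np.asarray(moca_total, dtype=float)
    if np.any((arr < 0) | (arr > 30)):
        raise ValueError("MoCA total scores must lie in [0, 30]")
    labels = (arr <= MOCA_DEMENTIA_CUTOFF).astype(int)
    return int(labels) if np.isscalar(moca_total) else labels


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    ridge: float = 0.0,
    predictors: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ModelSpec:
    """Maximum-likelihood logistic fit by Newton/IRLS, optional ridge.

    The ridge penalty (not applied to the intercept) only stabilises the
    Hessian; the reported log-likelihood and AIC are unpenalised. With
    ridge = 0, diverging coefficients (perfect separation) raise
    :class:`SeparationError`.
    """
    if isinstance(X, pd.DataFrame):
        predictors = tuple(X.columns) if predictors is None else tuple(predictors)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if predictors is None:
            predictors = tuple(f"x{i}" for i in range(X.shape[1]))
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if X.shape[1] and np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant predictor column")

    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    penalty = np.zeros(p + 1)
    penalty[1:] = ridge

    def objective(b: np.ndarray) -> float:
        # penalised negative log-likelihood (clipped eta keeps exp finite)
        eta = np.clip(design @ b, -35, 35)
        return float(-np.sum(y * eta - np.logaddexp(0.0, eta)) + 0.5 * np.sum(penalty * b * b))

    obj = objective(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(design @ beta, -35, 35)  # floor on the IRLS weights
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = design.T @ (y - mu) - penalty * beta
        hess = (design * w[:, None]).T @ design + np.diag(penalty)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular Hessian; classes may be separable") from exc
        # damped Newton: halve until the penalised objective does not worsen
        scale = 1.0
        for _ in range(40):
            new_obj = objective(beta + scale * step)
            if new_obj <= obj + 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if ridge == 0.0 and (np.max(np.abs(beta)) > 1e3 or not np.all(np.isfinite(beta))):
            raise SeparationError("diverging coefficients: perfect separation")
        if np.max(np.abs(scale * step)) < tol or abs(obj - new_obj) < 1e-13 * (1 + abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if not converged and ridge == 0.0:
        raise SeparationError(f"IRLS did not converge in {max_iter} iterations")
    if ridge == 0.0:
        # perfect separation: every fitted probability saturates on its label,
        # so the unpenalised likelihood has no finite maximiser
        mu = 1.0 / (1.0 + np.exp(-np.clip(design @ beta, -500, 500)))
        if np.all(np.abs(y - mu) < 1e-6):
            raise SeparationError("perfect separation: fitted probabilities saturate")

    eta = design @ beta
    # log-likelihood via the numerically stable log(1 + exp(.))
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    aic = 2.0 * (p + 1) - 2.0 * loglik
    return ModelSpec(
        predictors=tuple(predictors),
        coefficients=beta,
        log_likelihood=loglik,
        aic=aic,
        converged=converged,
        n_iter=it,
        ridge=ridge,
    )


def fit_null_logistic(y: Sequence[int]) -> ModelSpec:
    """Intercept-only logistic model (closed form)."""
    y = np.asarray(y, dtype=float)
    pbar = y.mean()
    beta = np.array([np.log(pbar / (1.0 - pbar))])
    loglik = float(np.sum(y * np.log(pbar) + (1 - y) * np.log(1 - pbar)))
    return ModelSpec((), beta, loglik, 2.0 - 2.0 * loglik, True, 0)


def reduce_by_aic(
    candidates: Sequence[str],
    X: pd.DataFrame,
    y: Sequence[int],
    ridge: float = 0.0,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Exhaustive smallest-AIC search over all non-empty predictor subsets.

    Ties prefer fewer predictors, then lexicographic order. Subsets whose
    fit fails (e.g. separation) are recorded and skipped. Returns the best
    model and the full AIC table.
    """
    candidates = list(candidates)
    if len(candidates) > 20:
        raise ValueError("exhaustive search limited to <= 20 candidates")
    rows = []
    best: ModelSpec | None = None
    for size in range(1, len(candidates) + 1):
        for subset in combinations(sorted(candidates), size):
            try:
                model = fit_logistic(X[list(subset)], y, ridge=ridge)
            except (SeparationError, ValueError) as exc:
                rows.append({"predictors": subset, "aic": np.nan, "error": str(exc)})
                continue
            rows.append({"predictors": subset, "aic": model.aic, "error": ""})
            if best is None or model.aic < best.aic - 1e-12:
                best = model
    if best is None:
        raise RuntimeError("every candidate subset failed to fit")
    return best, pd.DataFrame(rows)


def split_train_test(
    y: Sequence[int],
    train_frac: float = 0.7,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split; deterministic under ``seed``."""
    y = np.asarray(y)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, stratify=y, random_state=seed
    )
    for side, name in ((train_idx, "train"), (test_idx, "test")):
        counts = np.bincount(y[side], minlength=2)
        if counts.min() < 2:
            raise ValueError(f"{name} split has a class with < 2 members")
    return np.sort(train_idx), np.sort(test_idx)


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the Mann-Whitney statistic; tied pairs count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Point estimates: AUC plus the maximal sens+spec operating point.

    Cut-points are the observed unique scores plus +inf ("predict none");
    a score >= threshold predicts the positive class. Ties in sens+spec are
    broken toward higher specificity, then toward the larger threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    auc = auc_score(scores, labels)

    cutpoints = np.concatenate([np.unique(scores), [np.inf]])
    best = None
    for t in cutpoints:
        pred = scores >= t
        sens = float(np.sum(pred & pos)) / n1
        spec = float(np.sum(~pred & ~pos)) / n0
        key = (sens + spec, spec, t)
        if best is None or key > best[0]:
            acc = float(np.sum(pred == pos)) / len(labels)
            best = (key, sens, spec, acc, float(t))
    _, sens, spec, acc, threshold = best
    return RocResult(auc, sens, spec, acc, threshold)


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Class-stratified percentile bootstrap CI for a score-based metric."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    if idx_pos.size == 0 or idx_neg.size == 0:
        raise ValueError("both classes must be present")
    values = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx_pos, idx_pos.size), rng.choice(idx_neg, idx_neg.size)]
        )
        values[b] = metric_fn(scores[take], labels[take])
    lo, hi = np.percentile(values, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def _roc_metric(which: str) -> Callable[[np.ndarray, np.ndarray], float]:
    if which == "auc":
        return auc_score

    def metric(scores: np.ndarray, labels: np.ndarray) -> float:
        return getattr(roc_analysis(scores, labels), which)

    return metric


def roc_with_bootstrap(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> RocResult:
    """ROC point estimates plus percentile bootstrap CIs for each metric."""
    result = roc_analysis(scores, labels)
    for name in ("auc", "sensitivity", "specificity", "accuracy"):
        ci = bootstrap_ci(_roc_metric(name), scores, labels, n_boot, level, seed)
        setattr(result, f"{name}_ci", ci)
    return result


def model_comparison_table(
    cohort: pd.DataFrame,
    variable_sets: Sequence[Sequence[str]] = COMPARISON_VARIABLE_SETS,
    train_frac: float = 0.7,
    n_boot: int = 2000,
    ridge: float = 1e-6,
    seed: int | None = None,
) -> pd.DataFrame:
    """Train/test ROC comparison of the candidate logistic models.

    The cohort (PD patients only) is split ``train_frac``/rest stratified by
    the dementia label; each variable set is fit on the training side (tiny
    ridge for stability on small splits) and evaluated on the test side with
    bootstrap CIs. One row per variable set.
    """
    y = dementia_label(cohort["moca_total"].to_numpy())
    train_idx, test_idx = split_train_test(y, train_frac=train_frac, seed=seed)
    rows = []
    for vs in variable_sets:
        vs = list(vs)
        model = fit_logistic(cohort.iloc[train_idx][vs], y[train_idx], ridge=ridge)
        test_scores = model.predict_proba(cohort.iloc[test_idx])
        roc = roc_with_bootstrap(test_scores, y[test_idx], n_boot=n_boot, seed=seed)
        rows.append(
            {
                "variables": " + ".join(vs),
                "auc": roc.auc,
                "auc_ci_low": roc.auc_ci[0],
                "auc_ci_high": roc.auc_ci[1],
                "specificity": roc.specificity,
                "specificity_ci_low": roc.specificity_ci[0],
                "specificity_ci_high": roc.specificity_ci[1],
                "sensitivity": roc.sensitivity,
                "sensitivity_ci_low": roc.sensitivity_ci[0],
                "sensitivity_ci_high": roc.sensitivity_ci[1],
                "accuracy": roc.accuracy,
                "accuracy_ci_low": roc.accuracy_ci[0],
                "accuracy_ci_high": roc.accuracy_ci[1],
            }
        )
    return pd.DataFrame(rows)
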