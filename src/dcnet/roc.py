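"""ROC discrimination analysis of single-region and composite DC indexes.

A single index is one region's degree centrality; the composite index is the
predicted probability of an unpenalized logistic regression
z_i = a_0 + sum_j a_j X_ij, P_i = 1 / (1 + exp(-z_i)) combining the
significant regions.  Reported per comparison: AUC with DeLong 95% CI and a
test of AUC = 0.5, the Youden-optimal cut-off, and sensitivity/specificity
in percent.  The criterion convention is "positive if value > c"; the curve
orientation is chosen automatically so AUC >= 0.5 and is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)


class PerfectSeparationError(ValueError):
    """Raised when logistic-regression MLE diverges (perfectly separable
    classes); a penalized fit would be needed."""


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    cutoff: float
    sensitivity: float  # percent, at the Youden cut-off
    specificity: float  # percent
    youden: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # criterion values on the oriented scale
    orientation: int  # +1: positive if value > c; -1: positive if value < c

    @property
    def curve(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


@dataclass
class LRModel:
    """Unpenalized logistic regression fit (maximum likelihood by IRLS)."""

    a0: float
    coefficients: np.ndarray
    n_iter: int
    converged: bool
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.a0 + np.asarray(X, dtype=float) @ self.coefficients

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.linear_predictor(X)
        # equivalent stable form of 1 / (1 + exp(-z))
        return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))


def _binary_curve(values: np.ndarray, labels: np.ndarray):
    """ROC points over all distinct thresholds of the criterion
    "positive if value > c", descending.  Point k corresponds to c equal to
    the k-th distinct value (point 0 = (0,0) at c >= max; final point =
    (1,1) at c = -inf)."""
    order = np.argsort(-values, kind="stable")
    v, y = values[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(v)), v.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = distinct + 1 - tps
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[v[distinct], -np.inf]
    return fpr, tpr, thresholds


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC (with the half-tie convention) and its DeLong variance."""
    m, n = pos.size, neg.size
    combined = np.r_[pos, neg]
    # midranks handle ties exactly as DeLong's placement values require
    rank_all = stats.rankdata(combined, method="average")
    rank_pos = stats.rankdata(pos, method="average")
    rank_neg = stats.rankdata(neg, method="average")
    v10 = (rank_all[:m] - rank_pos) / n  # placement of each positive
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m  # placement of each negative
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_curve(values, labels, alpha: float = 0.05) -> ROCResult:
    """Full ROC analysis of one index against binary labels.

    Orientation is auto-selected so AUC >= 0.5 (recorded in ``orientation``;
    cut-offs are reported on the original scale).  AUC uses the trapezoid /
    half-tie convention; CI and the p-value for AUC = 0.5 use the DeLong
    variance.  The Youden cut-off maximizes sensitivity + specificity - 1,
    ties broken by higher sensitivity then lower cut-off.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-D and aligned")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("both classes must be present")
    if np.ptp(values) == 0:
        logger.warning("all index values identical: degenerate ROC curve, AUC = 0.5")
    auc_raw, _ = _delong_auc_variance(values[labels == 1], values[labels == 0])
    orientation = 1 if auc_raw >= 0.5 else -1
    v = values * orientation
    auc, var = _delong_auc_variance(v[labels == 1], v[labels == 0])
    se = np.sqrt(var)
    if se > 0:
        z = (auc - 0.5) / se
        p_value = float(2.0 * stats.norm.sf(abs(z)))
        ci_low = float(np.clip(auc - 1.959963984540054 * se, 0.0, 1.0))
        ci_high = float(np.clip(auc + 1.959963984540054 * se, 0.0, 1.0))
    else:
        p_value = 1.0 if auc == 0.5 else 0.0
        ci_low = ci_high = auc
    fpr, tpr, thresholds = _binary_curve(v, labels)
    # Youden scan over curve points (each point is one observed criterion)
    j = tpr - fpr
    best = 0
    for k in range(1, j.size):
        if (j[k] > j[best] + 1e-12) or (
            abs(j[k] - j[best]) <= 1e-12 and tpr[k] > tpr[best] + 1e-12
        ):
            best = k
    cutoff = float(thresholds[best] * orientation) if np.isfinite(thresholds[best]) else (
        float("-inf") if orientation == 1 else float("inf")
    )
    return ROCResult(
        auc=float(auc),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        cutoff=cutoff,
        sensitivity=float(100.0 * tpr[best]),
        specificity=float(100.0 * (1.0 - fpr[best])),
        youden=float(j[best]),
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        orientation=orientation,
    )


def youden_cutoff(result: ROCResult) -> tuple[float, float, float]:
    """(cut-off, sensitivity %, specificity %) at the Youden optimum."""
    return result.cutoff, result.sensitivity, result.specificity


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LRModel:
    """Unpenalized logistic regression by iteratively reweighted least
    squares (Newton scoring).

    Columns are standardized internally for conditioning; coefficients are
    reported on the original scale.  Convergence: max |score| < tol.
    Perfectly separable data makes the MLE diverge and raises
    :class:`PerfectSeparationError` (a penalized fit is the usual fallback).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y).astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant predictor column: drop it before fitting")
    Xs = np.hstack([np.ones((X.shape[0], 1)), (X - mu) / sd])
    beta = np.zeros(Xs.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        z = Xs @ beta
        p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
        score = Xs.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.maximum(p * (1.0 - p), 1e-12)
        hess = Xs.T @ (Xs * w[:, None])
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError as exc:
            raise PerfectSeparationError(
                f"singular information matrix at iteration {n_iter}: data may be "
                "perfectly separable; consider a penalized fit"
            ) from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 1e3:
            raise PerfectSeparationError(
                "diverging coefficients: classes are (quasi-)separable; "
                "consider a penalized fit"
            )
    if not converged:
        raise PerfectSeparationError(
            f"IRLS did not converge in {max_iter} iterations; data may be "
            "separable or ill-conditioned"
        )
    # a saturated fit can meet the score tolerance while the MLE diverges;
    # a standardized coefficient this large only occurs under separation
    if np.max(np.abs(beta[1:])) > 15.0:
        raise PerfectSeparationError(
            "standardized coefficients diverged: classes are (quasi-)separable; "
            "consider a penalized fit"
        )
    coef = beta[1:] / sd
    a0 = float(beta[0] - np.sum(beta[1:] * mu / sd))
    return LRModel(a0=a0, coefficients=coef, n_iter=n_iter, converged=converged, X=X, y=y)


def composite_roc(model: LRModel, X: np.ndarray, y: np.ndarray) -> ROCResult:
    """ROC of the fitted composite index (predicted probability P_i)."""
    return roc_curve(model.predict_proba(X), np.asarray(y).astype(int))


class CompositeIndexClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn classifier around :func:`fit_logistic` so the composite
    index composes with sklearn pipelines and model selection."""

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary classification only")
        y01 = (y == self.classes_[1]).astype(int)
        self.model_ = fit_logistic(X, y01, tol=self.tol, max_iter=self.max_iter)
        self.intercept_ = np.array([self.model_.a0])
        self.coef_ = self.model_.coefficients[None, :]
        return self

    def decision_function(self, X):
        return self.model_.linear_predictor(X)

    def predict_proba(self, X):
        p1 = self.model_.predict_proba(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.model_.predict_proba(X) >= 0.5).astype(int)]
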