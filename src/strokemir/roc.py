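"""ROC/AUC for single markers and logistic-combination biomarker panels.

AUC is the rank (Mann-Whitney) statistic with midrank tie handling: the
probability that a randomly chosen case outscores a randomly chosen control,
counting ties as one half.  The ROC curve is built by sweeping the unique
score thresholds; its trapezoidal area equals the rank AUC.

A multi-marker panel is scored by the linear predictor of a maximum-likelihood
logistic regression fitted by iteratively reweighted least squares (IRLS).
Perfect separation is detected and flagged rather than raised: coefficients
are returned at the iteration cap with a warning, since only the score
ordering (not the diverging coefficient magnitudes) matters for ROC use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


class RocError(ValueError):
    pass


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_thresholds: int

    @property
    def curve(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    coef: np.ndarray
    converged: bool
    n_iter: int
    separated: bool

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coef

    def predict_proba(self, X) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise RocError("labels must contain both classes, coded 0/1")
    return y


def auc(scores, labels) -> RocResult:
    """Rank-based AUC with midrank ties, plus the threshold-swept ROC curve."""
    s = np.asarray(scores, dtype=float)
    y = _check_labels(labels)
    if s.shape != y.shape:
        raise RocError("scores and labels must have the same length")
    n1, n0 = int(y.sum()), int((1 - y).sum())
    ranks = rankdata(s)
    u = float(ranks[y == 1].sum() - n1 * (n1 + 1) / 2)
    auc_value = u / (n1 * n0)

    # ROC curve: descending unique thresholds, cumulative TP/FP counts.
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    last_of_value = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[last_of_value] / n1]
    fpr = np.r_[0.0, fps[last_of_value] / n0]
    return RocResult(auc=auc_value, fpr=fpr, tpr=tpr, n_thresholds=len(last_of_value))


def fit_logistic(markers, labels, tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS with an intercept."""
    X = np.asarray(markers, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _check_labels(labels).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise RocError("need >= 2 samples per class")
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = A.T @ (y - mu)
        hess = (A * w[:, None]).T @ A
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = A @ beta
    # Perfect separation: every fitted linear predictor already classifies
    # correctly and the likelihood keeps pushing |beta| outward.
    separated = bool(not converged and np.all((eta > 0) == (y == 1)))
    if separated:
        warnings.warn(
            "perfect separation detected; coefficients returned at iteration cap",
            RuntimeWarning,
            stacklevel=2,
        )
    return LogisticFit(
        intercept=float(beta[0]),
        coef=beta[1:].copy(),
        converged=converged,
        n_iter=n_iter,
        separated=separated,
    )


def panel_auc(markers, labels, marker_subset=None) -> RocResult:
    """AUC of the fitted logistic linear predictor over a marker subset.

    ``markers`` may be a 2-D array or a pandas DataFrame; ``marker_subset``
    selects columns (by name for a DataFrame, by index otherwise).
    """
    if hasattr(markers, "loc") and marker_subset is not None:
        X = markers[list(marker_subset)].to_numpy(dtype=float)
    elif marker_subset is not None:
        X = np.asarray(markers, dtype=float)[:, list(marker_subset)]
    else:
        X = np.asarray(markers, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        raise RocError("marker subset must be non-empty")
    fit = fit_logistic(X, labels)
    return auc(fit.decision_function(X), labels)


def cross_validated_panel_auc(markers, labels, marker_subset=None, k: int = 5,
                              seed: int = 0) -> RocResult:
    """Stratified k-fold variant: AUC of out-of-fold linear-predictor scores.

    Clearly labeled as distinct from the default in-sample AUC; folds are
    stratified by class and shuffled by ``seed``.
    """
    if hasattr(markers, "loc"):
        X = (markers[list(marker_subset)] if marker_subset is not None else markers
             ).to_numpy(dtype=float)
    else:
        X = np.asarray(markers, dtype=float)
        if marker_subset is not None:
            X = X[:, list(marker_subset)]
    if X.ndim == 1:
        X = X[:, None]
    y = _check_labels(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    scores = np.empty(len(y), dtype=float)
    for fold in range(k):
        test = folds == fold
        fit = fit_logistic(X[~test], y[~test])
        scores[test] = fit.decision_function(X[test])
    return auc(scores, y)


def single_marker_aucs(markers, labels) -> dict[str, float]:
    """Per-column in-sample AUC (DataFrame input); warns if any AUC < 0.5."""
    out = {}
    for col in markers.columns:
        r = auc(markers[col].to_numpy(dtype=float), labels)
        if r.auc < 0.5:
            warnings.warn(
                f"marker {col!r} has AUC {r.auc:.3f} < 0.5; its score orientation "
                "may be inverted", RuntimeWarning, stacklevel=2,
            )
        out[col] = r.auc
    return out
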