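"""Linear SVM training, SVM-RFE ranking and LOOCV frequency-based selection.

Variables are ranked by backward elimination on the squared primal weights
of a linear soft-margin SVM,

    w_j^2 = ( sum_{i in phi} alpha_i y_i x_ij )^2,

where phi indexes the support vectors.  A leave-one-out loop repeats the
ranking on every reduced training set; within each fold the top-k* ranked
variables are marked selected, where k* minimises a stratified inner
cross-validation error over the nested subset sizes (smallest k on ties).
The optimum set consists of the variables selected at least
median(counts) + 1 times (lower median for even counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._smo import nested_subset_errors, rfe_removal_order, smo_solve

__all__ = [
    "SVMModel",
    "SelectionResult",
    "EmptySelectionError",
    "train_linear_svm",
    "rfe_rank",
    "loocv_select",
]

_SMO_TOL = 1e-10  # single fits: tight, so the dual matches QP oracles
_RFE_TOL = 1e-6  # inside RFE/CV loops: only the w^2 ordering matters
_SMO_MAX_ITER = 200_000


class EmptySelectionError(RuntimeError):
    """Raised when the median + 1 rule selects no variable."""


@dataclass
class SVMModel:
    """Fitted soft-margin linear SVM in dual and primal form."""

    alphas: np.ndarray
    bias: float
    weights: np.ndarray
    support_: np.ndarray  # indices with alpha > 0
    y: np.ndarray
    C: float
    n_iter: int = 0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        s = self.decision_function(X)
        # boundary ties go to the +1 class
        return np.where(s >= 0.0, 1.0, -1.0)


@dataclass
class SelectionResult:
    """Outcome of LOOCV SVM-RFE variable selection."""

    ranking: np.ndarray  # variables sorted best-first
    counts: np.ndarray  # per-variable selection frequency over folds
    threshold: int  # median(counts) + 1
    selected: np.ndarray  # indices with count >= threshold
    n_folds: int = 0
    variable_names: list | None = None

    def selected_names(self) -> list:
        if self.variable_names is None:
            return [int(j) for j in self.selected]
        return [self.variable_names[j] for j in self.selected]

    def to_dict(self) -> dict:
        return {
            "ranking": [int(j) for j in self.ranking],
            "counts": [int(c) for c in self.counts],
            "threshold": int(self.threshold),
            "selected": [int(j) for j in self.selected],
            "selected_names": self.selected_names(),
            "n_folds": int(self.n_folds),
        }


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a 2-D samples x variables array")
    if y.size != X.shape[0]:
        raise ValueError("label vector length does not match X")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in training data")
    classes = np.unique(y)
    if not np.array_equal(classes, np.array([-1.0, 1.0])):
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        raise ValueError("labels must be coded -1/+1")
    return X, y


def train_linear_svm(X, y, C: float = 1.0) -> SVMModel:
    """Fit a soft-margin linear SVM by SMO on the dual problem."""
    X, y = _validate_xy(X, y)
    if C <= 0:
        raise ValueError("C must be positive")
    K = X @ X.T
    alpha, bias, n_iter = smo_solve(K, y, float(C), _SMO_TOL, _SMO_MAX_ITER)
    if n_iter >= _SMO_MAX_ITER:
        raise RuntimeError("SMO failed to converge within the iteration budget")
    w = (alpha * y) @ X
    support = np.flatnonzero(alpha > 1e-10)
    return SVMModel(
        alphas=alpha, bias=float(bias), weights=w, support_=support, y=y, C=float(C),
        n_iter=int(n_iter),
    )


def rfe_rank(X, y, C: float = 1.0) -> np.ndarray:
    """SVM-RFE ranking: best variable first (removed last)."""
    X, y = _validate_xy(X, y)
    if X.shape[1] < 2:
        raise ValueError("RFE needs at least 2 variables")
    order = rfe_removal_order(X, y, float(C), _RFE_TOL, _SMO_MAX_ITER)
    return order[::-1].copy()


def _fold_scale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tolerant autoscaling for internal CV folds (zero-variance -> zeros)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Deterministic stratified fold assignment; every fold gets samples."""
    n = y.size
    assign = np.empty(n, dtype=np.int64)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % n_folds
    return assign


def loocv_select(
    X,
    y,
    C: float = 1.0,
    inner_folds: int = 5,
    seed: int = 0,
    variable_names: list | None = None,
) -> SelectionResult:
    """LOOCV SVM-RFE selection with the median + 1 frequency rule."""
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 samples for LOOCV selection")
    for cls in (-1.0, 1.0):
        if np.sum(y == cls) < 2:
            raise ValueError("each class needs at least 2 samples")
    rng = np.random.default_rng(seed)
    counts = np.zeros(p, dtype=np.int64)
    for left_out in range(n):
        mask = np.ones(n, dtype=bool)
        mask[left_out] = False
        Xtr_raw, ytr = X[mask], y[mask]
        if np.unique(ytr).size < 2:
            raise ValueError("LOOCV fold training set has a single class")
        Xtr, _, _ = _fold_scale(Xtr_raw)
        Xtr = np.ascontiguousarray(Xtr)
        ranking = rfe_removal_order(Xtr, ytr, float(C), _RFE_TOL, _SMO_MAX_ITER)[::-1]
        ranking = np.ascontiguousarray(ranking)
        folds = _stratified_folds(ytr, inner_folds, rng)
        total_errs = np.zeros(p, dtype=np.int64)
        for f in range(inner_folds):
            val = folds == f
            if not val.any() or val.all():
                continue
            total_errs += nested_subset_errors(
                np.ascontiguousarray(Xtr[~val]),
                np.ascontiguousarray(ytr[~val]),
                np.ascontiguousarray(Xtr[val]),
                np.ascontiguousarray(ytr[val]),
                ranking,
                float(C),
                _RFE_TOL,
                _SMO_MAX_ITER,
            )
        k_star = int(np.argmin(total_errs)) + 1  # smallest size on ties
        counts[ranking[:k_star]] += 1
    med = int(np.sort(counts)[(p - 1) // 2])  # lower median
    threshold = med + 1
    selected = np.flatnonzero(counts >= threshold)
    if selected.size == 0:
        raise EmptySelectionError(
            "median + 1 rule selected no variable (all counts at the median)"
        )
    # final ranking: by selection frequency, ties by variable index
    final_ranking = np.lexsort((np.arange(p), -counts))
    return SelectionResult(
        ranking=final_ranking,
        counts=counts,
        threshold=threshold,
        selected=selected,
        n_folds=n,
        variable_names=variable_names,
    )
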