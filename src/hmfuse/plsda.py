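"""NIPALS partial least squares, binary PLS-DA and multi-class PLS2-DA.

The discriminant model is the linear regression y = Xb + r fitted by
NIPALS: class membership is coded -1/+1 (binary) or one-hot (multi-class),
predictors and response are autoscaled on the training rows, and the
regression coefficients b = W (P'W)^{-1} Q' express the relative importance
of each variable.  The number of latent variables is chosen at the minimum
of the leave-one-out RMSECV curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Scaler, autoscale_fit_tolerant

__all__ = [
    "PLSModel",
    "PLSDAClassifier",
    "RMSECVCurve",
    "pls_fit",
    "rmsecv_select_lv",
    "fit_binary_plsda",
    "regression_coefficients",
    "fit_pls2da",
    "PLS2DAModel",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


class RankError(ValueError):
    """Requested more latent variables than the predictor rank supports."""


@dataclass
class PLSModel:
    """NIPALS PLS model on the (internally) scaled scale.

    W: X-weights (unit norm), T: X-scores, P: X-loadings, Q: y-loadings,
    B: regression coefficients so that yhat_scaled = X_scaled @ B.
    """

    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    B: np.ndarray
    residuals: np.ndarray
    n_components: int
    x_scaler: Scaler | None = None
    y_scaler: Scaler | None = None
    y_variance_per_lv: np.ndarray | None = None

    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.x_scaler is not None:
            X = self.x_scaler.transform(X)
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict the response on the original (unscaled) y scale."""
        yhat = self._scale_x(X) @ self.B
        if self.y_scaler is not None:
            yhat = self.y_scaler.inverse_transform(yhat)
        return yhat

    def transform(self, X: np.ndarray) -> np.ndarray:
        """X-scores of new samples: T = X_scaled @ W (P'W)^{-1}."""
        R = self.W @ np.linalg.inv(self.P.T @ self.W)
        return self._scale_x(X) @ R


@dataclass
class RMSECVCurve:
    rmsecv: np.ndarray  # entry a-1 is the LOO RMSE with a latent variables
    chosen_a: int  # argmin, smallest a on ties


def _nipals(X: np.ndarray, Y: np.ndarray, n_components: int):
    """Core NIPALS loop on pre-scaled matrices. Returns W, T, P, Q."""
    X = X.copy()
    Y = Y.copy()
    n, p = X.shape
    m = Y.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((m, n_components))
    for a in range(n_components):
        if m == 1:
            w = X.T @ Y[:, 0]
            nw = np.linalg.norm(w)
            if nw < 1e-13:
                raise RankError(
                    f"X exhausted after {a} components; cannot extract {n_components}"
                )
            w = w / nw
            t = X @ w
            tt = t @ t
            if tt < 1e-13:
                raise RankError(
                    f"X exhausted after {a} components; cannot extract {n_components}"
                )
            q = np.array([Y[:, 0] @ t / tt])
        else:
            u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
            t = np.zeros(n)
            for _ in range(_NIPALS_MAX_ITER):
                w = X.T @ u
                nw = np.linalg.norm(w)
                if nw < 1e-13:
                    raise RankError(
                        f"X exhausted after {a} components; cannot extract "
                        f"{n_components}"
                    )
                w = w / nw
                t_new = X @ w
                q = Y.T @ t_new / (t_new @ t_new)
                u = Y @ q / (q @ q)
                if np.linalg.norm(t_new - t) <= _NIPALS_TOL * max(
                    np.linalg.norm(t_new), 1e-300
                ):
                    t = t_new
                    break
                t = t_new
            tt = t @ t
            if tt < 1e-13:
                raise RankError(
                    f"X exhausted after {a} components; cannot extract {n_components}"
                )
        p_load = X.T @ t / tt
        X -= np.outer(t, p_load)
        if m > 1:
            Y = Y - np.outer(t, q)
        W[:, a] = w
        T[:, a] = t
        P[:, a] = p_load
        Q[:, a] = q
    return W, T, P, Q


def _coefficients(W, P, Q, a: int) -> np.ndarray:
    """B_a = W_a (P_a' W_a)^{-1} Q_a' using the first a components."""
    Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)


def pls_fit(X, Y, n_components: int, scale: bool = False) -> PLSModel:
    """Fit a PLS model by NIPALS.

    With ``scale=True`` X and Y are autoscaled internally and predictions
    are returned on the original scale.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x_scaler = y_scaler = None
    Xs, Ys = X, Y
    if scale:
        Xs, x_scaler = autoscale_fit_tolerant(X)
        Ys, y_scaler = autoscale_fit_tolerant(Y)
    rank = np.linalg.matrix_rank(Xs - Xs.mean(axis=0) if not scale else Xs)
    if n_components > rank:
        raise RankError(f"n_components={n_components} exceeds rank(X)={rank}")
    W, T, P, Q = _nipals(Xs, Ys, n_components)
    B = _coefficients(W, P, Q, n_components)
    resid = Ys - Xs @ B
    ssy = float(np.sum(Ys**2))
    yvar = np.array(
        [
            float(Q[:, a] @ Q[:, a]) * float(T[:, a] @ T[:, a]) / ssy if ssy > 0 else 0.0
            for a in range(n_components)
        ]
    )
    return PLSModel(
        W=W, T=T, P=P, Q=Q, B=B, residuals=resid, n_components=n_components,
        x_scaler=x_scaler, y_scaler=y_scaler, y_variance_per_lv=yvar,
    )


def rmsecv_select_lv(X, y, max_a: int) -> RMSECVCurve:
    """Leave-one-out RMSECV over 1..max_a latent variables.

    Each fold autoscales on its own training rows, refits, and predicts the
    left-out sample on the original y scale.  If a fold's rank is exhausted
    before max_a, the last extractable component's prediction is carried
    forward for the remaining sizes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if max_a < 1:
        raise ValueError("max_a must be >= 1")
    if n < 3:
        raise ValueError("need at least 3 samples for RMSECV")
    sq = np.zeros(max_a)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, xs = autoscale_fit_tolerant(X[mask])
        ytr, ys = autoscale_fit_tolerant(y[mask, None])
        a_max_fold = min(max_a, n - 2, X.shape[1])
        try:
            W, T, P, Q = _nipals(Xtr, ytr, a_max_fold)
        except RankError:
            # retry with the largest extractable count
            a_try = a_max_fold
            while a_try > 1:
                a_try -= 1
                try:
                    W, T, P, Q = _nipals(Xtr, ytr, a_try)
                    break
                except RankError:
                    continue
            else:
                raise
            a_max_fold = a_try
        xi = xs.transform(X[i : i + 1])
        prev = np.nan
        for a in range(1, max_a + 1):
            aa = min(a, a_max_fold)
            if aa == a or np.isnan(prev):
                B = _coefficients(W, P, Q, aa)
                pred = float(ys.inverse_transform(xi @ B)[0, 0])
                prev = pred
            sq[a - 1] += (y[i] - prev) ** 2
    curve = np.sqrt(sq / n)
    chosen = int(np.argmin(curve)) + 1
    return RMSECVCurve(rmsecv=curve, chosen_a=chosen)


@dataclass
class PLSDAClassifier:
    """Binary PLS-DA: classes coded -1 (class_a) and +1 (class_b)."""

    class_a: str
    class_b: str
    model: PLSModel
    n_components: int
    subset: np.ndarray | None = None  # variable indices used, None = all
    variable_names: list | None = None
    rmsecv: RMSECVCurve | None = None
    training_accuracy: float | None = None
    test_accuracy_: float | None = None

    def _take(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.subset is not None:
            X = X[:, self.subset]
        return X

    def decision_function(self, X) -> np.ndarray:
        """Predicted coded y; 0 is the class boundary."""
        return self.model.predict(self._take(X))[:, 0]

    def predict(self, X) -> np.ndarray:
        s = self.decision_function(X)
        # boundary ties resolve to class_b
        return np.where(s >= 0.0, self.class_b, self.class_a)

    def scores(self, X) -> np.ndarray:
        """Latent-variable scores of (possibly out-of-model) samples."""
        return self.model.transform(self._take(X))

    def validate(self, X, labels) -> float:
        labels = np.asarray(labels)
        pred = self.predict(X)
        acc = float(np.mean(pred == labels))
        self.test_accuracy_ = acc
        return acc


def _code_binary(labels, class_a: str, class_b: str) -> np.ndarray:
    labels = np.asarray(labels)
    present = set(np.unique(labels).tolist())
    if class_a not in present or class_b not in present:
        raise ValueError(f"classes {class_a!r} and {class_b!r} must both be present")
    y = np.where(labels == class_b, 1.0, -1.0)
    return y


def fit_binary_plsda(
    X,
    labels,
    class_a: str,
    class_b: str,
    n_components: int | None = None,
    max_components: int = 10,
    subset=None,
    variable_names: list | None = None,
) -> PLSDAClassifier:
    """Fit a two-class PLS-DA model on the rows belonging to the two classes.

    X and the coded response are autoscaled on those training rows; when
    ``n_components`` is None the latent-variable count is taken at the
    RMSECV minimum.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    keep = (labels == class_a) | (labels == class_b)
    Xp, lp = X[keep], labels[keep]
    y = _code_binary(lp, class_a, class_b)
    sub = None
    if subset is not None:
        sub = np.asarray(subset, dtype=int)
        Xp = Xp[:, sub]
    curve = None
    if n_components is None:
        max_a = min(max_components, Xp.shape[0] - 2, Xp.shape[1])
        curve = rmsecv_select_lv(Xp, y, max_a)
        n_components = curve.chosen_a
    model = pls_fit(Xp, y, n_components, scale=True)
    clf = PLSDAClassifier(
        class_a=class_a,
        class_b=class_b,
        model=model,
        n_components=n_components,
        subset=sub,
        variable_names=variable_names,
        rmsecv=curve,
    )
    pred = clf.predict(X[keep])
    clf.training_accuracy = float(np.mean(pred == lp))
    return clf


def regression_coefficients(classifier: PLSDAClassifier):
    """Regression coefficients b on the scaled scale, named per variable.

    Positive b means a higher value pushes the prediction toward class_b.
    """
    model = getattr(classifier, "model", None)
    if model is None or getattr(model, "B", None) is None:
        raise ValueError("classifier is not fitted")
    b = model.B[:, 0]
    names = classifier.variable_names
    if names is None:
        if classifier.subset is not None:
            names = [int(j) for j in classifier.subset]
        else:
            names = list(range(b.size))
    import pandas as pd

    return pd.Series(b, index=names, name="b")


@dataclass
class PLS2DAModel:
    """Multi-class PLS-DA with a one-hot response matrix."""

    classes: list
    model: PLSModel
    n_components: int
    training_accuracy: float | None = None

    def predict(self, X) -> np.ndarray:
        Yhat = self.model.predict(X)
        idx = np.argmax(Yhat, axis=1)
        return np.asarray(self.classes, dtype=object)[idx]


def fit_pls2da(
    X, labels, n_components: int | None = None, max_components: int = 10
) -> PLS2DAModel:
    """Fit PLS2-DA: one-hot response, prediction by largest predicted column."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 3:
        raise ValueError("fewer than 3 classes: use fit_binary_plsda instead")
    Y = np.stack([(labels == c).astype(float) for c in classes], axis=1)
    if n_components is None:
        # RMSECV over all response columns
        max_a = min(max_components, X.shape[0] - 2, X.shape[1])
        best, best_a = np.inf, 1
        for a in range(1, max_a + 1):
            sq = 0.0
            n = X.shape[0]
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                try:
                    m = pls_fit(X[mask], Y[mask], a, scale=True)
                except RankError:
                    sq = np.inf
                    break
                sq += float(np.sum((Y[i] - m.predict(X[i : i + 1])[0]) ** 2))
            rm = np.sqrt(sq / (n * len(classes)))
            if rm < best - 1e-12:
                best, best_a = rm, a
        n_components = best_a
    model = pls_fit(X, Y, n_components, scale=True)
    out = PLS2DAModel(classes=classes, model=model, n_components=n_components)
    out.training_accuracy = float(np.mean(out.predict(X) == labels))
    return out
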