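"""Compiled kernels for the soft-margin linear SVM dual and RFE loops.

The dual problem

    min_a  1/2 a' Q a - e' a,   Q_ij = y_i y_j K_ij
    s.t.   0 <= a_i <= C,  sum_i a_i y_i = 0

is solved by sequential minimal optimization with maximal-violating-pair
working-set selection.  The kernels below operate on precomputed Gram
matrices so that recursive feature elimination can downdate K by a
rank-one term per removed variable instead of recomputing it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["smo_solve", "rfe_removal_order", "nested_subset_errors"]


@njit(cache=True)
def smo_solve(K, y, C, tol, max_iter):
    """Solve the SVM dual for Gram matrix K and labels y in {-1,+1}.

    Returns (alpha, bias, n_iter).  bias follows the decision function
    f(x) = w.x + bias.
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    # grad_t = (Q alpha)_t - 1
    grad = -np.ones(n)
    eps_b = 1e-12
    it = 0
    gmax = 0.0
    gmin = 0.0
    while it < max_iter:
        i = -1
        j = -1
        gmax = -1e300
        gmin = 1e300
        for t in range(n):
            yg = -y[t] * grad[t]
            up = (y[t] > 0.0 and alpha[t] < C - eps_b) or (
                y[t] < 0.0 and alpha[t] > eps_b
            )
            low = (y[t] < 0.0 and alpha[t] < C - eps_b) or (
                y[t] > 0.0 and alpha[t] > eps_b
            )
            if up and yg > gmax:
                gmax = yg
                i = t
            if low and yg < gmin:
                gmin = yg
                j = t
        if i < 0 or j < 0 or gmax - gmin < tol:
            break
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if quad < 1e-12:
            quad = 1e-12
        # E_t = u_t - y_t = y_t * grad_t
        delta = y[j] * (y[i] * grad[i] - y[j] * grad[j]) / quad
        aj_old = alpha[j]
        ai_old = alpha[i]
        aj = aj_old + delta
        s = y[i] * y[j]
        if s < 0.0:
            L = max(0.0, aj_old - ai_old)
            H = min(C, C + aj_old - ai_old)
        else:
            L = max(0.0, ai_old + aj_old - C)
            H = min(C, ai_old + aj_old)
        if aj > H:
            aj = H
        elif aj < L:
            aj = L
        alpha[j] = aj
        alpha[i] = ai_old + s * (aj_old - aj)
        dai = (alpha[i] - ai_old) * y[i]
        daj = (aj - aj_old) * y[j]
        for t in range(n):
            grad[t] += y[t] * (dai * K[t, i] + daj * K[t, j])
        it += 1
    # bias: average of y_t - u_t over free support vectors, else the
    # midpoint of the KKT feasibility interval [gmin, gmax].
    nb = 0
    bsum = 0.0
    for t in range(n):
        if alpha[t] > eps_b and alpha[t] < C - eps_b:
            # u_t = y_t * (grad_t + 1)
            bsum += y[t] - y[t] * (grad[t] + 1.0)
            nb += 1
    if nb > 0:
        bias = bsum / nb
    else:
        bias = 0.5 * (gmax + gmin)
    return alpha, bias, it


@njit(cache=True)
def rfe_removal_order(X, y, C, tol, max_iter):
    """Backward elimination: remove argmin w_j^2 each round.

    Ties in w_j^2 are broken by removing the highest variable index.
    Returns the removal order (first removed first).
    """
    n, p = X.shape
    K = X @ np.ascontiguousarray(X.T)
    active = np.ones(p, np.bool_)
    order = np.empty(p, np.int64)
    for step in range(p):
        nact = p - step
        if nact == 1:
            for j in range(p):
                if active[j]:
                    order[step] = j
            break
        alpha, bias, _ = smo_solve(K, y, C, tol, max_iter)
        best_j = -1
        best_w2 = 1e300
        for j in range(p):
            if not active[j]:
                continue
            wj = 0.0
            for i in range(n):
                wj += alpha[i] * y[i] * X[i, j]
            w2 = wj * wj
            if w2 <= best_w2:  # ascending scan: ties keep highest index
                best_w2 = w2
                best_j = j
        order[step] = best_j
        active[best_j] = False
        for a in range(n):
            xa = X[a, best_j]
            for b in range(n):
                K[a, b] -= xa * X[b, best_j]
    return order


@njit(cache=True)
def nested_subset_errors(Xtr, ytr, Xval, yval, ranking, C, tol, max_iter):
    """Misclassification counts of SVMs on the nested top-k subsets.

    ranking lists variables best-first; entry k of the result is the
    number of validation errors of an SVM trained on ranking[:k+1].
    Ties on the decision boundary go to the +1 class.
    """
    n, p = Xtr.shape[0], ranking.size
    nval = Xval.shape[0]
    K = np.zeros((n, n))
    errs = np.empty(p, np.int64)
    w = np.zeros(p)
    for k in range(p):
        j = ranking[k]
        for a in range(n):
            xa = Xtr[a, j]
            for b in range(n):
                K[a, b] += xa * Xtr[b, j]
        alpha, bias, _ = smo_solve(K, ytr, C, tol, max_iter)
        for kk in range(k + 1):
            jj = ranking[kk]
            wjj = 0.0
            for i in range(n):
                wjj += alpha[i] * ytr[i] * Xtr[i, jj]
            w[kk] = wjj
        nerr = 0
        for v in range(nval):
            s = bias
            for kk in range(k + 1):
                s += w[kk] * Xval[v, ranking[kk]]
            pred = 1.0 if s > 0.0 else -1.0
            if s == 0.0:
                pred = 1.0
            if pred != yval[v]:
                nerr += 1
        errs[k] = nerr
    return errs
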