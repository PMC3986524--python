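"""Independent straight-line reimplementation of the scored pipeline.

Used as the oracle for cross-validated-score equivalence tests: no shared
code with cvperm's estimator/scoring modules, different numerical routes
(np.corrcoef, heapq-free sorting, explicit normal equations), same
contract: residualize -> shuffle-split -> [collinearity filter ->
F-score top-K -> ridge] -> mean of test RSS ratios.
"""

import numpy as np
from sklearn.model_selection import ShuffleSplit


def oracle_residualize(y, Z):
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta


def oracle_filter_collinear(X, tol=1e-6):
    kept = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.std(col) == 0.0:
            continue
        dup = False
        for i in kept:
            r = np.corrcoef(col, X[:, i])[0, 1]
            if abs(r) > 1.0 - tol:
                dup = True
                break
        if not dup:
            kept.append(j)
    return kept


def oracle_f_scores(X, y):
    n = len(y)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        if np.std(X[:, j]) == 0.0:
            scores[j] = 0.0
            continue
        r = float(np.corrcoef(X[:, j], y)[0, 1])
        r2 = min(r * r, 1.0)
        scores[j] = np.inf if r2 == 1.0 else r2 * (n - 2) / (1.0 - r2)
    return scores


def oracle_top_k(scores, k):
    # sort by (-score, index): ties to the lowest index
    order = sorted(range(len(scores)), key=lambda j: (-scores[j], j))
    return sorted(order[:k])


def oracle_ridge_fit(X, y, alpha):
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    w = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(X.shape[1]), Xc.T @ yc)
    return w, ym - xm @ w


def oracle_cv_r2(y_resid, X, k, alpha, n_iter, test_fraction, seed, tol=1e-6):
    """CV-R^2 of filter -> F-score top-K -> ridge, on a residualized target."""
    n = len(y_resid)
    n_test = int(round(test_fraction * n))
    ss = ShuffleSplit(n_splits=n_iter, test_size=n_test, random_state=seed)
    ratios = []
    for train, test in ss.split(np.zeros((n, 1))):
        kept = oracle_filter_collinear(X[train], tol)
        Xk = X[:, kept]
        scores = oracle_f_scores(Xk[train], y_resid[train])
        sel = oracle_top_k(scores, k)
        Xs = Xk[:, sel]
        w, c = oracle_ridge_fit(Xs[train], y_resid[train], alpha)
        pred = Xs[test] @ w + c
        err = y_resid[test] - pred
        ratios.append(float(err @ err) / float(y_resid[test] @ y_resid[test]))
    return 1.0 - float(np.mean(ratios))
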