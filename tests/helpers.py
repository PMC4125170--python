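"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and self-contained: exhaustive split
enumeration for gain-ratio trees, pairwise concordance for AUC, a plain
IRLS Newton solver for logistic regression.  These never call into the
package code paths they are used to check.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-12


def _entropy(counts) -> float:
    n = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * np.log2(p)
    return h


def brute_force_best_split(X, y, min_leaf: int = 1):
    """Exhaustive gain-ratio maximizer over all variables and midpoints.

    ``X`` is a DataFrame, ``y`` a 0/1 array.  Tie rule: highest gain ratio,
    then variable name order, then smaller threshold (all within 1e-12).
    Returns (variable, threshold, ratio) or None.
    """
    n = len(y)
    h_parent = _entropy([n - int(sum(y)), int(sum(y))])
    best = None
    for var in sorted(X.columns):
        values = sorted(set(float(v) for v in X[var]))
        for lo, hi in zip(values, values[1:]):
            thr = (lo + hi) / 2.0
            left = np.asarray(X[var], dtype=float) <= thr
            nl, nr = int(left.sum()), int((~left).sum())
            if nl < min_leaf or nr < min_leaf:
                continue
            yl = y[left]
            yr = y[~left]
            h_children = (nl * _entropy([nl - int(yl.sum()), int(yl.sum())])
                          + nr * _entropy([nr - int(yr.sum()), int(yr.sum())])) / n
            gain = h_parent - h_children
            if gain <= EPS:
                continue
            pl = nl / n
            split_info = -(pl * np.log2(pl) + (1 - pl) * np.log2(1 - pl))
            ratio = gain / split_info
            if best is None or ratio > best[2] + EPS:
                best = (var, thr, ratio)
            elif abs(ratio - best[2]) <= EPS:
                if (var, thr) < (best[0], best[1]) and var == best[0] and thr < best[1]:
                    best = (var, thr, ratio)
                # different variable at equal ratio: earlier name already won
    return best


def concordance_auc(scores, labels) -> float:
    """AUC as the exhaustive concordant-pair fraction (ties get 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = len(pos) * len(neg)
    c = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                c += 1.0
            elif sp == sn:
                c += 0.5
    return c / total


def irls_logistic(X, y, max_iter: int = 200, tol: float = 1e-12):
    """Plain Newton/IRLS maximum-likelihood logistic fit.

    ``X`` includes the intercept column.  Returns the coefficient vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta
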