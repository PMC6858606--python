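"""Numerical kernels: L1-penalized logistic path and LogitBoost stumps.

These are the inner loops of signature selection and evaluation; they are
jitted with numba so that stability selection (hundreds to thousands of
cross-validated path fits) and leave-one-out tuning of the boosted classifier
stay tractable on one CPU.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PCLIP = 1e-5
_ZCLIP = 4.0


@njit(cache=True)
def lasso_logistic_path(X, y, lambdas, max_outer=25, max_sweeps=100, tol=1e-6):
    """Coordinate-descent IRLS path for L1 logistic regression.

    X must be standardized (zero mean, unit variance per column); the
    intercept is unpenalized.  Returns (intercepts, coefs) along the
    decreasing `lambdas` path, warm-started.
    """
    n, p = X.shape
    nl = lambdas.shape[0]
    coefs = np.zeros((nl, p))
    intercepts = np.zeros(nl)
    beta = np.zeros(p)
    b0 = 0.0
    eta = np.zeros(n)
    for li in range(nl):
        lam = lambdas[li]
        for _outer in range(max_outer):
            # quadratic approximation at current (b0, beta)
            prob = 1.0 / (1.0 + np.exp(-eta))
            for i in range(n):
                if prob[i] < _PCLIP:
                    prob[i] = _PCLIP
                elif prob[i] > 1.0 - _PCLIP:
                    prob[i] = 1.0 - _PCLIP
            w = prob * (1.0 - prob)
            z = eta + (y - prob) / w
            r = z - eta  # working residual
            max_delta_outer = 0.0
            for _sweep in range(max_sweeps):
                max_delta = 0.0
                for j in range(p):
                    bj = beta[j]
                    # partial residual correlation
                    num = 0.0
                    den = 0.0
                    for i in range(n):
                        num += w[i] * X[i, j] * (r[i] + X[i, j] * bj)
                        den += w[i] * X[i, j] * X[i, j]
                    num /= n
                    den /= n
                    if den <= 0.0:
                        newb = 0.0
                    else:
                        if num > lam:
                            newb = (num - lam) / den
                        elif num < -lam:
                            newb = (num + lam) / den
                        else:
                            newb = 0.0
                    d = newb - bj
                    if d != 0.0:
                        beta[j] = newb
                        for i in range(n):
                            r[i] -= X[i, j] * d
                        if abs(d) > max_delta:
                            max_delta = abs(d)
                # intercept (unpenalized)
                num = 0.0
                den = 0.0
                for i in range(n):
                    num += w[i] * (r[i] + b0)
                    den += w[i]
                newb0 = num / den
                d0 = newb0 - b0
                if d0 != 0.0:
                    b0 = newb0
                    for i in range(n):
                        r[i] -= d0
                if abs(d0) > max_delta:
                    max_delta = abs(d0)
                if max_delta > max_delta_outer:
                    max_delta_outer = max_delta
                if max_delta < tol:
                    break
            for i in range(n):
                eta[i] = z[i] - r[i]
            if max_delta_outer < tol:
                break
        intercepts[li] = b0
        coefs[li] = beta
    return intercepts, coefs


@njit(cache=True)
def logitboost_fit(X, y, n_iters):
    """LogitBoost with single-feature threshold stumps.

    y in {0,1}; maintains F(x) with p = 1/(1+exp(-2F)); each iteration fits
    the best weighted-least-squares stump to the clipped working response and
    advances F by half the stump.  Ties in stump error resolve to the lowest
    feature index, then the lowest threshold (scan order + strict inequality).
    Returns (features, thresholds, left_values, right_values).
    """
    n, p = X.shape
    order = np.empty((p, n), dtype=np.int64)
    for j in range(p):
        order[j] = np.argsort(X[:, j], kind="mergesort")
    F = np.zeros(n)
    feats = np.empty(n_iters, dtype=np.int64)
    thrs = np.empty(n_iters)
    lefts = np.empty(n_iters)
    rights = np.empty(n_iters)
    for it in range(n_iters):
        prob = 1.0 / (1.0 + np.exp(-2.0 * F))
        for i in range(n):
            if prob[i] < _PCLIP:
                prob[i] = _PCLIP
            elif prob[i] > 1.0 - _PCLIP:
                prob[i] = 1.0 - _PCLIP
        w = prob * (1.0 - prob)
        z = (y - prob) / w
        for i in range(n):
            if z[i] > _ZCLIP:
                z[i] = _ZCLIP
            elif z[i] < -_ZCLIP:
                z[i] = -_ZCLIP
        total_w = 0.0
        total_wz = 0.0
        total_wz2 = 0.0
        for i in range(n):
            total_w += w[i]
            total_wz += w[i] * z[i]
            total_wz2 += w[i] * z[i] * z[i]
        const_fit = total_wz / total_w
        best_err = np.inf
        best_f = -1
        best_thr = 0.0
        best_l = const_fit
        best_r = const_fit
        for j in range(p):
            wl = 0.0
            wzl = 0.0
            idx = order[j]
            for ii in range(n - 1):
                i = idx[ii]
                wl += w[i]
                wzl += w[i] * z[i]
                xcur = X[i, j]
                xnext = X[idx[ii + 1], j]
                if xcur == xnext:
                    continue
                wr = total_w - wl
                wzr = total_wz - wzl
                if wl <= 0.0 or wr <= 0.0:
                    continue
                err = total_wz2 - wzl * wzl / wl - wzr * wzr / wr
                if err < best_err - 1e-12:
                    best_err = err
                    best_f = j
                    best_thr = 0.5 * (xcur + xnext)
                    best_l = wzl / wl
                    best_r = wzr / wr
        if best_f < 0:
            # all features constant under current weights: constant stump
            best_f = 0
            best_thr = np.inf
            best_l = const_fit
            best_r = const_fit
        feats[it] = best_f
        thrs[it] = best_thr
        lefts[it] = best_l
        rights[it] = best_r
        for i in range(n):
            if X[i, best_f] <= best_thr:
                F[i] += 0.5 * best_l
            else:
                F[i] += 0.5 * best_r
    return feats, thrs, lefts, rights


@njit(cache=True)
def logitboost_decision(X, feats, thrs, lefts, rights, n_iters):
    """F(x) after `n_iters` boosting steps."""
    n = X.shape[0]
    F = np.zeros(n)
    for it in range(n_iters):
        j = feats[it]
        for i in range(n):
            if X[i, j] <= thrs[it]:
                F[i] += 0.5 * lefts[it]
            else:
                F[i] += 0.5 * rights[it]
    return F


@njit(cache=True)
def loocv_iteration_accuracy(X, y, grid):
    """Leave-one-out accuracy of LogitBoost at each iteration count in `grid`.

    One fit per left-out sample (at max(grid) iterations); the held-out
    decision value is evaluated at every grid point from the staged model.
    """
    n = X.shape[0]
    max_iters = grid[-1]
    ngrid = grid.shape[0]
    correct = np.zeros(ngrid)
    Xtr = np.empty((n - 1, X.shape[1]))
    ytr = np.empty(n - 1)
    for held in range(n):
        k = 0
        for i in range(n):
            if i != held:
                Xtr[k] = X[i]
                ytr[k] = y[i]
                k += 1
        feats, thrs, lefts, rights = logitboost_fit(Xtr, ytr, max_iters)
        Fh = 0.0
        g = 0
        for it in range(max_iters):
            if X[held, feats[it]] <= thrs[it]:
                Fh += 0.5 * lefts[it]
            else:
                Fh += 0.5 * rights[it]
            if it + 1 == grid[g]:
                pred = 1.0 if Fh > 0.0 else 0.0
                if pred == y[held]:
                    correct[g] += 1.0
                g += 1
                if g >= ngrid:
                    break
    return correct / n
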