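"""Independent oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way (explicit
loops, exhaustive enumeration, textbook IRLS) and stays independent of the
code paths it checks.
"""

from __future__ import annotations

import numpy as np


def knn_oracle(points: np.ndarray, k: int) -> list[list[int]]:
    """Exhaustive neighbour search: sort all rows by (distance, index)."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points.reshape(-1, 1)
    n = points.shape[0]
    sets = []
    for i in range(n):
        ranked = sorted(
            (float(np.sum((points[i] - points[j]) ** 2)), j)
            for j in range(n) if j != i
        )
        sets.append(sorted([i] + [j for _, j in ranked[: k - 1]]))
    return sets


def irls_logistic(X: np.ndarray, y: np.ndarray, maxiter: int = 200,
                  tol: float = 1e-12) -> np.ndarray:
    """Textbook iteratively reweighted least squares for logistic MLE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        z = eta + (y - p) / np.maximum(W, 1e-12)
        beta_new = np.linalg.solve((X * W[:, None]).T @ X, (X * W[:, None]).T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


def risky_oracle(X_or: np.ndarray, X_an: np.ndarray, w1: float,
                 rmd2: np.ndarray) -> np.ndarray:
    """Row-by-row, dimension-by-dimension interval membership check."""
    n, p = X_or.shape
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        inside = True
        for j in range(p):
            lo = X_or[i, j] - w1 * rmd2[i]
            hi = X_or[i, j] + w1 * rmd2[i]
            if not (lo <= X_an[i, j] <= hi):
                inside = False
        flags[i] = inside
    return flags


def unsafe_oracle(X_an: np.ndarray, w2: float, m: int,
                  risky: np.ndarray) -> np.ndarray:
    """Count close anonymised neighbours of each risky row, one by one."""
    n = X_an.shape[0]
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        if not risky[i]:
            continue
        close = 0
        for j in range(n):
            if j != i and np.sqrt(np.sum((X_an[i] - X_an[j]) ** 2)) <= w2:
                close += 1
        flags[i] = close < m
    return flags


def sample_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, sd (n-1), skewness and excess kurtosis (moment estimators)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    sd = x.std(ddof=1)
    z = (x - mu) / x.std(ddof=0)
    return float(mu), float(sd), float(np.mean(z ** 3)), float(np.mean(z ** 4) - 3)
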