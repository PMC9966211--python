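"""Independent oracles used by the test suite.

These deliberately avoid the package's own recursions: the smoother oracle
solves the penalised-least-squares normal equations directly as a dense
linear system, and the filter oracle is a plain textbook matrix-form Kalman
recursion.
"""

from __future__ import annotations

import numpy as np


def second_difference_matrix(n: int) -> np.ndarray:
    """(n-2) x n matrix D with rows (1, -2, 1)."""
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i] = 1.0
        D[i, i + 1] = -2.0
        D[i, i + 2] = 1.0
    return D


def penalized_ls_trend(y: np.ndarray, nvr: float) -> np.ndarray:
    """Minimiser of ||y - T||^2 + (1/nvr) ||D T||^2 (dense solve)."""
    y = np.asarray(y, float)
    n = len(y)
    D = second_difference_matrix(n)
    A = np.eye(n) + (1.0 / nvr) * D.T @ D
    return np.linalg.solve(A, y)


def penalized_ls_variance(y: np.ndarray, nvr: float, r: float) -> np.ndarray:
    """Posterior variance of the trend: r * diag((I + D'D/nvr)^-1)."""
    n = len(y)
    D = second_difference_matrix(n)
    A = np.eye(n) + (1.0 / nvr) * D.T @ D
    return r * np.diag(np.linalg.inv(A))


def textbook_irw_filter(y: np.ndarray, nvr: float):
    """Matrix-form Kalman recursion for the IRW model, exact diffuse start.

    State [level, slope], slope a random walk whose increment also enters
    the level; observation = level + noise (unit variance).
    """
    y = np.asarray(y, float)
    n = len(y)
    F = np.array([[1.0, 1.0], [0.0, 1.0]])
    G = np.array([[1.0], [1.0]])
    H = np.array([[1.0, 0.0]])
    Q = nvr * (G @ G.T)
    a = np.array([y[1], y[1] - y[0]])
    P = np.array([[1.0, 1.0], [1.0, 2.0]])
    states = np.zeros((n, 2))
    covs = np.zeros((n, 2, 2))
    states[0] = (y[0], a[1])
    covs[0] = [[1.0, 0.0], [0.0, P[1, 1]]]
    states[1], covs[1] = a, P
    for t in range(2, n):
        a = F @ a
        P = F @ P @ F.T + Q
        S = (H @ P @ H.T).item() + 1.0
        K = (P @ H.T / S).ravel()
        v = y[t] - (H @ a).item()
        a = a + K * v
        P = (np.eye(2) - np.outer(K, H.ravel())) @ P
        states[t], covs[t] = a, P
    return states, covs


def ols_line(y: np.ndarray) -> np.ndarray:
    """Ordinary least-squares straight line through (0..n-1, y)."""
    t = np.arange(len(y), dtype=float)
    b, a = np.polyfit(t, np.asarray(y, float), 1)
    return a + b * t
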