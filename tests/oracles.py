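"""Independent reference implementations used only to cross-check nirscal.

The PLS1 oracle here is a deliberately different computational route from
the package's scaling-chain implementation: textbook NIPALS with explicit
deflation and the closed-form coefficient matrix B = W (PᵀW)⁻¹ q.
"""

from __future__ import annotations

import numpy as np


def nipals_pls1_coefficients(X: np.ndarray, y: np.ndarray, n_components: int):
    """Plain PLS1 regression coefficients via W (PᵀW)⁻¹ q.

    Returns (b, intercept) such that y ≈ intercept + X @ b.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    E = X - x_mean
    f = y - y_mean
    Ws, Ps, qs = [], [], []
    for _ in range(n_components):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w = w / nw
        t = E @ w
        tt = t @ t
        p = E.T @ t / tt
        q = t @ f / tt
        E = E - np.outer(t, p)
        f = f - q * t
        Ws.append(w)
        Ps.append(p)
        qs.append(q)
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.asarray(qs)
    b = W @ np.linalg.solve(P.T @ W, q)
    return b, float(y_mean - x_mean @ b)


def nipals_pls1_predict(X_train, y_train, X_test, n_components: int) -> np.ndarray:
    b, b0 = nipals_pls1_coefficients(X_train, y_train, n_components)
    return b0 + np.asarray(X_test, dtype=float) @ b


def loo_secv(X: np.ndarray, y: np.ndarray, n_components: int) -> float:
    """Brute-force leave-one-out SECV with the plain PLS1 oracle."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    errors = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pred = nipals_pls1_predict(X[mask], y[mask], X[i : i + 1], n_components)
        errors[i] = y[i] - pred[0]
    return float(np.sqrt((errors @ errors) / n))
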