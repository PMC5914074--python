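"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written down a different path from the
package implementation: the L1 problems are solved as smooth bound-constrained
programs over the positive/negative parts (theta = p - q, p, q >= 0) with
L-BFGS-B on a column-equilibrated design, the kernel-L2 penalty uses an
explicit matrix inverse, and the structural oracles (Toeplitz rows, medians,
interpolation) are naive double loops.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def lasso_min(X: np.ndarray, y: np.ndarray, weight: float) -> tuple[float, np.ndarray]:
    """Optimal value and minimizer of ||y - X theta||^2 + weight ||theta||_1."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, m = X.shape
    s = np.linalg.norm(X, axis=0)
    s[s == 0] = 1.0
    Xs = X / s  # theta_j = phi_j / s_j, penalty weight_j = weight / s_j
    w = weight / s
    G = Xs.T @ Xs
    b = Xs.T @ y
    yy = y @ y

    def fun(z):
        p, q = z[:m], z[m:]
        phi = p - q
        val = yy - 2 * b @ phi + phi @ G @ phi + w @ (p + q)
        g = 2 * (G @ phi - b)
        return val, np.r_[g + w, -g + w]

    res = minimize(
        fun,
        np.zeros(2 * m),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * m),
        options=dict(maxiter=100_000, maxfun=500_000, ftol=1e-16, gtol=1e-12),
    )
    phi = res.x[:m] - res.x[m:]
    return float(res.fun), phi / s


def elastic_min(
    Y: np.ndarray,
    Phi: np.ndarray,
    P: np.ndarray,
    gamma: float,
    alpha: float,
) -> tuple[float, np.ndarray]:
    """Optimal value/minimizer of ||Y-Phi th||^2 + gamma th'P^{-1}th + alpha||th||_1.

    The quadratic penalty uses the explicit inverse of P (a route the package
    itself avoids), folded into an equivalent lasso via a symmetric square
    root, so this shares no code path with the implementation under test.
    """
    Pinv = np.linalg.inv(np.asarray(P, float))
    Pinv = (Pinv + Pinv.T) / 2.0
    w, V = np.linalg.eigh(Pinv)
    S = V @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ V.T  # symmetric sqrt of P^{-1}
    Xa = np.vstack([Phi, np.sqrt(gamma) * S])
    ya = np.r_[Y, np.zeros(Phi.shape[1])]
    val, theta = lasso_min(Xa, ya, alpha)
    return val, theta


def toeplitz_rows_bruteforce(u: np.ndarray, y: np.ndarray, m: int):
    """Row-by-row construction of the FIR regression by the index formulas."""
    M = len(u)
    N = M - m
    Y = np.empty(N)
    Phi = np.empty((N, m))
    for i in range(1, N + 1):        # 1-based row index
        Y[i - 1] = y[m + i - 1]      # y(m+i)
        for j in range(1, m + 1):    # 1-based lag index
            Phi[i - 1, j - 1] = u[m + i - j - 1]  # u(m+i-j)
    return Y, Phi

def sliding_median3(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(np.asarray(x, float))
    x = np.asarray(x, float)
    for i in range(len(x)):
        lo, hi = max(0, i - 1), min(len(x), i + 2)
        if i == 0 or i == len(x) - 1:
            out[i] = x[i]
        else:
            out[i] = np.median(x[lo:hi])
    return out


def piecewise_linear(tq: float, t: np.ndarray, v: np.ndarray) -> float:
    """Evaluate the piecewise-linear interpolant at a single probe point."""
    k = int(np.searchsorted(t, tq, side="right")) - 1
    if tq == t[-1]:
        return float(v[-1])
    frac = (tq - t[k]) / (t[k + 1] - t[k])
    return float(v[k] + frac * (v[k + 1] - v[k]))
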