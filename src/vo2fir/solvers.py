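"""Estimators for the FIR regression: LS, ridge, kernel-L2 and the kernelized elastic net.

Cost functions, all over theta in R^m with residual r = Y - Phi theta:

- least squares:        ||r||^2
- (weighted) ridge:     ||r||^2 + gamma theta' W theta
- kernel-L2:            ||r||^2 + gamma theta' P^{-1} theta
- kernel elastic net:   ||r||^2 + gamma theta' P^{-1} theta + alpha ||theta||_1

The elastic net is solved by reduction to a plain lasso on the augmented
system (see :mod:`vo2fir.regression`) with L1 weight alpha / sqrt(1+gamma),
followed by restoration.  The inner lasso uses coordinate descent with a
duality-gap stopping rule; the reported gap certifies optimality of the
returned iterate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoLars

from .kernels import KernelMatrix, upper_cholesky_of_inverse
from .regression import (
    AugmentedProblem,
    FIRModel,
    RegressionProblem,
    augment,
    restore,
)

__all__ = [
    "RegularizerWeights",
    "EstimationResult",
    "IllConditionedError",
    "solve_ls",
    "solve_ridge",
    "solve_kernel_l2",
    "solve_l1",
    "solve_kernel_elastic",
]

#: condition-number limit above which plain least squares is refused
COND_LIMIT = 1e12

#: |g_i| below this fraction of max|g| counts as a numerical zero when
#: reporting sparsity
ZERO_FRACTION = 1e-6


class IllConditionedError(np.linalg.LinAlgError):
    """The unregularized problem is too ill-conditioned to solve reliably."""


@dataclass(frozen=True)
class RegularizerWeights:
    """Penalty weights: `gamma` for the kernel-L2 term, `alpha` for the L1 term."""

    gamma: float = 0.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.alpha < 0:
            raise ValueError("regularizer weights must be nonnegative")


@dataclass(frozen=True, eq=False)
class EstimationResult:
    """Outcome of one estimator run.

    ``gap`` is the duality gap (L1 solvers) or the gradient norm of the
    quadratic objective (closed-form solvers) at the returned iterate;
    ``n_zero`` counts coefficients below the numerical-zero threshold and is
    only populated by the sparse estimator.
    """

    impulse_response: FIRModel
    objective: float
    status: str  # 'converged' | 'max_iter' | 'infeasible'
    gap: float
    n_iter: int
    n_zero: int | None = None

    @property
    def theta(self) -> np.ndarray:
        return self.impulse_response.g


def _quad_result(theta: np.ndarray, problem: RegressionProblem, objective: float,
                 grad_norm: float, ts: float = 1.0) -> EstimationResult:
    return EstimationResult(
        impulse_response=FIRModel(g=theta, ts=ts),
        objective=float(objective),
        status="converged",
        gap=float(grad_norm),
        n_iter=1,
    )


def solve_ls(problem: RegressionProblem, cond_limit: float = COND_LIMIT) -> EstimationResult:
    """Plain least squares; refuses ill-conditioned designs.

    With a single step input and heavy noise Phi'Phi is typically close to
    singular -- the very situation the regularized estimators exist for -- so
    a condition number above `cond_limit` raises instead of returning an
    unstable estimate.
    """
    cond = np.linalg.cond(problem.Phi)
    if not np.isfinite(cond) or cond > cond_limit:
        raise IllConditionedError(
            f"design matrix condition number {cond:.3e} exceeds {cond_limit:.1e}; "
            "use a regularized estimator"
        )
    theta, *_ = np.linalg.lstsq(problem.Phi, problem.Y, rcond=None)
    r = problem.Y - problem.Phi @ theta
    grad = 2.0 * problem.Phi.T @ r
    return _quad_result(theta, problem, r @ r, np.linalg.norm(grad))


def solve_ridge(
    problem: RegressionProblem, W: np.ndarray, gamma: float
) -> EstimationResult:
    """Weighted ridge regression: minimize ||Y - Phi theta||^2 + gamma theta' W theta."""
    if not gamma > 0:
        raise ValueError("ridge weight gamma must be positive")
    W = np.asarray(W, dtype=float)
    if W.shape != (problem.m, problem.m):
        raise ValueError(f"W shape {W.shape} does not match FIR order {problem.m}")
    A = problem.Phi.T @ problem.Phi + gamma * W
    b = problem.Phi.T @ problem.Y
    try:
        theta = linalg.solve(A, b, assume_a="sym")
    except linalg.LinAlgError as exc:
        raise IllConditionedError(f"regularized normal matrix is singular: {exc}")
    r = problem.Y - problem.Phi @ theta
    obj = r @ r + gamma * theta @ W @ theta
    grad = 2.0 * (A @ theta - b)
    return _quad_result(theta, problem, obj, np.linalg.norm(grad))


def solve_kernel_l2(
    problem: RegressionProblem,
    K: KernelMatrix,
    gamma: float,
    method: str = "auto",
) -> EstimationResult:
    """Kernel-weighted L2 estimator: minimize ||Y - Phi theta||^2 + gamma theta' P^{-1} theta.

    Two equivalent closed forms are available: the primal normal equations
    ``(Phi'Phi + gamma P^{-1}) theta = Phi'Y`` and the kernel-side formula
    ``theta = P Phi' (Phi P Phi' + gamma I)^{-1} Y``, preferred when N < m.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    if method not in ("auto", "primal", "dual"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = "dual" if problem.N < problem.m else "primal"
    P = K.P
    if method == "primal":
        R = upper_cholesky_of_inverse(K)
        A = problem.Phi.T @ problem.Phi + gamma * (R.T @ R)
        b = problem.Phi.T @ problem.Y
        theta = linalg.solve(A, b, assume_a="sym")
    else:
        G = problem.Phi @ P @ problem.Phi.T + gamma * np.eye(problem.N)
        theta = P @ problem.Phi.T @ linalg.solve(G, problem.Y, assume_a="sym")
    r = problem.Y - problem.Phi @ theta
    obj = r @ r + gamma * theta @ linalg.solve(P, theta, assume_a="sym")
    return _quad_result(theta, problem, obj, 0.0)


def _lasso_duality_gap(X: np.ndarray, y: np.ndarray, theta: np.ndarray,
                       weight: float) -> float:
    """Duality gap of min ||y - X theta||^2 + weight ||theta||_1 at theta."""
    r = y - X @ theta
    primal = r @ r + weight * np.abs(theta).sum()
    corr = np.abs(2.0 * X.T @ r).max() if theta.size else 0.0
    scale = 1.0 if corr <= weight or corr == 0.0 else weight / corr
    nu = 2.0 * scale * r
    dual = nu @ y - nu @ nu / 4.0
    return float(max(primal - dual, 0.0))


def solve_l1(
    aug: AugmentedProblem,
    weight: float,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> EstimationResult:
    """L1-penalized least squares on the augmented system.

    Minimizes ``||Ystar - Phistar theta*||^2 + weight ||theta*||_1`` by the
    LARS homotopy (exact piecewise-linear solution path, deterministic and
    robust to the severe column-scale disparity the kernel-penalty rows
    introduce), certified by the duality gap of the unscaled objective at the
    returned point.  If the relative gap exceeds `tol`, the solution is
    refined by cyclic coordinate descent and the better iterate is kept;
    failure to certify within `max_iter` returns status ``'max_iter'`` with
    the best iterate (caller decides).  ``weight = 0`` falls back to plain
    least squares.
    """
    if weight < 0:
        raise ValueError("L1 weight must be nonnegative")
    if not tol > 0:
        raise ValueError("tol must be positive")
    X, y = aug.Phistar, aug.Ystar
    n, m = X.shape

    def _objective(th: np.ndarray) -> float:
        r = y - X @ th
        return float(r @ r + weight * np.abs(th).sum())

    if weight == 0.0:
        theta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return EstimationResult(
            impulse_response=FIRModel(g=theta),
            objective=_objective(theta),
            status="converged",
            gap=0.0,
            n_iter=1,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lars = LassoLars(
            alpha=weight / (2.0 * n),
            fit_intercept=False,
            max_iter=max(500, 8 * m),
        )
        lars.fit(X, y)
    theta = np.asarray(lars.coef_, dtype=float)
    n_iter = int(np.atleast_1d(lars.n_iter_)[0])
    obj = _objective(theta)
    gap = _lasso_duality_gap(X, y, theta, weight)
    if gap > tol * max(obj, 1.0):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            cd = Lasso(
                alpha=weight / (2.0 * n),
                fit_intercept=False,
                tol=tol,
                max_iter=max_iter,
            )
            cd.fit(X, y)
        theta_cd = np.asarray(cd.coef_, dtype=float)
        n_iter += int(np.max(cd.n_iter_))
        if _objective(theta_cd) < obj:
            theta = theta_cd
            obj = _objective(theta)
            gap = _lasso_duality_gap(X, y, theta, weight)
    status = "converged" if gap <= tol * max(obj, 1.0) else "max_iter"
    return EstimationResult(
        impulse_response=FIRModel(g=theta),
        objective=obj,
        status=status,
        gap=gap,
        n_iter=n_iter,
    )


def elastic_objective(
    problem: RegressionProblem,
    theta: np.ndarray,
    R: np.ndarray,
    weights: RegularizerWeights,
) -> float:
    """Evaluate the kernelized elastic-net cost at `theta` (R'R = P^{-1})."""
    r = problem.Y - problem.Phi @ theta
    return float(
        r @ r
        + weights.gamma * np.sum((R @ theta) ** 2)
        + weights.alpha * np.abs(theta).sum()
    )


def solve_kernel_elastic(
    problem: RegressionProblem,
    K: KernelMatrix,
    weights: RegularizerWeights,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    R: np.ndarray | None = None,
    ts: float = 1.0,
) -> EstimationResult:
    """Kernelized elastic net: L1 + kernel-weighted L2 penalized FIR estimate.

    Pipeline: upper Cholesky factor of P^{-1} -> augmentation -> lasso ->
    restoration.  A precomputed `R` may be passed to amortize the
    factorization across repeated solves with the same kernel.  The reported
    objective and duality gap refer to the original (unaugmented) cost; the
    gap transfers unchanged because the two objectives are equal along the
    theta* = sqrt(1+gamma) theta bijection.  ``n_zero`` counts coefficients
    with |g_i| below ZERO_FRACTION * max|g|.
    """
    if R is None:
        R = upper_cholesky_of_inverse(K)
    aug = augment(problem, R, weights.gamma)
    inner = solve_l1(
        aug, weights.alpha / np.sqrt(1.0 + weights.gamma), tol=tol, max_iter=max_iter
    )
    theta = restore(inner.theta, weights.gamma)
    obj = elastic_objective(problem, theta, R, weights)
    gmax = np.abs(theta).max()
    n_zero = int(np.sum(np.abs(theta) < ZERO_FRACTION * gmax)) if gmax > 0 else theta.size
    return EstimationResult(
        impulse_response=FIRModel(g=theta, ts=ts),
        objective=obj,
        status=inner.status,
        gap=inner.gap,
        n_iter=inner.n_iter,
        n_zero=n_zero,
    )
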