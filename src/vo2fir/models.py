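"""Model/Results surface for FIR and ARX identification.

Two estimator front-ends in the style of statistical modelling packages:

- :class:`KernelFIR` -- nonparametric FIR model estimated with the kernelized
  elastic net (L1 + kernel-weighted L2 penalties); ``fit()`` returns a
  :class:`KernelFIRResults` carrying the impulse response, the optimality
  certificate, sparsity diagnostics and goodness-of-fit.
- :class:`ARX` -- the parametric baseline; ``fit()`` returns
  :class:`ARXResults` with coefficients, AIC, and free-run simulation.

Both take ``endog`` (measured output, e.g. VO2 in ml/min) and ``exog``
(input, e.g. normalized treadmill speed) as equal-length uniformly sampled
records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import arx as _arx
from .kernels import KernelMatrix, KernelSpec, build_kernel, upper_cholesky_of_inverse
from .regression import FIRModel, RegressionProblem, SampledSignal, build_regressor, simulate_fir
from .solvers import EstimationResult, RegularizerWeights, solve_kernel_elastic

__all__ = ["KernelFIR", "KernelFIRResults", "ARX", "ARXResults", "nrmse_fit"]


def nrmse_fit(y_hat: np.ndarray, y_ref: np.ndarray) -> float:
    """NRMSE goodness of fit, 1 - ||yhat - y|| / ||y - mean(y)||; 1 is perfect."""
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    if y_hat.size != y_ref.size:
        raise ValueError("signals must have equal length")
    denom = np.linalg.norm(y_ref - y_ref.mean())
    if denom == 0.0:
        raise ValueError("reference signal is constant; fit ratio undefined")
    return float(1.0 - np.linalg.norm(y_hat - y_ref) / denom)


def _as_signal(x, ts: float) -> SampledSignal:
    if isinstance(x, SampledSignal):
        return x
    return SampledSignal(values=np.asarray(x, dtype=float), ts=ts)


class KernelFIR:
    """Sparse kernel-regularized FIR model of a single-input single-output system.

    Parameters
    ----------
    endog : array-like or SampledSignal
        Measured output record y(1..M).
    exog : array-like or SampledSignal
        Input record u(1..M), same length and sampling.
    m : int
        FIR order (number of impulse-response coefficients).
    kernel : KernelSpec
        Prior covariance family and hyperparameters; default is the stable
        spline kernel with c=1, lam=0.98.
    gamma, alpha : float
        Kernel-L2 and L1 penalty weights.
    ts : float
        Sampling interval in seconds (used when endog/exog are bare arrays).
    """

    def __init__(
        self,
        endog,
        exog,
        m: int = 120,
        kernel: KernelSpec | None = None,
        gamma: float = 8.0,
        alpha: float = 10.0,
        ts: float = 1.0,
    ) -> None:
        self.endog = _as_signal(endog, ts)
        self.exog = _as_signal(exog, ts)
        self.m = int(m)
        self.kernel_spec = kernel if kernel is not None else KernelSpec("ss", c=1.0, lam=0.98)
        self.weights = RegularizerWeights(gamma=gamma, alpha=alpha)
        self.problem: RegressionProblem = build_regressor(self.exog, self.endog, self.m)
        self._kernel_matrix: KernelMatrix | None = None
        self._R: np.ndarray | None = None

    @classmethod
    def from_signals(cls, u: SampledSignal, y: SampledSignal, **kwargs) -> "KernelFIR":
        return cls(endog=y, exog=u, **kwargs)

    @property
    def kernel_matrix(self) -> KernelMatrix:
        if self._kernel_matrix is None:
            self._kernel_matrix = build_kernel(self.kernel_spec, self.m)
        return self._kernel_matrix

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 100_000,
        R: np.ndarray | None = None,
    ) -> "KernelFIRResults":
        """Estimate the impulse response by the kernelized elastic net."""
        if R is None:
            if self._R is None:
                self._R = upper_cholesky_of_inverse(self.kernel_matrix)
            R = self._R
        est = solve_kernel_elastic(
            self.problem,
            self.kernel_matrix,
            self.weights,
            tol=tol,
            max_iter=max_iter,
            R=R,
            ts=self.endog.ts,
        )
        return KernelFIRResults(model=self, estimation=est)


@dataclass(frozen=True, eq=False)
class KernelFIRResults:
    """Fitted kernelized-elastic-net FIR model."""

    model: KernelFIR
    estimation: EstimationResult

    @property
    def impulse_response(self) -> FIRModel:
        return self.estimation.impulse_response

    @property
    def params(self) -> np.ndarray:
        """Impulse-response coefficients g_1..g_m."""
        return self.estimation.impulse_response.g

    @property
    def fittedvalues(self) -> np.ndarray:
        """Model output Phi @ theta for samples m+1..M (the regression rows)."""
        return self.model.problem.Phi @ self.params

    @property
    def resid(self) -> np.ndarray:
        return self.model.problem.Y - self.fittedvalues

    @property
    def gain(self) -> float:
        """Estimated steady-state step-response gain (sum of coefficients)."""
        return self.impulse_response.gain

    @property
    def n_zero(self) -> int:
        return self.estimation.n_zero

    def fit_ratio(self, reference: np.ndarray | None = None) -> float:
        """NRMSE fit of the model output over samples m+1..M.

        By default the measured output is the reference; a noise-free
        reference of the same length M (or N) may be supplied instead.
        """
        if reference is None:
            ref = self.model.problem.Y
        else:
            reference = np.asarray(reference, dtype=float).ravel()
            ref = reference[-self.model.problem.N :] if reference.size != self.model.problem.N else reference
        return nrmse_fit(self.fittedvalues, ref)

    def predict(self, exog=None, offset: float = 0.0) -> SampledSignal:
        """Noise-free convolution of the estimated IR with an input record."""
        u = self.model.exog if exog is None else _as_signal(exog, self.model.exog.ts)
        out = simulate_fir(self.impulse_response, u)
        return SampledSignal(values=out.values + offset, ts=out.ts, t0=out.t0)

    def step_response(self) -> np.ndarray:
        return self.impulse_response.step_response()

    def summary(self) -> str:
        m = self.model
        spec = m.kernel_spec
        lines = [
            "Kernelized elastic-net FIR estimation",
            "=" * 46,
            f"samples (M)          : {len(m.endog)}",
            f"FIR order (m)        : {m.m}",
            f"regression rows (N)  : {m.problem.N}",
            f"kernel               : {spec.kind.upper()} (c={spec.c:g}, lam={spec.lam:g}"
            + (f", rho={spec.rho:g})" if spec.rho is not None else ")"),
            f"gamma / alpha        : {m.weights.gamma:g} / {m.weights.alpha:g}",
            f"solver status        : {self.estimation.status} "
            f"({self.estimation.n_iter} iterations, duality gap {self.estimation.gap:.3e})",
            f"objective value      : {self.estimation.objective:.6g}",
            f"zero coefficients    : {self.n_zero} / {m.m}",
            f"step-response gain   : {self.gain:.6g}",
            f"fit ratio (measured) : {self.fit_ratio():.4f}",
        ]
        return "\n".join(lines)


class ARX:
    """Parametric ARX(na, nb) baseline model fitted by least squares."""

    def __init__(self, endog, exog, na: int = 1, nb: int = 1, ts: float = 1.0) -> None:
        self.endog = _as_signal(endog, ts)
        self.exog = _as_signal(exog, ts)
        self.na = int(na)
        self.nb = int(nb)

    @classmethod
    def select_order(
        cls, endog, exog, orders: Sequence[tuple[int, int]], ts: float = 1.0
    ) -> tuple[int, int]:
        """AIC-minimizing (na, nb) over a candidate list."""
        y = _as_signal(endog, ts)
        u = _as_signal(exog, ts)
        return _arx.aic_select(u, y, orders)

    def fit(self) -> "ARXResults":
        model = _arx.fit_arx(self.exog, self.endog, self.na, self.nb)
        return ARXResults(model=self, arx=model)


@dataclass(frozen=True, eq=False)
class ARXResults:
    """Fitted ARX baseline."""

    model: ARX
    arx: _arx.ARXModel

    @property
    def params(self) -> np.ndarray:
        return np.r_[self.arx.a, self.arx.b]

    @property
    def resid(self) -> np.ndarray:
        """One-step-ahead prediction residuals."""
        return _arx.arx_residuals(self.arx, self.model.exog, self.model.endog)

    @property
    def rss(self) -> float:
        e = self.resid
        return float(e @ e)

    @property
    def aic(self) -> float:
        e = self.resid
        N = e.size
        return float(N * np.log(max(self.rss, 1e-300) / N) + 2 * (self.arx.na + self.arx.nb))

    def simulate(self, exog=None, y_init: Sequence[float] | None = None) -> SampledSignal:
        """Free-run simulation; defaults to the training input with measured
        initial outputs."""
        u = self.model.exog if exog is None else _as_signal(exog, self.model.exog.ts)
        if y_init is None:
            y_init = self.model.endog.values[: self.arx.na]
        return _arx.simulate_arx(self.arx, u, y_init)

    def fit_ratio(self, reference: np.ndarray | None = None, start: int = 0) -> float:
        """NRMSE fit of the free-run simulation from sample `start` (0-based)."""
        yhat = self.simulate().values[start:]
        ref = self.model.endog.values if reference is None else np.asarray(reference, float).ravel()
        return nrmse_fit(yhat, ref[start:])

    def summary(self) -> str:
        a_txt = ", ".join(f"a{i+1}={v:.6g}" for i, v in enumerate(self.arx.a))
        b_txt = ", ".join(f"b{j+1}={v:.6g}" for j, v in enumerate(self.arx.b))
        lines = [
            f"ARX({self.arx.na}, {self.arx.nb}) least-squares fit",
            "=" * 46,
            f"input coefficients   : {a_txt}",
            f"output coefficients  : {b_txt}",
            f"stable               : {self.arx.is_stable}",
            f"dc gain              : {self.arx.dc_gain:.6g}",
            f"one-step RSS         : {self.rss:.6g}",
            f"AIC                  : {self.aic:.6g}",
        ]
        return "\n".join(lines)
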