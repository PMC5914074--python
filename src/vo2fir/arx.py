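"""ARX baseline: prediction-error (least-squares) fitting and AIC order selection.

The parametric comparison model is the ARX structure

    y(k) = a_1 u(k-1) + ... + a_nb u(k-nb)
         + b_1 y(k-1) + ... + b_na y(k-na) + eps(k),

where the a's weight past inputs and the b's past outputs.  For this
structure the prediction error method reduces exactly to linear least squares
on the lagged-regressor matrix, which is what `fit_arx` solves (min-norm
pseudo-inverse policy on degenerate data).  Model-order choice uses Akaike's
information criterion in its scale-free form AIC = N ln(RSS/N) + 2(na+nb).

Free-run simulation (`simulate_arx`) feeds the model its *own* past outputs,
which is what step-response comparison plots require; one-step-ahead
prediction would flatter the baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .regression import SampledSignal

__all__ = [
    "ARXModel",
    "StabilityWarning",
    "fit_arx",
    "simulate_arx",
    "arx_residuals",
    "aic_select",
]


class StabilityWarning(UserWarning):
    """Free-run simulation of an unstable ARX model."""


@dataclass(frozen=True, eq=False)
class ARXModel:
    """ARX coefficients: `a` weights input lags (nb of them), `b` output lags (na)."""

    a: np.ndarray
    b: np.ndarray
    ts: float = 1.0

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if a.size < 1 or b.size < 1:
            raise ValueError("ARX model needs na, nb >= 1")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def nb(self) -> int:
        return self.a.size

    @property
    def na(self) -> int:
        return self.b.size

    @property
    def is_stable(self) -> bool:
        """Stability of the autoregressive part (roots of z^na - sum b_j z^(na-j))."""
        poly = np.r_[1.0, -self.b]
        return bool(np.all(np.abs(np.roots(poly)) <= 1.0 + 1e-10))

    @property
    def dc_gain(self) -> float:
        """Steady-state gain sum(a) / (1 - sum(b)) for a stable model."""
        return float(self.a.sum() / (1.0 - self.b.sum()))

    def to_csv(self, path) -> None:
        rows = [("a", i + 1, v) for i, v in enumerate(self.a)]
        rows += [("b", j + 1, v) for j, v in enumerate(self.b)]
        pd.DataFrame(rows, columns=["coef", "lag", "value"]).to_csv(path, index=False)


def _lagged_design(
    u: np.ndarray, y: np.ndarray, na: int, nb: int
) -> tuple[np.ndarray, np.ndarray]:
    p = max(na, nb)
    M = y.size
    if M <= p:
        raise ValueError(f"need more than max(na, nb)={p} samples, got {M}")
    k = np.arange(p, M)
    cols = [u[k - i] for i in range(1, nb + 1)]
    cols += [y[k - j] for j in range(1, na + 1)]
    return np.column_stack(cols), y[k]


def fit_arx(u: SampledSignal, y: SampledSignal, na: int, nb: int) -> ARXModel:
    """Least-squares (= prediction-error) fit of an ARX(na, nb) model."""
    if na < 1 or nb < 1:
        raise ValueError("ARX orders must satisfy na, nb >= 1")
    if len(u) != len(y):
        raise ValueError("input and output records must have equal length")
    X, t = _lagged_design(u.values, y.values, na, nb)
    coef, *_ = np.linalg.lstsq(X, t, rcond=None)
    return ARXModel(a=coef[:nb], b=coef[nb:], ts=y.ts)


def arx_residuals(model: ARXModel, u: SampledSignal, y: SampledSignal) -> np.ndarray:
    """One-step-ahead prediction residuals on the model's valid sample range."""
    X, t = _lagged_design(u.values, y.values, model.na, model.nb)
    return t - X @ np.r_[model.a, model.b]


def simulate_arx(
    model: ARXModel, u: SampledSignal, y_init: Sequence[float]
) -> SampledSignal:
    """Free-run simulation: predicted outputs are fed back, not measured ones.

    The first na outputs are seeded from `y_init`; inputs before the start of
    the record are taken as zero.  An unstable autoregressive polynomial
    triggers a :class:`StabilityWarning` (the trajectory is still returned).
    """
    na, nb = model.na, model.nb
    y_init = np.asarray(y_init, dtype=float).ravel()
    if y_init.size < na:
        raise ValueError(f"y_init must provide at least na={na} values")
    uv = u.values
    M = uv.size
    yhat = np.empty(M)
    yhat[:na] = y_init[:na]
    if not model.is_stable:
        warnings.warn(
            "free-run simulation of an unstable ARX model", StabilityWarning,
            stacklevel=2,
        )
    a, b = model.a, model.b
    for k in range(na, M):
        acc = 0.0
        for i in range(1, nb + 1):
            if k - i >= 0:
                acc += a[i - 1] * uv[k - i]
        acc += b @ yhat[k - na : k][::-1]
        yhat[k] = acc
    return SampledSignal(values=yhat, ts=u.ts, t0=u.t0)


def aic_select(
    u: SampledSignal, y: SampledSignal, orders: Sequence[tuple[int, int]]
) -> tuple[int, int]:
    """Pick the (na, nb) minimizing AIC = N ln(RSS/N) + 2(na+nb).

    RSS comes from one-step prediction residuals over each candidate's own
    valid range; ties break toward the smaller parameter count.
    """
    if len(orders) == 0:
        raise ValueError("candidate order list must be non-empty")
    best: tuple[float, int, int] | None = None
    best_order: tuple[int, int] | None = None
    for na, nb in orders:
        model = fit_arx(u, y, na, nb)
        e = arx_residuals(model, u, y)
        N = e.size
        rss = float(e @ e)
        aic = N * np.log(max(rss, 1e-300) / N) + 2 * (na + nb)
        key = (aic, na + nb, na)
        if best is None or key < best:
            best = key
            best_order = (na, nb)
    return best_order
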