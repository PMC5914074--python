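"""FIR data model: signals, Toeplitz regression problem, elastic-net augmentation.

The measured output is modelled as a finite impulse response (FIR) of order m
acting on the input,

    y(t) = sum_{i=1..m} g_i u(t - i) + eps(t),      t = 1..M  (1-based),

which stacks into the linear regression ``Y_N = Phi_N theta + eps_N`` with
``N = M - m`` usable rows: row i of Y is y(m+i) and row i of Phi is
[u(m+i-1), u(m+i-2), ..., u(i)].  No zero-padding is applied on the left --
rows that would need u(t) with t < 1 simply do not exist.

The kernel-weighted elastic net is solved through an augmented plain-lasso
problem: with R the upper Cholesky factor of P^{-1},

    Phi* = (1+gamma)^{-1/2} [Phi ; sqrt(gamma) R],   Y* = [Y ; 0],
    theta* = sqrt(1+gamma) theta,

so that ||Y* - Phi* theta*||^2 = ||Y - Phi theta||^2 + gamma ||R theta||^2
exactly, and the original coefficients are restored as
theta = theta* / sqrt(1+gamma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy.linalg import toeplitz

__all__ = [
    "SampledSignal",
    "FIRModel",
    "RegressionProblem",
    "AugmentedProblem",
    "build_regressor",
    "simulate_fir",
    "augment",
    "restore",
]


@dataclass(frozen=True, eq=False)
class SampledSignal:
    """A uniformly sampled real-valued signal.

    Samples are stored 0-based internally; the 1-based time index t = 1..M of
    the regression formulas maps to ``values[t-1]``.  ``t0`` is the absolute
    time (seconds) of the first sample, used by the breath-by-breath pipeline
    to align resampled records with the exercise protocol.
    """

    values: np.ndarray
    ts: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not self.ts > 0:
            raise ValueError(f"sampling interval must be positive, got {self.ts}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.t0 + self.ts * np.arange(len(self))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "SampledSignal":
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        if t.size < 2:
            return cls(values=v, ts=1.0, t0=float(t[0]) if t.size else 0.0)
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        return cls(values=v, ts=float(dt[0]), t0=float(t[0]))


@dataclass(frozen=True, eq=False)
class FIRModel:
    """Estimated impulse-response coefficients g_1..g_m (1-based lags)."""

    g: np.ndarray
    ts: float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float).ravel()
        if g.size < 1:
            raise ValueError("FIR model needs at least one coefficient")
        if not np.all(np.isfinite(g)):
            raise ValueError("FIR coefficients must be finite")
        object.__setattr__(self, "g", g)

    @property
    def m(self) -> int:
        return self.g.size

    @property
    def gain(self) -> float:
        """Steady-state step-response gain, sum of all coefficients."""
        return float(self.g.sum())

    def step_response(self) -> np.ndarray:
        """Response to a unit step applied at t=1, evaluated at t = 1..m."""
        return np.cumsum(self.g)

    def to_csv(self, path) -> None:
        pd.DataFrame({"index": np.arange(1, self.m + 1), "g": self.g}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, ts: float = 1.0) -> "FIRModel":
        df = pd.read_csv(path)
        return cls(g=df["g"].to_numpy(dtype=float), ts=ts)


@dataclass(frozen=True, eq=False)
class RegressionProblem:
    """The stacked FIR regression (Y, Phi) with N = M - m rows."""

    Y: np.ndarray
    Phi: np.ndarray
    m: int

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float).ravel()
        Phi = np.asarray(self.Phi, dtype=float)
        if Phi.ndim != 2 or Phi.shape != (Y.size, self.m):
            raise ValueError(
                f"regressor shape {Phi.shape} inconsistent with N={Y.size}, m={self.m}"
            )
        if Y.size < 1:
            raise ValueError("regression problem needs at least one row")
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "Phi", Phi)

    @property
    def N(self) -> int:
        return self.Y.size


@dataclass(frozen=True, eq=False)
class AugmentedProblem:
    """Lasso-ready augmented system; the last m rows carry the kernel penalty."""

    Ystar: np.ndarray
    Phistar: np.ndarray
    gamma: float

    @property
    def m(self) -> int:
        return self.Phistar.shape[1]


def build_regressor(u: SampledSignal, y: SampledSignal, m: int) -> RegressionProblem:
    """Build the Toeplitz-structured FIR regression from input/output records."""
    if len(u) != len(y):
        raise ValueError(f"input ({len(u)}) and output ({len(y)}) lengths differ")
    if u.ts != y.ts:
        raise ValueError("input and output sampling intervals differ")
    M = len(u)
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError(f"FIR order must be a positive integer, got {m}")
    if M <= m:
        raise ValueError(
            f"insufficient data for FIR order: need M > m, got M={M}, m={m}"
        )
    uv = u.values
    # row i (1-based) is [u(m+i-1), ..., u(i)]: first column u[m-1:M-1],
    # first row u[m-1::-1] in 0-based storage.
    Phi = toeplitz(uv[m - 1 : M - 1], uv[m - 1 :: -1])
    return RegressionProblem(Y=y.values[m:], Phi=Phi, m=int(m))


def simulate_fir(
    model: FIRModel,
    u: SampledSignal,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SampledSignal:
    """Causal convolution y(t) = sum g_i u(t-i) + eps, with u(t)=0 for t <= 0.

    ``eps`` is i.i.d. Gaussian with standard deviation `noise_sd`; zero gives
    a deterministic output and requires no generator.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    y = _sig.lfilter(np.r_[0.0, model.g], [1.0], u.values)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("a seeded generator is required when noise_sd > 0")
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    return SampledSignal(values=y, ts=u.ts, t0=u.t0)


def augment(
    problem: RegressionProblem, R: np.ndarray, gamma: float
) -> AugmentedProblem:
    """Fold the quadratic kernel penalty into extra rows of a lasso problem."""
    R = np.asarray(R, dtype=float)
    if R.shape != (problem.m, problem.m):
        raise ValueError(f"R shape {R.shape} does not match FIR order {problem.m}")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    scale = 1.0 / np.sqrt(1.0 + gamma)
    Phistar = scale * np.vstack([problem.Phi, np.sqrt(gamma) * R])
    Ystar = np.concatenate([problem.Y, np.zeros(problem.m)])
    return AugmentedProblem(Ystar=Ystar, Phistar=Phistar, gamma=float(gamma))


def restore(theta_star: np.ndarray, gamma: float) -> np.ndarray:
    """Map the augmented-problem solution back: theta = theta* / sqrt(1+gamma)."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    return np.asarray(theta_star, dtype=float) / np.sqrt(1.0 + gamma)
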