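"""Prior covariance kernels for regularized FIR impulse-response estimation.

The impulse response of a stable physiological system (here: oxygen uptake
responding to treadmill speed) decays exponentially.  That prior knowledge is
encoded as an m x m covariance matrix P over the FIR coefficients
``theta = [g_1 .. g_m]``; the quadratic penalty ``theta' P^{-1} theta`` then
shrinks high-frequency and slowly-decaying estimates.  Three classic kernels
are provided, indexed 1-based in i, j = 1..m:

- DI (diagonal):            P(i,j) = c * lam**i            if i == j, else 0
- DC (diagonal/correlated): P(i,j) = c * rho**|i-j| * lam**((i+j)/2)
- SS (stable spline):       P(i,j) = c * lam**(2*max(i,j))/2
                                       * (lam**min(i,j) - lam**max(i,j)/3)

For SS two entry conventions exist in the literature; the ``canonical``
min/max form above is provably positive definite and is the default.  The
alternative ``printed`` form swaps min and max inside the parenthesis; it
coincides with the canonical form on the diagonal but becomes indefinite for
large ``|i-j|`` (e.g. lam=0.98, m=120) and is therefore only available behind
an explicit flag, still guarded by the positive-definiteness check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "KernelSpec",
    "KernelMatrix",
    "PDReport",
    "build_kernel",
    "validate_pd",
    "upper_cholesky_of_inverse",
    "KernelValidationError",
    "NotPositiveDefiniteError",
    "KernelParameterWarning",
]

#: relative (to the largest eigenvalue) threshold for the eigenvalue check.
#: A matrix whose computed smallest eigenvalue is materially negative
#: (below -PD_RTOL * max) is rejected outright; one whose smallest eigenvalue
#: merely underflows the eigensolver's resolution (decay kernels at large m
#: are graded: their spectrum spans more than 16 decades) is accepted iff its
#: Cholesky factorization succeeds, which is the operational requirement of
#: the estimator.  We never jitter the diagonal -- that would silently change
#: the estimator.
PD_RTOL = 1e-12


def _cholesky_ok(P: np.ndarray) -> bool:
    try:
        linalg.cholesky(P, lower=True)
        return True
    except linalg.LinAlgError:
        return False


class KernelValidationError(ValueError):
    """A kernel specification violates its hard parameter constraints."""


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """A kernel matrix is not numerically positive definite."""


class KernelParameterWarning(UserWarning):
    """Kernel parameters lie outside the advisory (recommended) ranges."""


# advisory ranges from the tuning literature; violation warns but does not fail
_ADVISORY = {
    "di": "0.7 <= lam < 1",
    "ss": "0.9 <= lam < 1",
    "dc": "0.72 <= lam < 1 and -0.99 <= rho <= 0.99",
}


@dataclass(frozen=True)
class KernelSpec:
    """Specification of a decay kernel.

    Parameters
    ----------
    kind : {'di', 'ss', 'dc'}
        Kernel family (case-insensitive).
    c : float
        Positive overall scale of the prior covariance.
    lam : float
        Decay rate, ``0 < lam < 1``; smaller values encode faster decay of
        the impulse response.
    rho : float, optional
        Correlation parameter, DC kernel only; ``|rho| <= 1`` and ``rho != 0``.
    """

    kind: str
    c: float = 1.0
    lam: float = 0.9
    rho: float | None = None

    def __post_init__(self) -> None:
        kind = str(self.kind).lower()
        object.__setattr__(self, "kind", kind)
        if kind not in ("di", "ss", "dc"):
            raise KernelValidationError(f"unknown kernel kind {self.kind!r}")
        if not self.c > 0:
            raise KernelValidationError(f"kernel scale c must be > 0, got {self.c}")
        if not 0.0 < self.lam < 1.0:
            raise KernelValidationError(f"decay lam must lie in (0, 1), got {self.lam}")
        if kind == "dc":
            if self.rho is None:
                raise KernelValidationError("DC kernel requires rho")
            if not abs(self.rho) <= 1.0 or self.rho == 0.0:
                raise KernelValidationError(
                    f"DC kernel requires 0 < |rho| <= 1, got {self.rho}"
                )
        elif self.rho is not None:
            raise KernelValidationError(f"rho is only meaningful for the DC kernel")
        self._warn_advisory()

    def _warn_advisory(self) -> None:
        ok = True
        if self.kind == "di":
            ok = 0.7 <= self.lam
        elif self.kind == "ss":
            ok = 0.9 <= self.lam
        elif self.kind == "dc":
            ok = 0.72 <= self.lam and abs(self.rho) <= 0.99
        if not ok:
            warnings.warn(
                f"{self.kind.upper()} kernel parameters outside the advisory "
                f"range ({_ADVISORY[self.kind]}); estimation proceeds but may "
                "be poorly regularized",
                KernelParameterWarning,
                stacklevel=3,
            )


@dataclass(frozen=True, eq=False)
class KernelMatrix:
    """A built m x m kernel matrix together with its specification."""

    P: np.ndarray
    spec: KernelSpec
    m: int

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        if P.shape != (self.m, self.m):
            raise ValueError(f"kernel matrix shape {P.shape} != ({self.m}, {self.m})")

    def to_csv(self, path) -> None:
        np.savetxt(path, self.P, delimiter=",")


@dataclass(frozen=True)
class PDReport:
    """Diagnostic report of a symmetry / positive-definiteness check."""

    min_eigenvalue: float
    max_eigenvalue: float
    symmetry_residual: float
    passed: bool


def build_kernel(spec: KernelSpec, m: int, ss_form: str = "canonical") -> KernelMatrix:
    """Construct the m x m kernel matrix for `spec`.

    Indices are 1-based (i, j = 1..m) in the formulas above.  The result is
    checked for symmetry and positive definiteness; an indefinite matrix
    raises :class:`NotPositiveDefiniteError` naming the offending eigenvalue.
    """
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise KernelValidationError(f"FIR order m must be a positive integer, got {m}")
    i = np.arange(1, m + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    c, lam = spec.c, spec.lam
    if spec.kind == "di":
        P = np.diag(c * lam ** i)
    elif spec.kind == "dc":
        P = c * spec.rho ** np.abs(I - J) * lam ** ((I + J) / 2.0)
    elif spec.kind == "ss":
        mx = np.maximum(I, J)
        mn = np.minimum(I, J)
        if ss_form == "canonical":
            P = c * (lam ** (2 * mx) / 2.0) * (lam ** mn - lam ** mx / 3.0)
        elif ss_form == "printed":
            P = c * (lam ** (2 * mx) / 2.0) * (lam ** mx - lam ** mn / 3.0)
        else:
            raise ValueError(f"unknown ss_form {ss_form!r}")
    else:  # pragma: no cover - guarded by KernelSpec
        raise KernelValidationError(spec.kind)
    P = (P + P.T) / 2.0  # exact symmetry against round-off
    w = np.linalg.eigvalsh(P)
    if w[0] <= PD_RTOL * w[-1] and not (w[0] > -PD_RTOL * w[-1] and _cholesky_ok(P)):
        raise NotPositiveDefiniteError(
            f"{spec.kind.upper()} kernel (m={m}) is not positive definite: "
            f"smallest eigenvalue {w[0]:.3e} vs largest {w[-1]:.3e}"
        )
    return KernelMatrix(P=P, spec=spec, m=m)


def validate_pd(K: KernelMatrix | np.ndarray, tol: float = PD_RTOL) -> PDReport:
    """Check symmetry and positive definiteness of a kernel matrix.

    Passes iff the smallest eigenvalue exceeds ``tol`` times the largest, or
    -- for graded matrices whose smallest eigenvalues underflow the
    eigensolver's resolution -- iff no computed eigenvalue is materially
    negative (below ``-tol`` times the largest) and the Cholesky
    factorization succeeds.  Asymmetric input (relative symmetry residual
    above 1e-8) is an error, not a failed report, because the
    eigen-decomposition would be meaningless.
    """
    P = K.P if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"kernel matrix must be square, got shape {P.shape}")
    scale = np.abs(P).max()
    sym_resid = float(np.abs(P - P.T).max() / scale) if scale > 0 else 0.0
    if sym_resid > 1e-8:
        raise ValueError(f"matrix is not symmetric (residual {sym_resid:.3e})")
    Psym = (P + P.T) / 2.0
    w = np.linalg.eigvalsh(Psym)
    passed = bool(w[0] > tol * abs(w[-1])) or bool(
        w[0] > -tol * abs(w[-1]) and _cholesky_ok(Psym)
    )
    return PDReport(
        min_eigenvalue=float(w[0]),
        max_eigenvalue=float(w[-1]),
        symmetry_residual=sym_resid,
        passed=passed,
    )


def upper_cholesky_of_inverse(K: KernelMatrix | np.ndarray) -> np.ndarray:
    """Upper-triangular R with ``R' R = P^{-1}``, so ``theta' P^{-1} theta = ||R theta||^2``.

    Computed without forming ``P^{-1}`` explicitly: from the lower Cholesky
    factor ``P = L L'`` we have ``P^{-1} = (L^{-1})' L^{-1}``; the QR
    decomposition ``L^{-1} = Q R`` then yields ``R' R = P^{-1}`` with R upper
    triangular (signs fixed so the diagonal is positive).
    """
    P = K.P if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    try:
        L = linalg.cholesky(P, lower=True)
    except linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(
            f"kernel matrix is not positive definite: {exc}"
        ) from exc
    Linv = linalg.solve_triangular(L, np.eye(P.shape[0]), lower=True)
    R = np.linalg.qr(Linv, mode="r")
    s = np.sign(np.diag(R))
    s[s == 0] = 1.0
    return s[:, None] * R
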