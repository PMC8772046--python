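"""Proximal and spectral primitives shared by the solver.

These are the building blocks of the alternating-direction solver: the
elementwise shrinkage operator (proximal map of the L1 norm), singular
value thresholding (proximal map of the nuclear norm), the truncated
nuclear norm, and the leading singular-factor pair used in its convex
surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "FactorPair",
    "soft_threshold",
    "svt",
    "truncated_nuclear_norm",
    "top_r_factors",
    "spectral_norm",
]


def _as_finite_matrix(M: ArrayLike, name: str = "M") -> NDArray[np.float64]:
    A = np.asarray(M, dtype=float)
    if A.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={A.ndim}")
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{name} contains non-finite entries")
    return A


def _svd(A: NDArray[np.float64], compute_uv: bool = True):
    """SVD with a fallback driver for matrices where gesdd stalls."""
    try:
        return np.linalg.svd(A, full_matrices=False, compute_uv=compute_uv)
    except np.linalg.LinAlgError:
        if compute_uv:
            return scipy.linalg.svd(A, full_matrices=False, lapack_driver="gesvd")
        return scipy.linalg.svd(A, compute_uv=False, lapack_driver="gesvd")


@dataclass(frozen=True)
class FactorPair:
    """Top-r singular factors of a matrix.

    ``A`` holds the r leading left singular vectors as rows, ``B`` the r
    leading right singular vectors as rows, so that ``Tr(A @ Z @ B.T)``
    equals the sum of the r largest singular values of Z.  Rows are
    orthonormal: ``A @ A.T == I_r`` and ``B @ B.T == I_r``.
    """

    A: NDArray[np.float64]
    B: NDArray[np.float64]
    r: int

    def surrogate_trace(self, Z: ArrayLike) -> float:
        """Tr(A Z Bᵀ); zero when r == 0."""
        if self.r == 0:
            return 0.0
        Z = np.asarray(Z, dtype=float)
        return float(np.trace(self.A @ Z @ self.B.T))


def soft_threshold(M: ArrayLike, tau: float) -> NDArray[np.float64]:
    """Elementwise shrinkage ``sign(m) * max(|m| - tau, 0)``.

    This is the proximal operator of ``tau * ||.||_1``: the unique
    minimizer of ``1/2 (p - m)^2 + tau |p|`` in each entry.
    """
    if tau < 0:
        raise ValueError(f"shrinkage threshold must be nonnegative, got {tau}")
    A = _as_finite_matrix(np.atleast_2d(M))
    return np.sign(A) * np.maximum(np.abs(A) - tau, 0.0)


def svt(M: ArrayLike, tau: float) -> NDArray[np.float64]:
    """Singular value thresholding: soft-threshold the singular values.

    Returns ``U diag(max(s_i - tau, 0)) V^T`` for the SVD of M — the
    proximal operator of ``tau * ||.||_*`` (nuclear norm).
    """
    if tau < 0:
        raise ValueError(f"shrinkage threshold must be nonnegative, got {tau}")
    A = _as_finite_matrix(M)
    U, s, Vt = _svd(A)
    s_shrunk = np.maximum(s - tau, 0.0)
    return (U * s_shrunk) @ Vt


def truncated_nuclear_norm(M: ArrayLike, r: int) -> float:
    """Sum of all singular values except the r largest.

    With ``r = 0`` this is the plain nuclear norm; with ``r = min(p, q)``
    it is zero.  Leaving the r leading values unpenalized gives a tighter
    surrogate of matrix rank than the nuclear norm.
    """
    A = _as_finite_matrix(M)
    kmax = min(A.shape)
    if not 0 <= r <= kmax:
        raise ValueError(f"truncation rank r={r} outside [0, {kmax}]")
    s = _svd(A, compute_uv=False)
    return float(np.sum(s[r:]))


def top_r_factors(Z: ArrayLike, r: int) -> FactorPair:
    """Leading r left/right singular vectors of Z, as row-orthonormal A, B.

    A deterministic sign convention is applied (the largest-magnitude
    entry of each left singular vector is made positive, with the
    matching sign flip on the right vector) so repeated calls on equal
    input give bit-identical factors.
    """
    A = _as_finite_matrix(Z, "Z")
    kmax = min(A.shape)
    if not 0 <= r <= kmax:
        raise ValueError(f"truncation rank r={r} outside [0, {kmax}]")
    if r == 0:
        return FactorPair(
            A=np.empty((0, A.shape[0])), B=np.empty((0, A.shape[1])), r=0
        )
    U, _, Vt = _svd(A)
    Ur, Vr = U[:, :r], Vt[:r, :]
    # fixed sign convention for reproducibility under SVD sign ambiguity
    lead = np.argmax(np.abs(Ur), axis=0)
    signs = np.sign(Ur[lead, np.arange(r)])
    signs[signs == 0] = 1.0
    return FactorPair(A=(Ur * signs).T, B=Vr * signs[:, None], r=r)


def spectral_norm(M: ArrayLike) -> float:
    """Largest singular value of M (operator 2-norm)."""
    A = _as_finite_matrix(M)
    if A.size == 0:
        return 0.0
    return float(np.linalg.norm(A, 2))
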