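"""Lyapunov equation: forward covariance solve and regression vectorization.

For a linearized stochastically forced network near a stable steady state,
the stationary concentration covariance C obeys

    J C + C J^T = -2 D.

Forward direction (data generation): given a Hurwitz-stable Jacobian J and a
fluctuation matrix D, solve for C.  Inverse direction: given C and the zero
pattern of J, the same bilinear identity is rewritten as a linear system
``A q = b`` in the free Jacobian entries q, with one equation per upper
triangle position (i <= j) and ``b = -2 vech(D)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .network import JacobianStructure

__all__ = [
    "UnstableJacobianError",
    "VectorizedSystem",
    "stability_margin",
    "assert_stable",
    "solve_covariance",
    "vectorize",
    "vectorize_rhs",
    "triu_indices_rowmajor",
]

#: Rejection threshold for the largest eigenvalue real part.
STABILITY_MARGIN = -1e-9


class UnstableJacobianError(ValueError):
    """Raised when a Jacobian is not Hurwitz-stable."""


def stability_margin(J: np.ndarray) -> float:
    """Largest real part over the spectrum of J (negative = stable)."""
    return float(np.max(np.real(np.linalg.eigvals(np.asarray(J, dtype=float)))))


def assert_stable(J: np.ndarray) -> None:
    margin = stability_margin(J)
    if margin > STABILITY_MARGIN:
        raise UnstableJacobianError(
            f"unstable Jacobian: max Re(eig) = {margin:.3e}"
        )


def solve_covariance(J: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Stationary covariance C solving ``J C + C J^T = -2 D``.

    Uses the Bartels-Stewart solver; the result is explicitly symmetrized.
    Raises :class:`UnstableJacobianError` for non-Hurwitz J and warns with a
    condition estimate when the residual exceeds the contract
    ``1e-8 * max(1, max|D|)``.
    """
    J = np.asarray(J, dtype=float)
    D = np.asarray(D, dtype=float)
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be symmetric")
    assert_stable(J)
    C = scipy.linalg.solve_continuous_lyapunov(J, -2.0 * D)
    C = 0.5 * (C + C.T)
    residual = np.max(np.abs(J @ C + C @ J.T + 2.0 * D))
    tol = 1e-8 * max(1.0, np.max(np.abs(D)))
    if residual > tol:
        n = J.shape[0]
        L = np.kron(np.eye(n), J) + np.kron(J, np.eye(n))
        warnings.warn(
            f"ill-conditioned Lyapunov solve: residual {residual:.3e}, "
            f"cond estimate {np.linalg.cond(L):.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
    return C


def triu_indices_rowmajor(n: int) -> list[tuple[int, int]]:
    """Upper-triangle positions (i <= j) in row-major order.

    This ordering is the fixed contract between equation rows of
    :func:`vectorize` and entries of :func:`vectorize_rhs`.
    """
    return [(i, j) for i in range(n) for j in range(i, n)]


@dataclass
class VectorizedSystem:
    """The coefficient side of ``A q = b`` restricted to a Jacobian pattern.

    ``A`` has ``n(n+1)/2`` rows (upper-triangle equations, row-major) and
    one column per free Jacobian entry; ``index_map`` lists the (row, col)
    Jacobian position of each column in row-major order.
    """

    A: np.ndarray
    index_map: list[tuple[int, int]]
    n: int

    @property
    def col_of(self) -> dict[tuple[int, int], int]:
        return {pos: c for c, pos in enumerate(self.index_map)}

    def true_q(self, J: np.ndarray) -> np.ndarray:
        """Free entries of a concrete Jacobian in column order."""
        J = np.asarray(J, dtype=float)
        return np.array([J[k, l] for (k, l) in self.index_map])


def vectorize(C: np.ndarray, pattern: JacobianStructure) -> VectorizedSystem:
    """Coefficient matrix of the Lyapunov identity in the free J entries.

    Equation row (i, j), i <= j, of ``J C + C J^T = -2 D`` gives the free
    unknown ``J[k, l]`` the coefficient ``[k == i] C[l, j] + [k == j] C[l, i]``
    (diagonal rows pick up both terms).  With q the true free entries and b
    from :func:`vectorize_rhs`, ``A q = b`` holds identically.
    """
    C = np.asarray(C, dtype=float)
    n = pattern.n
    if C.shape != (n, n):
        raise ValueError("C shape must match the pattern")
    cols = pattern.nonzeros()
    rows = triu_indices_rowmajor(n)
    A = np.zeros((len(rows), len(cols)))
    for r, (i, j) in enumerate(rows):
        for c, (k, l) in enumerate(cols):
            a = 0.0
            if k == i:
                a += C[l, j]
            if k == j:
                a += C[l, i]
            A[r, c] = a
    return VectorizedSystem(A=A, index_map=cols, n=n)


def vectorize_rhs(D: np.ndarray) -> np.ndarray:
    """Right-hand side ``b = -2 vech(D)`` in the row ordering of
    :func:`vectorize` (upper triangle, row-major)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    return np.array([-2.0 * D[i, j] for (i, j) in triu_indices_rowmajor(n)])
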