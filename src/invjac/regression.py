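"""Regression-loss inverse differential Jacobian.

Directly solving the vectorized Lyapunov systems for the two conditions,

    A_h q_h = b_h,    A_d q_d = b_d,

is ill-conditioned; instead of recovering Jacobian values, each candidate
interaction (i, j) is scored by a hypothesis test embedded in least squares:
stack the two systems with the single constraint that J_ij is *shared*
between the conditions,

    A_c = [A_h 0; 0 A_d]  with the two J_ij columns merged,
    b_c = [b_h; b_d],

and record the residual of the least-squares fit,

    R*_ij = min over sampled b_c of || b_c - A_c q* ||_2.

If the interaction truly did not change, the constraint is satisfiable and
the residual stays small; a large residual flags a changed interaction.
Because only the structure of D (hence of b) is known, the loss is
minimized over many sampled fluctuation matrices; the reported matrix is
min-max normalized to [0, 1] over the evaluated support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .lyapunov import VectorizedSystem, vectorize, vectorize_rhs
from .network import JacobianStructure

__all__ = [
    "RegressionLossMatrix",
    "element_loss",
    "regression_loss_matrix",
    "ElementProjections",
    "stack_rhs",
    "sample_rhs_matrix",
    "minmax_normalize",
]


def minmax_normalize(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min-max normalize over ``mask`` to [0, 1]; NaN outside the mask.

    Degenerate case (all masked values equal up to machine noise) maps to
    all zeros rather than stretching rounding error across the range.
    """
    out = np.full(values.shape, np.nan)
    v = values[mask]
    lo, hi = v.min(), v.max()
    if hi - lo <= 1e-12 * max(1.0, abs(hi)):
        out[mask] = 0.0
    else:
        out[mask] = (values[mask] - lo) / (hi - lo)
    return out


def _combined_matrix(
    sys_h: VectorizedSystem, sys_d: VectorizedSystem, element: tuple[int, int]
) -> np.ndarray:
    """Stacked block system with the element's two columns merged into one.

    Column order: [shared J_ij | remaining h columns | remaining d columns].
    """
    if sys_h.index_map != sys_d.index_map:
        raise ValueError("condition systems must share the Jacobian pattern")
    col = sys_h.col_of.get(tuple(element))
    if col is None:
        raise ValueError(f"element {element} is not in the Jacobian pattern support")
    A_h, A_d = sys_h.A, sys_d.A
    rows = A_h.shape[0]
    if A_d.shape != A_h.shape:
        raise ValueError("A_h and A_d dimensions differ")
    rest_h = np.delete(A_h, col, axis=1)
    rest_d = np.delete(A_d, col, axis=1)
    p = A_h.shape[1]
    A_c = np.zeros((2 * rows, 2 * p - 1))
    A_c[:rows, 0] = A_h[:, col]
    A_c[rows:, 0] = A_d[:, col]
    A_c[:rows, 1:p] = rest_h
    A_c[rows:, p:] = rest_d
    return A_c


def element_loss(
    sys_h: VectorizedSystem,
    sys_d: VectorizedSystem,
    b_c: np.ndarray,
    element: tuple[int, int],
) -> float:
    """Constrained least-squares residual for one candidate element.

    Solves ``min_q ||b_c - A_c q||_2`` by minimum-norm least squares (safe
    under rank deficiency) and returns the Euclidean residual norm.
    """
    A_c = _combined_matrix(sys_h, sys_d, element)
    b_c = np.asarray(b_c, dtype=float)
    if b_c.shape != (A_c.shape[0],):
        raise ValueError(
            f"b_c has shape {b_c.shape}, expected ({A_c.shape[0]},)"
        )
    q, *_ = scipy.linalg.lstsq(A_c, b_c, lapack_driver="gelsd")
    return float(np.linalg.norm(b_c - A_c @ q))


def stack_rhs(D_h: np.ndarray, D_d: np.ndarray) -> np.ndarray:
    """``b_c = [b_h; b_d]`` for one sampled fluctuation-matrix pair."""
    return np.concatenate([vectorize_rhs(D_h), vectorize_rhs(D_d)])


def sample_rhs_matrix(
    sampler,
    n_samples: int,
    seed: int,
    extra_samples: Sequence[tuple[np.ndarray, np.ndarray]] = (),
) -> np.ndarray:
    """Column-stacked b_c draws, one column per sample.

    Sample s uses its own generator keyed by (seed, s), so the stream is
    prefix-stable: increasing ``n_samples`` never changes earlier columns.
    ``extra_samples`` are deterministic (D_h, D_d) pairs prepended to the
    stream without consuming seeds.
    """
    cols = [stack_rhs(Dh, Dd) for (Dh, Dd) in extra_samples]
    for s in range(n_samples):
        rng = np.random.default_rng([int(seed), s])
        cols.append(stack_rhs(*sampler.sample_pair(rng)))
    return np.column_stack(cols)


class ElementProjections:
    """Per-element orthonormal bases of col(A_c), reusable across samplers.

    The combined matrix A_c depends only on (C_h, C_d, pattern, element) —
    not on the sampled fluctuation matrices — so the projection onto its
    column space is computed once per element and applied to all sampled
    right-hand sides as a single matrix product.  The residual
    ``||b - Q Q^T b||`` equals the least-squares residual of
    :func:`element_loss` (full-rank or not).
    """

    def __init__(
        self,
        C_h: np.ndarray,
        C_d: np.ndarray,
        pattern: JacobianStructure,
        include_diagonal: bool = False,
    ):
        self.sys_h = vectorize(C_h, pattern)
        self.sys_d = vectorize(C_d, pattern)
        self.pattern = pattern
        self.elements = [
            (k, l)
            for (k, l) in self.sys_h.index_map
            if include_diagonal or k != l
        ]
        if not self.elements:
            raise ValueError("empty evaluated support")
        self._bases = {
            e: scipy.linalg.orth(_combined_matrix(self.sys_h, self.sys_d, e))
            for e in self.elements
        }

    def losses(self, B: np.ndarray) -> dict[tuple[int, int], float]:
        """Min-over-samples residual per element; B columns are b_c draws."""
        out = {}
        for e, Q in self._bases.items():
            Rsd = B - Q @ (Q.T @ B)
            out[e] = float(np.min(np.linalg.norm(Rsd, axis=0)))
        return out


@dataclass
class RegressionLossMatrix:
    """Normalized regression-loss matrix R*, the differential-Jacobian proxy.

    ``R`` holds values in [0, 1] on the evaluated support and NaN elsewhere;
    ``raw`` the unnormalized min-over-samples losses.  ``degenerate`` is set
    when all losses were equal (normalized matrix all zeros).
    """

    R: np.ndarray
    raw: np.ndarray
    support: np.ndarray  # boolean mask of evaluated positions
    strategy: str = ""
    n_samples: int = 0
    seed: int = 0
    degenerate: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.R.shape[0]

    def argmax(self) -> tuple[int, int]:
        """Position of the largest normalized loss (ties: lowest index)."""
        masked = np.where(self.support, self.R, -np.inf)
        return tuple(np.unravel_index(int(np.argmax(masked)), masked.shape))


def regression_loss_matrix(
    C_h: np.ndarray,
    C_d: np.ndarray,
    pattern: JacobianStructure,
    sampler,
    n_samples: int = 1000,
    seed: int = 0,
    include_diagonal: bool = False,
    extra_samples: Sequence[tuple[np.ndarray, np.ndarray]] = (),
) -> RegressionLossMatrix:
    """Full inverse differential Jacobian inference.

    For every Jacobian-pattern position in the evaluated support (off
    diagonal by default), the constrained regression loss is minimized over
    ``n_samples`` sampled (D_h, D_d) pairs and min-max normalized to [0, 1].
    Deterministic given (inputs, seed).
    """
    extra_samples = list(extra_samples)
    if n_samples < 1 and not extra_samples:
        raise ValueError("n_samples must be >= 1")
    proj = ElementProjections(C_h, C_d, pattern, include_diagonal)
    B = sample_rhs_matrix(sampler, n_samples, seed, extra_samples)
    losses = proj.losses(B)
    n = pattern.n
    raw = np.full((n, n), np.nan)
    support = np.zeros((n, n), dtype=bool)
    for (k, l), v in losses.items():
        raw[k, l] = v
        support[k, l] = True
    R = minmax_normalize(np.nan_to_num(raw, nan=0.0), support)
    hi, lo = np.nanmax(raw), np.nanmin(raw)
    degenerate = bool(hi - lo <= 1e-12 * max(1.0, abs(hi)))
    return RegressionLossMatrix(
        R=R,
        raw=raw,
        support=support,
        strategy=getattr(sampler, "name", type(sampler).__name__),
        n_samples=n_samples,
        seed=int(seed),
        degenerate=degenerate,
        metadata={"include_diagonal": include_diagonal,
                  "n_extra_samples": len(extra_samples)},
    )
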