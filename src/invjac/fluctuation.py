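"""Fluctuation matrices: construction from network structure and sampling.

The stochastic forcing on metabolite dynamics has covariance

    D = S . (K . D2 . K^T) . S^T + D1

where ``D1`` is the (diagonal) covariance of noise acting directly on
metabolites, ``D2`` the (diagonal) covariance of noise on reaction
parameters, and ``K = dv/dp`` the diagonal matrix of rate sensitivities at
steady state.  Parameter noise propagated through the stoichiometry is what
creates off-diagonal structure in ``D``.

During inference only the structure (and optionally per-entry upper bounds
from enzyme-activity variance) is known, so candidate ``D`` matrices are
drawn by one of three strategies:

* ``diagonal``     — the classical assumption: independent metabolite noise;
* ``topological``  — respect the zero/sign structure, magnitudes on [0, 1];
* ``integrative``  — additionally cap each off-diagonal magnitude by the
  enzyme-activity variance mapped to that interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .network import INDETERMINATE, ReactionNetwork, Superpathway

__all__ = [
    "FluctuationModel",
    "FluctuationStructure",
    "build_D",
    "superpathway_sign",
    "sample_diagonal",
    "sample_topological",
    "sample_integrative",
    "DiagonalSampler",
    "TopologicalSampler",
    "IntegrativeSampler",
    "PairedSampler",
]


@dataclass
class FluctuationModel:
    """Concrete noise model (D1, D2, K) attached to a reaction network."""

    D1_diag: np.ndarray  # length n, variance of direct metabolite noise
    D2_diag: np.ndarray  # length m, variance of parameter noise
    K_diag: np.ndarray   # length m, dv/dp at steady state

    def __post_init__(self) -> None:
        self.D1_diag = np.asarray(self.D1_diag, dtype=float)
        self.D2_diag = np.asarray(self.D2_diag, dtype=float)
        self.K_diag = np.asarray(self.K_diag, dtype=float)
        if (self.D1_diag < 0).any() or (self.D2_diag < 0).any():
            raise ValueError("variances must be nonnegative")
        if self.D2_diag.shape != self.K_diag.shape:
            raise ValueError("D2 and K must have one entry per reaction")


def build_D(net: ReactionNetwork, model: FluctuationModel) -> np.ndarray:
    """Exact fluctuation matrix ``S.K.D2.K^T.S^T + D1`` (symmetric PSD)."""
    if model.D1_diag.shape != (net.n_species,):
        raise ValueError("D1 length must equal number of species")
    if model.D2_diag.shape != (net.n_reactions,):
        raise ValueError("D2/K length must equal number of reactions")
    w = model.K_diag**2 * model.D2_diag  # diagonal of K.D2.K^T
    D = (net.S * w) @ net.S.T + np.diag(model.D1_diag)
    return 0.5 * (D + D.T)  # remove rounding asymmetry


def superpathway_sign(sp: Superpathway) -> int:
    """Sign of the off-diagonal ``D`` entry for a superpathway: (-1)^(k+1).

    ``k`` is the number of type-2 (same-side) steps; a pure chain of
    opposite-side steps is negative, each same-side step flips the sign.
    """
    return (-1) ** (sp.n_type2 + 1)


@dataclass
class FluctuationStructure:
    """Structural information available to the inference-time samplers.

    ``sign`` is over {-1, 0, +1, INDETERMINATE} with +1 diagonal.
    ``bounds``, when given, caps |entry| per position (required off-diagonal
    for integrative sampling; a nonzero bounds diagonal overrides
    ``diag_scale`` per metabolite).  ``diag_scale`` fixes the sampling range
    of the direct-metabolite (diagonal) fluctuations.
    """

    sign: np.ndarray
    bounds: np.ndarray | None = None
    diag_scale: float = 1.0

    def __post_init__(self) -> None:
        self.sign = np.asarray(self.sign, dtype=int)
        n = self.sign.shape[0]
        if self.sign.shape != (n, n):
            raise ValueError("sign matrix must be square")
        if not np.array_equal(self.sign, self.sign.T):
            raise ValueError("sign matrix must be symmetric")
        if not np.isin(self.sign, (-1, 0, 1, INDETERMINATE)).all():
            raise ValueError("sign entries must be -1, 0, +1 or INDETERMINATE")
        if not (np.diag(self.sign) == 1).all():
            raise ValueError("diagonal signs must be +1")
        if self.bounds is not None:
            self.bounds = np.asarray(self.bounds, dtype=float)
            if self.bounds.shape != self.sign.shape:
                raise ValueError("bounds shape must match sign shape")
            if not np.allclose(self.bounds, self.bounds.T):
                raise ValueError("bounds must be symmetric")
            if (self.bounds < 0).any():
                raise ValueError("bounds must be nonnegative")
        if self.diag_scale <= 0:
            raise ValueError("diag_scale must be positive")

    @property
    def n(self) -> int:
        return self.sign.shape[0]


def _resolve_signs(structure: FluctuationStructure, rng: np.random.Generator) -> np.ndarray:
    """Concrete {-1, 0, +1} sign matrix; one draw per indeterminate entry
    per sample (mirrored), so each sample is internally consistent."""
    sign = structure.sign.copy()
    ii, jj = np.where(np.triu(sign, 1) == INDETERMINATE)
    for i, j in zip(ii, jj):
        s = rng.choice([-1, 1])
        sign[i, j] = sign[j, i] = s
    return sign


def sample_diagonal(n: int, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """Diagonal D with i.i.d. uniform [0, scale] entries (classical model)."""
    return np.diag(rng.uniform(0.0, scale, size=n))


def sample_topological(structure: FluctuationStructure, rng: np.random.Generator) -> np.ndarray:
    """Structured D: per-entry uniform [0, 1] magnitudes times the sign
    pattern; structural zeros preserved exactly; symmetric."""
    n = structure.n
    sign = _resolve_signs(structure, rng)
    D = np.zeros((n, n))
    np.fill_diagonal(D, rng.uniform(0.0, structure.diag_scale, size=n))
    ii, jj = np.where(np.triu(sign, 1) != 0)
    mags = rng.uniform(0.0, 1.0, size=ii.size)
    D[ii, jj] = D[jj, ii] = sign[ii, jj] * mags
    return D


def sample_integrative(structure: FluctuationStructure, rng: np.random.Generator) -> np.ndarray:
    """Structured D with enzyme-activity upper bounds.

    Off-diagonal magnitudes are uniform on [0, bound(i, j)]; diagonal
    entries uniform on [0, diag_scale] (or the bounds diagonal where
    nonzero).  Raises if a structurally nonzero off-diagonal has no bound.
    """
    if structure.bounds is None:
        raise ValueError("integrative sampling requires a bounds matrix")
    n = structure.n
    sign = _resolve_signs(structure, rng)
    ii, jj = np.where(np.triu(sign, 1) != 0)
    for i, j in zip(ii, jj):
        if structure.bounds[i, j] <= 0:
            raise ValueError(
                f"missing enzyme-activity bound for structural nonzero "
                f"({i}, {j})"
            )
    D = np.zeros((n, n))
    diag_hi = np.where(np.diag(structure.bounds) > 0,
                       np.diag(structure.bounds), structure.diag_scale)
    np.fill_diagonal(D, rng.uniform(0.0, diag_hi))
    mags = rng.uniform(0.0, structure.bounds[ii, jj])
    D[ii, jj] = D[jj, ii] = sign[ii, jj] * mags
    return D


# ---------------------------------------------------------------------------
# sampler objects (what the inference loop consumes)


class Sampler(Protocol):
    def sample_pair(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw independent (D_h, D_d) candidates for one sample index."""
        ...


@dataclass
class DiagonalSampler:
    n: int
    scale: float = 1.0
    name: str = field(default="diagonal", init=False)

    def sample_one(self, rng):
        return sample_diagonal(self.n, rng, self.scale)

    def sample_pair(self, rng):
        return self.sample_one(rng), self.sample_one(rng)


@dataclass
class TopologicalSampler:
    structure: FluctuationStructure
    name: str = field(default="topological", init=False)

    def sample_one(self, rng):
        return sample_topological(self.structure, rng)

    def sample_pair(self, rng):
        return self.sample_one(rng), self.sample_one(rng)


@dataclass
class IntegrativeSampler:
    structure: FluctuationStructure
    name: str = field(default="integrative", init=False)

    def sample_one(self, rng):
        return sample_integrative(self.structure, rng)

    def sample_pair(self, rng):
        return self.sample_one(rng), self.sample_one(rng)


@dataclass
class PairedSampler:
    """Distinct per-condition samplers, e.g. condition-specific bounds."""

    sampler_h: object
    sampler_d: object

    @property
    def name(self) -> str:
        return f"{self.sampler_h.name}/{self.sampler_d.name}"

    def sample_pair(self, rng):
        return self.sampler_h.sample_one(rng), self.sampler_d.sample_one(rng)
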