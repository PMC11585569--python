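"""Synthetic kinetic networks and benchmark data for the evaluation workflow.

The evaluation needs, with known ground truth: (i) a stable mass-action
reaction network and its Jacobian, (ii) a second condition obtained by
scaling selected rate constants, so the set of changed Jacobian entries is
known exactly, and (iii) pairs of perturbed fluctuation matrices (D_h, D_d)
controlled by three parameters — the number N of off-diagonal fluctuation
positions, their relative magnitude Md, and the noise scale eps_D.

Construction of the perturbed pair follows the benchmark recipe: one shared
base D with uniform [0, 1] diagonal entries; N randomly chosen off-diagonal
positions each receive a magnitude uniform on [0, Md] (mirrored), and the
same magnitude is added to both incident diagonal entries; finally D_h and
D_d are the base plus independent symmetric Gaussian noise of standard
deviation eps_D * Md.  Negative or non-PSD draws are permitted (and can be
counted by the caller); the covariance generation is a linear solve and
does not require them to be projected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fluctuation import FluctuationStructure
from .lyapunov import (
    UnstableJacobianError,
    solve_covariance,
    stability_margin,
    vectorize,
)
from .network import ReactionNetwork, jacobian_structure

__all__ = [
    "KineticModel",
    "ConditionPair",
    "PerturbationComponent",
    "PerturbationSpec",
    "DPerturbationTruth",
    "ExpressionFixture",
    "generate_network",
    "make_condition_pair",
    "sample_perturbed_D_pair",
    "generate_covariance_pair",
    "generate_expression_fixture",
    "random_stable_system",
]


@dataclass
class KineticModel:
    """A mass-action instantiation of a reaction network at steady state.

    Rates are ``v_r = k_r * prod(substrates)`` with unit stoichiometry; the
    designated steady state ``M0`` is exact by construction (per-species
    balancing first-order outflow and constant inflow).
    """

    network: ReactionNetwork
    k: np.ndarray      # rate constants, one per reaction
    M0: np.ndarray     # steady-state concentrations

    def rates(self, k: np.ndarray | None = None) -> np.ndarray:
        k = self.k if k is None else np.asarray(k, dtype=float)
        net = self.network
        idx = {s: i for i, s in enumerate(net.species)}
        v = np.empty(net.n_reactions)
        for r, rid in enumerate(net.reactions):
            prod = 1.0
            for s in net.dependencies[rid]:
                prod *= self.M0[idx[s]]
            v[r] = k[r] * prod
        return v

    def jacobian(self, k: np.ndarray | None = None) -> np.ndarray:
        """``J = S . dv/dM`` at M0; dv_r/dM_j = v_r / M_j for substrates."""
        net = self.network
        idx = {s: i for i, s in enumerate(net.species)}
        v = self.rates(k)
        dvdM = np.zeros((net.n_reactions, net.n_species))
        for r, rid in enumerate(net.reactions):
            for s in net.dependencies[rid]:
                j = idx[s]
                dvdM[r, j] = v[r] / self.M0[j]
            # constant inflows have no dependencies -> zero row
        return net.S @ dvdM

    def K_diag(self, k: np.ndarray | None = None) -> np.ndarray:
        """Rate-parameter sensitivities dv_r/dk_r = v_r / k_r (diagonal K)."""
        k = self.k if k is None else np.asarray(k, dtype=float)
        return self.rates(k) / k


def generate_network(
    n: int,
    m: int,
    density: float = 0.35,
    rate_law: str = "mass_action",
    rng: np.random.Generator | None = None,
    max_tries: int = 50,
) -> KineticModel:
    """Random sparse stable mass-action network with an exact steady state.

    ``m`` core reactions draw 1-2 substrates and 1-2 products (disjoint;
    ``density`` is the probability of the bimolecular choice on each side).
    Each species additionally gets a balancing first-order outflow and
    constant inflow so that a random positive concentration vector is an
    exact steady state.

    Networks are re-drawn until the Jacobian is Hurwitz-stable *and* the
    inverse problem is structurally identifiable: the vectorized Lyapunov
    system restricted to the Jacobian pattern must have full column rank
    (fewer free entries than upper-triangle equations in every connected
    block), otherwise every constrained regression is exactly consistent
    and the loss carries no signal.
    """
    if rate_law != "mass_action":
        raise ValueError(f"unsupported rate law {rate_law!r}")
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng() if rng is None else rng

    for _ in range(max_tries):
        species = [f"M{i}" for i in range(n)]
        reactions, S_cols, deps = [], [], {}
        for r in range(m):
            n_sub = 1 + int(rng.random() < density) if n > 1 else 1
            n_prod = 1 + int(rng.random() < density)
            chosen = rng.choice(n, size=min(n, n_sub + n_prod), replace=False)
            subs, prods = chosen[:n_sub], chosen[n_sub:]
            col = np.zeros(n)
            col[subs] = -1.0
            col[prods] = 1.0
            rid = f"R{r}"
            reactions.append(rid)
            S_cols.append(col)
            deps[rid] = {species[i] for i in subs}
        k_core = rng.lognormal(mean=0.0, sigma=0.5, size=m)
        M0 = rng.uniform(0.5, 2.0, size=n)

        # net core production at M0
        phi = np.zeros(n)
        for r, rid in enumerate(reactions):
            v = k_core[r] * np.prod([M0[species.index(s)] for s in deps[rid]])
            phi += S_cols[r] * v
        # balancing outflow (first order) and constant inflow per species
        k_all = list(k_core)
        for i in range(n):
            k_out = max(0.3, phi[i] / M0[i] + 0.1)
            rid = f"out{i}"
            reactions.append(rid)
            col = np.zeros(n)
            col[i] = -1.0
            S_cols.append(col)
            deps[rid] = {species[i]}
            k_all.append(k_out)
            rid = f"in{i}"
            reactions.append(rid)
            col = np.zeros(n)
            col[i] = 1.0
            S_cols.append(col)
            deps[rid] = set()
            k_all.append(k_out * M0[i] - phi[i])  # constant inflow rate

        net = ReactionNetwork(
            species, reactions, np.column_stack(S_cols), deps
        )
        model = KineticModel(net, np.asarray(k_all), M0)
        J = model.jacobian()
        if stability_margin(J) >= -1e-9:
            continue
        pattern = jacobian_structure(net)
        p = len(pattern.nonzeros())
        if p > n * (n + 1) // 2:
            continue
        C0 = solve_covariance(J, np.diag(rng.uniform(0.5, 1.5, size=n)))
        if np.linalg.matrix_rank(vectorize(C0, pattern).A) == p:
            return model
    raise UnstableJacobianError(
        f"no stable identifiable network found in {max_tries} tries"
    )


@dataclass
class ConditionPair:
    """Two condition Jacobians sharing a zero-pattern, with ground truth."""

    J_h: np.ndarray
    J_d: np.ndarray
    changed_entries: dict[tuple[int, int], float]  # position -> |ratio|
    changed_reactions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.J_h.shape != self.J_d.shape:
            raise ValueError("condition Jacobians must share a shape")

    @property
    def n(self) -> int:
        return self.J_h.shape[0]


def make_condition_pair(
    model: KineticModel,
    changed_reactions: Sequence[str],
    factor: float = 5.0,
) -> ConditionPair:
    """Second condition by scaling selected rate constants by ``factor``.

    Both Jacobians are evaluated at the reference state, so entries fed by
    the changed reactions scale by exactly ``factor`` (mass-action
    linearity in k) and all other entries are identical.
    """
    net = model.network
    missing = set(changed_reactions) - set(net.reactions)
    if missing:
        raise ValueError(f"unknown reactions {sorted(missing)}")
    k_d = model.k.copy()
    for rid in changed_reactions:
        k_d[net.reactions.index(rid)] *= factor
    J_h = model.jacobian()
    J_d = model.jacobian(k_d)
    margin = stability_margin(J_d)
    if margin > -1e-9:
        raise UnstableJacobianError(
            f"perturbed condition unstable (max Re(eig) = {margin:.3e}); "
            "try a smaller factor"
        )
    diff = np.abs(J_h - J_d) > 1e-12
    changed = {}
    for i, j in np.argwhere(diff):
        hi, di = J_h[i, j], J_d[i, j]
        ratio = np.inf if hi == 0 or di == 0 else max(abs(di / hi), abs(hi / di))
        changed[(int(i), int(j))] = float(ratio)
    return ConditionPair(J_h, J_d, changed, list(changed_reactions))


def stable_benchmark_model(
    n: int,
    m: int,
    density: float,
    n_changed: int,
    factor: float,
    rng: np.random.Generator,
    max_tries: int = 50,
) -> tuple[KineticModel, ConditionPair]:
    """Generate a network and condition pair, retrying until both stable.

    Re-draws the changed-reaction subset (and if necessary the network)
    until the perturbed condition is also Hurwitz-stable.
    """
    last_err: Exception | None = None
    for _ in range(max_tries):
        model = generate_network(n, m, density=density, rng=rng)
        core = [r for r in model.network.reactions if r.startswith("R")]
        for _ in range(10):
            changed = [core[i] for i in
                       rng.choice(len(core), size=n_changed, replace=False)]
            try:
                return model, make_condition_pair(model, changed, factor)
            except UnstableJacobianError as err:
                last_err = err
    raise UnstableJacobianError(
        f"no stable condition pair found in {max_tries} tries: {last_err}"
    )


# ---------------------------------------------------------------------------
# perturbed fluctuation-matrix pairs


@dataclass
class PerturbationComponent:
    """One group of off-diagonal fluctuation positions.

    ``in_topology`` marks whether inference-time topological structure
    includes this group (benchmarks with mixed magnitudes give structure
    only for the large-magnitude group).
    """

    n: int
    magnitude: float
    in_topology: bool = True

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("component count must be >= 0")
        if self.magnitude <= 0:
            raise ValueError("component magnitude must be > 0")


@dataclass
class PerturbationSpec:
    """Benchmark parameters (N, Md, eps_D) for fluctuation-pair sampling."""

    components: list[PerturbationComponent]
    eps_D: float

    def __post_init__(self) -> None:
        if self.eps_D < 0:
            raise ValueError("eps_D must be >= 0")

    @classmethod
    def simple(cls, N: int, Md: float, eps_D: float) -> "PerturbationSpec":
        return cls([PerturbationComponent(N, Md)], eps_D)

    @property
    def N_total(self) -> int:
        return sum(c.n for c in self.components)

    @property
    def Md_max(self) -> float:
        return max((c.magnitude for c in self.components), default=1.0)

    @property
    def label(self) -> str:
        parts = "+".join(f"{c.n}x{c.magnitude:g}" for c in self.components)
        return f"N={parts},eps={self.eps_D:g}"


@dataclass
class DPerturbationTruth:
    """Ground truth of one sampled fluctuation-matrix pair."""

    positions: list[tuple[int, int]]           # chosen upper-triangle positions
    signs: dict[tuple[int, int], int]
    magnitudes: dict[tuple[int, int], float]   # drawn base magnitudes
    caps: dict[tuple[int, int], float]         # Md of the owning component
    in_topology: dict[tuple[int, int], bool]
    base: np.ndarray
    n: int

    def topological_structure(self, diag_scale: float = 1.0) -> FluctuationStructure:
        """Sign structure over the positions flagged for topology."""
        sign = np.zeros((self.n, self.n), dtype=int)
        np.fill_diagonal(sign, 1)
        for (i, j) in self.positions:
            if self.in_topology[(i, j)]:
                sign[i, j] = sign[j, i] = self.signs[(i, j)]
        return FluctuationStructure(sign, diag_scale=diag_scale)

    def integrative_structure(self, diag_scale: float = 1.0) -> FluctuationStructure:
        """Sign structure over all positions with per-entry magnitude caps.

        Only off-diagonal entries are bounded (by the owning component's
        magnitude cap, standing in for the enzyme-activity variance);
        diagonal entries keep the usual [0, diag_scale] sampling range.
        """
        sign = np.zeros((self.n, self.n), dtype=int)
        np.fill_diagonal(sign, 1)
        bounds = np.zeros((self.n, self.n))
        for (i, j) in self.positions:
            sign[i, j] = sign[j, i] = self.signs[(i, j)]
            bounds[i, j] = bounds[j, i] = self.caps[(i, j)]
        return FluctuationStructure(sign, bounds=bounds, diag_scale=diag_scale)


def sample_perturbed_D_pair(
    n: int,
    spec: PerturbationSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, DPerturbationTruth]:
    """Draw a perturbed fluctuation-matrix pair with known structure.

    Shared base: diagonal uniform [0, 1]; N chosen off-diagonal positions
    get a magnitude uniform [0, Md] with a random sign (mirrored), the
    unsigned magnitude added to both incident diagonals.  D_h and D_d are
    the base plus independent symmetric Gaussian noise, sd = eps_D * Md.
    """
    max_pairs = n * (n - 1) // 2
    if spec.N_total > max_pairs:
        raise ValueError(
            f"requested {spec.N_total} off-diagonal positions, only "
            f"{max_pairs} exist for n={n}"
        )
    base = np.diag(rng.uniform(0.0, 1.0, size=n))
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen_idx = rng.choice(len(all_pairs), size=spec.N_total, replace=False)
    positions, signs, mags, caps, in_topo = [], {}, {}, {}, {}
    cursor = 0
    for comp in spec.components:
        for t in range(comp.n):
            i, j = all_pairs[chosen_idx[cursor]]
            cursor += 1
            u = rng.uniform(0.0, comp.magnitude)
            s = int(rng.choice([-1, 1]))
            base[i, j] = base[j, i] = s * u
            base[i, i] += u
            base[j, j] += u
            positions.append((i, j))
            signs[(i, j)] = s
            mags[(i, j)] = u
            caps[(i, j)] = comp.magnitude
            in_topo[(i, j)] = comp.in_topology
    sd = spec.eps_D * spec.Md_max

    def _noisy() -> np.ndarray:
        if sd == 0:
            return base.copy()
        G = np.zeros((n, n))
        iu = np.triu_indices(n)
        G[iu] = rng.normal(0.0, sd, size=len(iu[0]))
        return base + G + np.triu(G, 1).T

    D_h, D_d = _noisy(), _noisy()
    truth = DPerturbationTruth(positions, signs, mags, caps, in_topo, base, n)
    return D_h, D_d, truth


def generate_covariance_pair(
    pair: ConditionPair, D_h: np.ndarray, D_d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Forward Lyapunov solves for the two conditions."""
    return solve_covariance(pair.J_h, D_h), solve_covariance(pair.J_d, D_d)


def random_stable_system(
    n: int, rng: np.random.Generator, density: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Random Hurwitz-stable (J, D) pair for oracle/property testing.

    J is a (optionally sparsified) Gaussian matrix shifted to have its
    spectrum strictly in the left half plane; D is a random symmetric PSD
    matrix with a strictly positive diagonal.
    """
    J = rng.normal(size=(n, n))
    if density < 1.0:
        mask = rng.random((n, n)) < density
        np.fill_diagonal(mask, True)
        J = J * mask
    J = J - (np.max(np.real(np.linalg.eigvals(J))) + rng.uniform(0.5, 1.5)) * np.eye(n)
    W = rng.normal(size=(n, n))
    D = W @ W.T / n + 0.1 * np.eye(n)
    return J, D


# ---------------------------------------------------------------------------
# expression fixture for the enzyme-activity mapping


@dataclass
class ExpressionFixture:
    """Synthetic expression + GPR fixture with closed-form activity variances.

    AND rules are built with one dominant gene (means separated by eight
    pooled standard deviations) so the max reduces to that gene almost
    surely, keeping the ground-truth variance in closed form.
    """

    expression: pd.DataFrame            # genes x samples
    condition_of: dict[str, str]        # sample -> condition
    rules: list[tuple[str, str]]        # (reaction_id, rule text)
    true_variances: pd.DataFrame        # reactions x conditions


def generate_expression_fixture(
    m_reactions: int,
    n_genes: int,
    samples_per_condition: int,
    rng: np.random.Generator,
    conditions: tuple[str, str] = ("h", "d"),
) -> ExpressionFixture:
    """Expression table, GPR rules and closed-form activity variances.

    Rules cycle through four shapes — single gene, OR of two, AND of two
    (dominant first gene), and (AND) OR single — with disjoint gene sets so
    activities are sums/maxima of independent genes.
    """
    if m_reactions < 1 or samples_per_condition < 2:
        raise ValueError("need >= 1 reaction and >= 2 samples per condition")
    shapes = [1, 2, 2, 3]
    needed = sum(shapes[r % 4] for r in range(m_reactions))
    if n_genes < needed:
        raise ValueError(
            f"need at least {needed} genes for {m_reactions} reactions"
        )
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [
        f"{c}{s}" for c in conditions for s in range(samples_per_condition)
    ]
    condition_of = {
        f"{c}{s}": c for c in conditions for s in range(samples_per_condition)
    }
    mu = {(g, c): rng.uniform(5.0, 10.0) for g in genes for c in conditions}
    sd = {(g, c): rng.uniform(0.5, 2.0) for g in genes for c in conditions}

    rules: list[tuple[str, str]] = []
    var_rows = {}
    cursor = 0
    for r in range(m_reactions):
        rid = f"R{r}"
        shape = shapes[r % 4]
        gs = genes[cursor:cursor + shape]
        cursor += shape
        if shape == 1:
            rules.append((rid, gs[0]))
            var_rows[rid] = {c: sd[(gs[0], c)] ** 2 for c in conditions}
        elif shape == 2 and r % 4 == 1:  # OR
            rules.append((rid, f"{gs[0]} or {gs[1]}"))
            var_rows[rid] = {
                c: sd[(gs[0], c)] ** 2 + sd[(gs[1], c)] ** 2 for c in conditions
            }
        elif shape == 2:  # AND with dominant first gene
            for c in conditions:
                mu[(gs[0], c)] = mu[(gs[1], c)] + 8.0 * (
                    sd[(gs[0], c)] + sd[(gs[1], c)]
                )
            rules.append((rid, f"{gs[0]} and {gs[1]}"))
            var_rows[rid] = {c: sd[(gs[0], c)] ** 2 for c in conditions}
        else:  # (AND) OR single
            for c in conditions:
                mu[(gs[0], c)] = mu[(gs[1], c)] + 8.0 * (
                    sd[(gs[0], c)] + sd[(gs[1], c)]
                )
            rules.append((rid, f"({gs[0]} and {gs[1]}) or {gs[2]}"))
            var_rows[rid] = {
                c: sd[(gs[0], c)] ** 2 + sd[(gs[2], c)] ** 2 for c in conditions
            }

    data = np.empty((n_genes, len(samples)))
    for gi, g in enumerate(genes):
        for si, s in enumerate(samples):
            c = condition_of[s]
            data[gi, si] = rng.normal(mu[(g, c)], sd[(g, c)])
    expression = pd.DataFrame(data, index=genes, columns=samples)
    true_variances = pd.DataFrame(var_rows).T[list(conditions)]
    true_variances.index.name = "reaction_id"
    return ExpressionFixture(expression, condition_of, rules, true_variances)
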