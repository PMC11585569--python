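"""Reaction networks and the structural patterns they induce.

A metabolic network near steady state is summarised by its stoichiometric
matrix ``S`` (n species x m reactions) and, for each reaction, the set of
species its rate depends on.  Two structural objects are derived from this:

* the zero-pattern of the Jacobian ``J = S . dv/dM`` — entry (i, j) may be
  nonzero only if some reaction both changes species i and depends on
  species j;
* the zero/sign pattern of the fluctuation matrix ``D`` when noise enters
  through reaction parameters — species sharing a reaction receive
  correlated forcing, negative when they sit on opposite reaction sides and
  positive when on the same side.

When only a subset of metabolites is measured, interactions are condensed
superpathways: multi-step paths through unmeasured intermediates.  The sign
of the corresponding ``D`` entry is ``(-1)**(k + 1)`` with ``k`` the number
of same-side (type-2) steps along the path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INDETERMINATE",
    "ReactionNetwork",
    "JacobianStructure",
    "Superpathway",
    "InteractionNetwork",
    "jacobian_structure",
    "d_sign_structure",
    "read_network_tsv",
    "write_network_tsv",
    "read_interactions_tsv",
    "write_interactions_tsv",
]

#: Sign code for off-diagonal fluctuation entries whose sign cannot be
#: resolved from structure alone (conflicting contributions from several
#: shared reactions).  Samplers draw a random +/-1 for such entries.
INDETERMINATE = 2


@dataclass
class ReactionNetwork:
    """A stoichiometric network with rate dependencies.

    Parameters
    ----------
    species
        Ordered metabolite identifiers; fixes row indexing of all matrices.
    reactions
        Ordered reaction identifiers, unique.
    S
        Stoichiometric coefficients, shape ``(n_species, n_reactions)``.
    dependencies
        For each reaction id, the set of species its rate depends on.
    enzyme_of
        Optional reaction id -> enzyme/parameter identifier.  One parameter
        per reaction (diagonal ``K``); defaults to the reaction id itself.
    """

    species: list[str]
    reactions: list[str]
    S: np.ndarray
    dependencies: dict[str, set[str]]
    enzyme_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n, m = len(self.species), len(self.reactions)
        if self.S.shape != (n, m):
            raise ValueError(
                f"S has shape {self.S.shape}, expected ({n}, {m})"
            )
        if len(set(self.reactions)) != m:
            raise ValueError("reaction identifiers must be unique")
        if len(set(self.species)) != n:
            raise ValueError("species identifiers must be unique")
        known = set(self.species)
        for rid, deps in self.dependencies.items():
            if rid not in set(self.reactions):
                raise ValueError(f"dependency given for unknown reaction {rid!r}")
            missing = set(deps) - known
            if missing:
                raise ValueError(
                    f"reaction {rid!r} depends on unknown species {sorted(missing)}"
                )
        for rid in self.reactions:
            self.dependencies.setdefault(rid, set())
            self.enzyme_of.setdefault(rid, rid)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def dependency_matrix(self) -> np.ndarray:
        """Indicator matrix ``(m, n)``: reaction r depends on species j."""
        dep = np.zeros((self.n_reactions, self.n_species), dtype=int)
        idx = {s: i for i, s in enumerate(self.species)}
        for r, rid in enumerate(self.reactions):
            for s in self.dependencies[rid]:
                dep[r, idx[s]] = 1
        return dep

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "reactions": list(self.reactions),
            "S": self.S.tolist(),
            "dependencies": {r: sorted(d) for r, d in self.dependencies.items()},
            "enzyme_of": dict(self.enzyme_of),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReactionNetwork":
        return cls(
            species=list(d["species"]),
            reactions=list(d["reactions"]),
            S=np.asarray(d["S"], dtype=float),
            dependencies={r: set(v) for r, v in d["dependencies"].items()},
            enzyme_of=dict(d.get("enzyme_of", {})),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ReactionNetwork":
        return cls.from_dict(json.loads(s))


@dataclass
class JacobianStructure:
    """Zero-pattern of the steady-state Jacobian: 1 = may be nonzero."""

    pattern: np.ndarray
    species: list[str] | None = None

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=int)
        n = self.pattern.shape[0]
        if self.pattern.shape != (n, n):
            raise ValueError("pattern must be square")
        if not np.isin(self.pattern, (0, 1)).all():
            raise ValueError("pattern entries must be 0 or 1")

    @property
    def n(self) -> int:
        return self.pattern.shape[0]

    def nonzeros(self) -> list[tuple[int, int]]:
        """Free positions in row-major order (fixes the unknown ordering)."""
        return [tuple(ij) for ij in np.argwhere(self.pattern)]

    def to_dict(self) -> dict:
        return {"pattern": self.pattern.tolist(), "species": self.species}

    @classmethod
    def from_dict(cls, d: Mapping) -> "JacobianStructure":
        return cls(np.asarray(d["pattern"]), d.get("species"))


@dataclass
class Superpathway:
    """A condensed multi-step interaction between two measured metabolites.

    ``step_types`` lists, in order, 1 for steps whose interface metabolites
    lie on opposite sides of the reaction and 2 for same-side steps.
    """

    source: str
    target: str
    step_types: list[int]
    reactions: list[str] = field(default_factory=list)
    sign_override: int | None = None

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("superpathway endpoints must be distinct")
        if len(self.step_types) < 1:
            raise ValueError("superpathway needs at least one step")
        if not all(t in (1, 2) for t in self.step_types):
            raise ValueError("step types must be 1 or 2")
        if self.sign_override not in (None, -1, 1, INDETERMINATE):
            raise ValueError("sign_override must be -1, +1 or INDETERMINATE")

    @property
    def n_type2(self) -> int:
        return sum(1 for t in self.step_types if t == 2)

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "target": self.target,
            "step_types": list(self.step_types),
            "reactions": list(self.reactions),
            "sign_override": self.sign_override,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Superpathway":
        return cls(
            d["source"], d["target"], list(d["step_types"]),
            list(d.get("reactions", [])), d.get("sign_override"),
        )


@dataclass
class InteractionNetwork:
    """Measured-metabolite interaction network (superpathway condensation).

    This is the form in which upstream network-reconstruction pipelines hand
    over structure: one record per interaction with its step composition and
    the reactions/enzymes traversed.
    """

    species: list[str]
    superpathways: list[Superpathway]

    def __post_init__(self) -> None:
        known = set(self.species)
        for sp in self.superpathways:
            if sp.source not in known or sp.target not in known:
                raise ValueError(
                    f"superpathway {sp.source}->{sp.target} references "
                    "unlisted species"
                )

    @property
    def n(self) -> int:
        return len(self.species)

    def jacobian_structure(self) -> JacobianStructure:
        """Symmetric zero-pattern: endpoints of each interaction, plus diagonal."""
        n = self.n
        idx = {s: i for i, s in enumerate(self.species)}
        pat = np.eye(n, dtype=int)
        for sp in self.superpathways:
            i, j = idx[sp.source], idx[sp.target]
            pat[i, j] = pat[j, i] = 1
        return JacobianStructure(pat, species=list(self.species))

    def sign_structure(self) -> np.ndarray:
        """Fluctuation sign matrix from the superpathway sign rule.

        Returns an ``(n, n)`` int matrix over {-1, 0, +1, INDETERMINATE};
        diagonal +1.  Conflicting parallel superpathways between the same
        endpoints are flagged INDETERMINATE.
        """
        from .fluctuation import superpathway_sign  # local to avoid cycle

        n = self.n
        idx = {s: i for i, s in enumerate(self.species)}
        sign = np.zeros((n, n), dtype=int)
        np.fill_diagonal(sign, 1)
        for sp in self.superpathways:
            s = sp.sign_override if sp.sign_override is not None else superpathway_sign(sp)
            i, j = idx[sp.source], idx[sp.target]
            prev = sign[i, j]
            if prev != 0 and prev != s:
                s = INDETERMINATE
            sign[i, j] = sign[j, i] = s
        return sign

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "superpathways": [sp.to_dict() for sp in self.superpathways],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "InteractionNetwork":
        return cls(
            list(d["species"]),
            [Superpathway.from_dict(x) for x in d["superpathways"]],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "InteractionNetwork":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# structural derivations


def jacobian_structure(net: ReactionNetwork) -> JacobianStructure:
    """Zero-pattern of ``J = S . dv/dM`` from stoichiometry and dependencies.

    ``pattern[i, j] = 1`` iff some reaction r has ``S[i, r] != 0`` and its
    rate depends on species j.
    """
    dep = net.dependency_matrix()  # (m, n)
    pattern = ((np.abs(net.S) > 0).astype(int) @ dep > 0).astype(int)
    return JacobianStructure(pattern, species=list(net.species))


def d_sign_structure(net: ReactionNetwork) -> np.ndarray:
    """Zero/sign pattern of the parameter-noise part of ``D``.

    Off-diagonal (i, j) is nonzero iff species i and j share a reaction; a
    single shared reaction r contributes ``sign(S[i, r] * S[j, r])``
    (negative for opposite sides, positive for same side).  Agreeing
    contributions keep their common sign; conflicting contributions are
    flagged :data:`INDETERMINATE` rather than silently resolved.  Diagonal
    entries are +1.
    """
    S = net.S
    n = net.n_species
    sign = np.zeros((n, n), dtype=int)
    np.fill_diagonal(sign, 1)
    for i in range(n):
        for j in range(i + 1, n):
            contrib = {
                int(np.sign(S[i, r] * S[j, r]))
                for r in range(net.n_reactions)
                if S[i, r] != 0 and S[j, r] != 0
            }
            contrib.discard(0)
            if not contrib:
                continue
            s = contrib.pop() if len(contrib) == 1 else INDETERMINATE
            sign[i, j] = sign[j, i] = s
    return sign


# ---------------------------------------------------------------------------
# TSV interfaces


def read_network_tsv(path, enzymes_path=None) -> ReactionNetwork:
    """Read a reaction network from a TSV edge list.

    Columns: ``reaction_id, species_id, stoich_coeff, is_dependency`` —
    one row per (reaction, species) incidence.  A species may appear with
    zero stoichiometry if the rate merely depends on it.  ``enzymes_path``
    optionally maps ``reaction_id -> enzyme_id`` (two TSV columns).
    """
    df = pd.read_csv(path, sep="\t", dtype={"reaction_id": str, "species_id": str})
    required = {"reaction_id", "species_id", "stoich_coeff", "is_dependency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"network TSV missing columns {sorted(missing)}")
    species = list(dict.fromkeys(df["species_id"]))
    reactions = list(dict.fromkeys(df["reaction_id"]))
    sidx = {s: i for i, s in enumerate(species)}
    ridx = {r: i for i, r in enumerate(reactions)}
    S = np.zeros((len(species), len(reactions)))
    deps: dict[str, set[str]] = {r: set() for r in reactions}
    for row in df.itertuples(index=False):
        S[sidx[row.species_id], ridx[row.reaction_id]] = float(row.stoich_coeff)
        if int(row.is_dependency):
            deps[row.reaction_id].add(row.species_id)
    enzyme_of = {}
    if enzymes_path is not None:
        edf = pd.read_csv(enzymes_path, sep="\t", dtype=str)
        enzyme_of = dict(zip(edf["reaction_id"], edf["enzyme_id"]))
    return ReactionNetwork(species, reactions, S, deps, enzyme_of)


def write_network_tsv(net: ReactionNetwork, path, enzymes_path=None) -> None:
    rows = []
    for r, rid in enumerate(net.reactions):
        touched = set(np.flatnonzero(net.S[:, r]))
        touched |= {net.species_index(s) for s in net.dependencies[rid]}
        for i in sorted(touched):
            sp = net.species[i]
            rows.append(
                {
                    "reaction_id": rid,
                    "species_id": sp,
                    "stoich_coeff": net.S[i, r],
                    "is_dependency": int(sp in net.dependencies[rid]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if enzymes_path is not None:
        pd.DataFrame(
            {"reaction_id": net.reactions,
             "enzyme_id": [net.enzyme_of[r] for r in net.reactions]}
        ).to_csv(enzymes_path, sep="\t", index=False)


def read_interactions_tsv(path) -> InteractionNetwork:
    """Read an interaction network TSV.

    Columns: ``source, target, n_type2_steps, reaction_ids, sign_override``.
    ``reaction_ids`` is a comma-separated list (also sets the step count;
    steps beyond the type-2 count are type 1).  ``sign_override`` is empty,
    -1, 1, or the word ``indeterminate``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"source", "target", "n_type2_steps", "reaction_ids"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interaction TSV missing columns {sorted(missing)}")
    species: list[str] = []
    sps = []
    for row in df.itertuples(index=False):
        for s in (row.source, row.target):
            if s not in species:
                species.append(s)
        rids = [x for x in str(row.reaction_ids).split(",") if x]
        k2 = int(row.n_type2_steps)
        n_steps = max(len(rids), k2, 1)
        step_types = [2] * k2 + [1] * (n_steps - k2)
        ov_raw = getattr(row, "sign_override", "")
        if ov_raw in ("", "nan"):
            override = None
        elif str(ov_raw).lower().startswith("indet"):
            override = INDETERMINATE
        else:
            override = int(float(ov_raw))
        sps.append(Superpathway(row.source, row.target, step_types, rids, override))
    return InteractionNetwork(species, sps)


def write_interactions_tsv(inet: InteractionNetwork, path) -> None:
    rows = []
    for sp in inet.superpathways:
        if sp.sign_override is None:
            ov = ""
        elif sp.sign_override == INDETERMINATE:
            ov = "indeterminate"
        else:
            ov = str(sp.sign_override)
        rows.append(
            {
                "source": sp.source,
                "target": sp.target,
                "n_type2_steps": sp.n_type2,
                "reaction_ids": ",".join(sp.reactions),
                "sign_override": ov,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
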