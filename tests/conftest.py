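import numpy as np
import pytest

from invjac.network import ReactionNetwork


@pytest.fixture
def chain_net() -> ReactionNetwork:
    """Two species, one reaction A -> B whose rate depends on A."""
    return ReactionNetwork(
        species=["A", "B"],
        reactions=["r1"],
        S=np.array([[-1.0], [1.0]]),
        dependencies={"r1": {"A"}},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_network(rng, n=6, m=8):
    """Random stoichiometry + dependencies, structure only (no kinetics)."""
    species = [f"M{i}" for i in range(n)]
    reactions = [f"R{r}" for r in range(m)]
    S = np.zeros((n, m))
    deps = {}
    for r, rid in enumerate(reactions):
        k = rng.integers(1, 4)
        rows = rng.choice(n, size=k, replace=False)
        S[rows, r] = rng.choice([-2, -1, 1, 2], size=k)
        deps[rid] = {species[i] for i in rng.choice(n, size=rng.integers(1, 3),
                                                    replace=False)}
    return ReactionNetwork(species, reactions, S, deps)
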