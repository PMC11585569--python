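"""Derive Jacobian and fluctuation-matrix structure from a reaction network.

Builds a 4-metabolite toy pathway (A -> B -> C, plus the condensation
A + C -> D) and prints the two structural objects the inference relies on:
the Jacobian zero-pattern (which interactions may exist at all) and the
zero/sign pattern of the fluctuation matrix D (how enzyme noise couples
metabolites: negative across a reaction, positive on the same side).
"""

import numpy as np

from invjac import (
    FluctuationModel,
    ReactionNetwork,
    build_D,
    d_sign_structure,
    jacobian_structure,
)

net = ReactionNetwork(
    species=["A", "B", "C", "D"],
    reactions=["v1", "v2", "v3"],
    S=np.array([
        [-1, 0, -1],   # A consumed by v1 and v3
        [1, -1, 0],    # B produced by v1, consumed by v2
        [0, 1, -1],    # C produced by v2, consumed by v3
        [0, 0, 1],     # D produced by v3
    ], dtype=float),
    dependencies={"v1": {"A"}, "v2": {"B"}, "v3": {"A", "C"}},
)

pattern = jacobian_structure(net)
print("Jacobian zero-pattern (rows react to columns):")
print(pattern.pattern)

sign = d_sign_structure(net)
print("\nFluctuation sign structure (-1 opposite sides, +1 same side):")
print(sign)

# a concrete D for unit parameter noise on every reaction plus direct
# metabolite noise of variance 0.5
model = FluctuationModel(
    D1_diag=np.full(4, 0.5), D2_diag=np.ones(3), K_diag=np.ones(3)
)
D = build_D(net, model)
print("\nFluctuation matrix D = S.K.D2.K^T.S^T + D1:")
print(D)
print("\nNote how A and C (co-substrates of v3) get a positive coupling,"
      "\nwhile substrate/product pairs couple negatively.")
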