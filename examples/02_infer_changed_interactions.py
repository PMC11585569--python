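"""Infer which metabolic interactions changed between two conditions.

Generates a synthetic benchmark instance (a stable 8-metabolite mass-action
network; one reaction's rate constant scaled 5-fold in the second
condition), computes the two steady-state covariance matrices through the
Lyapunov equation, and runs the regression-loss inference with
structure-aware fluctuation sampling.  Entries near 1 in the printed R*
matrix flag interactions whose kinetics changed.
"""

import numpy as np

from invjac import (
    PerturbationSpec,
    TopologicalSampler,
    generate_covariance_pair,
    jacobian_structure,
    regression_loss_matrix,
)
from invjac.synth import sample_perturbed_D_pair, stable_benchmark_model

rng = np.random.default_rng(1)
model, pair = stable_benchmark_model(
    n=8, m=7, density=0.2, n_changed=1, factor=5.0, rng=rng
)
pattern = jacobian_structure(model.network)
changed = sorted(p for p in pair.changed_entries if p[0] != p[1])
print("ground-truth changed interactions (row, col):", changed)

# condition-specific fluctuations: 2 off-diagonal positions, mild noise
spec = PerturbationSpec.simple(N=2, Md=1.0, eps_D=0.1)
D_h, D_d, truth = sample_perturbed_D_pair(pair.n, spec, rng)
C_h, C_d = generate_covariance_pair(pair, D_h, D_d)

result = regression_loss_matrix(
    C_h, C_d, pattern,
    TopologicalSampler(truth.topological_structure()),
    n_samples=1000, seed=0,
)
np.set_printoptions(precision=2, suppress=True)
print("\nnormalized regression-loss matrix R* (NaN = structurally absent):")
print(result.R)
print("\nlargest loss at:", result.argmax(),
      "-> correctly flagged" if result.argmax() in set(changed)
      else "-> a false positive this run")
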