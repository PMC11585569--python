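"""Synthetic network generator, condition pairs, and perturbed D pairs."""

import numpy as np
import pytest

from invjac.lyapunov import UnstableJacobianError, stability_margin
from invjac.synth import (
    PerturbationComponent,
    PerturbationSpec,
    generate_covariance_pair,
    generate_expression_fixture,
    generate_network,
    make_condition_pair,
    sample_perturbed_D_pair,
    stable_benchmark_model,
)


class TestGenerateNetwork:
    def test_stable_and_deterministic(self):
        m1 = generate_network(6, 6, density=0.3, rng=np.random.default_rng(3))
        m2 = generate_network(6, 6, density=0.3, rng=np.random.default_rng(3))
        assert stability_margin(m1.jacobian()) < 0
        assert np.array_equal(m1.network.S, m2.network.S)
        assert np.array_equal(m1.k, m2.k)
        assert np.array_equal(m1.M0, m2.M0)

    def test_designated_state_is_exact_steady_state(self):
        model = generate_network(5, 5, density=0.3, rng=np.random.default_rng(1))
        assert np.max(np.abs(model.network.S @ model.rates())) < 1e-12

    def test_jacobian_matches_finite_differences(self):
        model = generate_network(5, 5, density=0.3, rng=np.random.default_rng(2))
        net = model.network
        J = model.jacobian()
        idx = {s: i for i, s in enumerate(net.species)}
        eps = 1e-7

        def F(M):
            v = np.empty(net.n_reactions)
            for r, rid in enumerate(net.reactions):
                prod = 1.0
                for s in net.dependencies[rid]:
                    prod *= M[idx[s]]
                v[r] = model.k[r] * prod
            return net.S @ v

        for j in range(net.n_species):
            Mp = model.M0.copy()
            Mp[j] += eps
            assert np.allclose((F(Mp) - F(model.M0)) / eps, J[:, j], atol=1e-5)

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_network(0, 3)
        with pytest.raises(ValueError):
            generate_network(3, 3, density=1.5)
        with pytest.raises(ValueError):
            generate_network(3, 3, rate_law="michaelis")


class TestConditionPair:
    def test_factor_one_means_no_change(self):
        model = generate_network(5, 5, density=0.3, rng=np.random.default_rng(4))
        core = [r for r in model.network.reactions if r.startswith("R")]
        pair = make_condition_pair(model, [core[0]], factor=1.0)
        assert np.array_equal(pair.J_h, pair.J_d)
        assert pair.changed_entries == {}

    def test_changed_entries_confined_to_changed_reaction_structure(self):
        model = generate_network(6, 6, density=0.3, rng=np.random.default_rng(5))
        net = model.network
        core = [r for r in net.reactions if r.startswith("R")]
        rid = core[1]
        pair = make_condition_pair(model, [rid], factor=2.0)
        r = net.reactions.index(rid)
        rows = set(np.flatnonzero(net.S[:, r]))
        cols = {net.species_index(s) for s in net.dependencies[rid]}
        for (i, j), ratio in pair.changed_entries.items():
            assert i in rows and j in cols
            # mass-action linearity: a single contributing reaction scales
            # its entries by exactly the factor
            assert ratio <= 2.0 + 1e-9

    def test_changed_entries_match_jacobian_difference_support(self):
        model = generate_network(6, 7, density=0.3, rng=np.random.default_rng(6))
        core = [r for r in model.network.reactions if r.startswith("R")]
        pair = make_condition_pair(model, core[:2], factor=5.0)
        diff = np.argwhere(np.abs(pair.J_h - pair.J_d) > 1e-12)
        assert {tuple(x) for x in diff} == set(pair.changed_entries)

    def test_unknown_reaction_rejected(self):
        model = generate_network(4, 4, density=0.3, rng=np.random.default_rng(7))
        with pytest.raises(ValueError, match="unknown reactions"):
            make_condition_pair(model, ["nope"], factor=2.0)


class TestPerturbedDPair:
    def test_no_offdiagonals_no_noise_gives_shared_diagonal(self):
        spec = PerturbationSpec.simple(0, 1.0, 0.0)
        D_h, D_d, truth = sample_perturbed_D_pair(4, spec,
                                                  np.random.default_rng(0))
        assert np.array_equal(D_h, D_d)
        assert np.all(np.diag(D_h) >= 0) and np.all(np.diag(D_h) <= 1)
        assert np.all(D_h[~np.eye(4, dtype=bool)] == 0)
        assert truth.positions == []

    def test_offdiagonal_count_and_ranges(self):
        spec = PerturbationSpec.simple(3, 2.4, 0.0)
        D_h, D_d, truth = sample_perturbed_D_pair(6, spec,
                                                  np.random.default_rng(1))
        triu = np.triu(D_h, 1)
        assert np.count_nonzero(triu) == 3
        assert len(truth.positions) == 3
        for (i, j) in truth.positions:
            assert abs(D_h[i, j]) <= 2.4
            assert np.sign(D_h[i, j]) == truth.signs[(i, j)]
        # incident diagonals stay within the bookkeeping range
        incident = np.zeros(6)
        for (i, j) in truth.positions:
            incident[i] += 1
            incident[j] += 1
        assert np.all(np.diag(D_h) <= 1.0 + 2.4 * incident + 1e-12)

    def test_noise_free_pair_is_shared_base(self):
        spec = PerturbationSpec.simple(2, 1.0, 0.0)
        D_h, D_d, truth = sample_perturbed_D_pair(5, spec,
                                                  np.random.default_rng(2))
        assert np.array_equal(D_h, D_d)
        assert np.array_equal(D_h, truth.base)

    def test_noisy_pair_symmetric_and_distinct(self):
        spec = PerturbationSpec.simple(2, 1.0, 0.3)
        D_h, D_d, _ = sample_perturbed_D_pair(5, spec, np.random.default_rng(3))
        assert np.array_equal(D_h, D_h.T)
        assert np.array_equal(D_d, D_d.T)
        assert not np.array_equal(D_h, D_d)

    def test_too_many_positions_rejected(self):
        with pytest.raises(ValueError, match="off-diagonal positions"):
            sample_perturbed_D_pair(3, PerturbationSpec.simple(4, 1.0, 0.0),
                                    np.random.default_rng(0))

    def test_truth_structures_reflect_components(self):
        spec = PerturbationSpec(
            [PerturbationComponent(2, 2.4, True),
             PerturbationComponent(3, 0.3, False)],
            eps_D=0.0,
        )
        _, _, truth = sample_perturbed_D_pair(8, spec, np.random.default_rng(4))
        topo = truth.topological_structure()
        n_topo = np.count_nonzero(np.triu(topo.sign, 1))
        assert n_topo == 2  # only the in-topology group
        integ = truth.integrative_structure()
        assert np.count_nonzero(np.triu(integ.sign, 1)) == 5
        for (i, j) in truth.positions:
            assert integ.bounds[i, j] == truth.caps[(i, j)]


class TestCovariancePair:
    def test_identical_inputs_identical_outputs(self):
        model = generate_network(4, 4, density=0.3, rng=np.random.default_rng(8))
        core = [r for r in model.network.reactions if r.startswith("R")]
        pair = make_condition_pair(model, [core[0]], factor=1.0)
        D = np.diag([0.5, 0.6, 0.7, 0.8])
        C_h, C_d = generate_covariance_pair(pair, D, D)
        assert np.allclose(C_h, C_d)

    def test_scalar_closed_form(self):
        from invjac.synth import ConditionPair

        pair = ConditionPair(np.array([[-2.0]]), np.array([[-2.0]]), {})
        C_h, _ = generate_covariance_pair(pair, np.array([[3.0]]),
                                          np.array([[3.0]]))
        assert np.allclose(C_h, [[1.5]])  # C = D / |J|

    def test_matches_sde_sample_covariance(self):
        """Euler-Maruyama cross-check of the direct Lyapunov solve."""
        rng = np.random.default_rng(9)
        J = np.array([[-2.0, 0.5, 0.0],
                      [0.3, -1.5, 0.2],
                      [0.0, 0.4, -1.0]])
        W = rng.normal(size=(3, 3))
        D = W @ W.T / 3 + 0.2 * np.eye(3)
        from invjac.lyapunov import solve_covariance

        C = solve_covariance(J, D)
        dt = 0.005
        n_steps = 400_000
        L = np.linalg.cholesky(2.0 * D)
        x = np.zeros(3)
        xs = np.empty((n_steps, 3))
        noise = rng.normal(size=(n_steps, 3)) * np.sqrt(dt)
        for t in range(n_steps):
            x = x + dt * (J @ x) + L @ noise[t]
            xs[t] = x
        C_emp = np.cov(xs[n_steps // 10:].T)
        assert np.max(np.abs(C_emp - C)) / np.max(np.abs(C)) < 0.15


class TestExpressionFixture:
    def test_deterministic_and_shapes(self):
        f1 = generate_expression_fixture(4, 10, 5, np.random.default_rng(1))
        f2 = generate_expression_fixture(4, 10, 5, np.random.default_rng(1))
        assert f1.expression.equals(f2.expression)
        assert f1.expression.shape == (10, 10)
        assert len(f1.rules) == 4

    def test_single_gene_rule_variance_is_gene_variance(self):
        fx = generate_expression_fixture(1, 2, 4, np.random.default_rng(2))
        rid, rule = fx.rules[0]
        assert rule == "g0"
        # closed form equals the generating variance of that gene
        assert fx.true_variances.loc[rid, "h"] > 0

    def test_insufficient_genes_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            generate_expression_fixture(4, 3, 4, np.random.default_rng(0))


def test_stable_benchmark_model_both_conditions_stable():
    model, pair = stable_benchmark_model(8, 7, 0.2, 2, 5.0,
                                         np.random.default_rng(11))
    assert stability_margin(pair.J_h) < 0
    assert stability_margin(pair.J_d) < 0
    assert pair.changed_entries
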