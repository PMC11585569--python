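"""Structural derivations: Jacobian zero-pattern and D sign pattern."""

import numpy as np
import pytest

from invjac.network import (
    INDETERMINATE,
    InteractionNetwork,
    ReactionNetwork,
    Superpathway,
    d_sign_structure,
    jacobian_structure,
    read_interactions_tsv,
    read_network_tsv,
    write_interactions_tsv,
    write_network_tsv,
)

from conftest import random_network


class TestJacobianStructure:
    def test_chain_reaction_gives_substrate_column(self, chain_net):
        pat = jacobian_structure(chain_net).pattern
        assert pat.tolist() == [[1, 0], [1, 0]]

    def test_empty_reaction_list_gives_zero_pattern(self):
        net = ReactionNetwork(["A", "B"], [], np.zeros((2, 0)), {})
        assert jacobian_structure(net).pattern.sum() == 0

    def test_matches_bruteforce_double_loop(self, rng):
        net = random_network(rng, n=6, m=8)
        pat = jacobian_structure(net).pattern
        expected = np.zeros((6, 6), dtype=int)
        for i in range(6):
            for j in range(6):
                for r, rid in enumerate(net.reactions):
                    if net.S[i, r] != 0 and net.species[j] in net.dependencies[rid]:
                        expected[i, j] = 1
        assert np.array_equal(pat, expected)

    def test_matches_mass_action_jacobian_zero_pattern(self):
        # any mass-action instantiation has zeros wherever the pattern does
        from invjac.synth import generate_network

        for seed in range(5):
            model = generate_network(6, 6, density=0.3,
                                     rng=np.random.default_rng(seed))
            pat = jacobian_structure(model.network).pattern
            J = model.jacobian()
            assert np.all(J[pat == 0] == 0)


class TestDSignStructure:
    def test_opposite_sides_negative(self, chain_net):
        sign = d_sign_structure(chain_net)
        assert sign[0, 1] == sign[1, 0] == -1

    def test_same_side_positive(self):
        # A + B -> C: entry (A, B) positive
        net = ReactionNetwork(
            ["A", "B", "C"], ["r"], np.array([[-1.0], [-1.0], [1.0]]),
            {"r": {"A", "B"}},
        )
        sign = d_sign_structure(net)
        assert sign[0, 1] == 1
        assert sign[0, 2] == sign[1, 2] == -1

    def test_no_shared_reaction_is_zero(self):
        net = ReactionNetwork(
            ["A", "B"], ["r1", "r2"], np.array([[-1.0, 0.0], [0.0, -1.0]]),
            {"r1": {"A"}, "r2": {"B"}},
        )
        sign = d_sign_structure(net)
        assert sign[0, 1] == 0

    def test_symmetric_with_positive_diagonal(self, rng):
        net = random_network(rng)
        sign = d_sign_structure(net)
        assert np.array_equal(sign, sign.T)
        assert (np.diag(sign) == 1).all()

    def test_conflicting_contributions_flagged_indeterminate(self):
        # r1: A -> B (negative), r2: source -> A + B (positive)
        net = ReactionNetwork(
            ["A", "B"], ["r1", "r2"],
            np.array([[-1.0, 1.0], [1.0, 1.0]]),
            {"r1": {"A"}, "r2": set()},
        )
        sign = d_sign_structure(net)
        assert sign[0, 1] == INDETERMINATE


class TestRoundTrips:
    def test_network_tsv_round_trip(self, tmp_path, rng):
        # species order follows first appearance in the edge list, so the
        # round trip is compared up to that relabelling
        net = random_network(rng)
        write_network_tsv(net, tmp_path / "net.tsv", tmp_path / "enz.tsv")
        back = read_network_tsv(tmp_path / "net.tsv", tmp_path / "enz.tsv")
        assert set(back.species) == set(net.species)
        assert back.reactions == net.reactions
        perm = [back.species.index(s) for s in net.species]
        assert np.allclose(back.S[perm, :], net.S)
        assert back.dependencies == net.dependencies
        assert back.enzyme_of == net.enzyme_of

    def test_network_json_round_trip(self, chain_net):
        back = ReactionNetwork.from_json(chain_net.to_json())
        assert back.species == chain_net.species
        assert np.allclose(back.S, chain_net.S)

    def test_interactions_tsv_round_trip(self, tmp_path):
        inet = InteractionNetwork(
            ["X", "Y", "Z"],
            [
                Superpathway("X", "Y", [1, 2], ["R1", "R2"]),
                Superpathway("Y", "Z", [2], ["R3"], sign_override=-1),
            ],
        )
        write_interactions_tsv(inet, tmp_path / "i.tsv")
        back = read_interactions_tsv(tmp_path / "i.tsv")
        assert back.species == inet.species
        assert back.superpathways[0].n_type2 == 1
        assert back.superpathways[1].sign_override == -1
        assert np.array_equal(back.sign_structure(), inet.sign_structure())

    def test_interaction_structures(self):
        inet = InteractionNetwork(
            ["X", "Y"], [Superpathway("X", "Y", [2], ["R1"])]
        )
        pat = inet.jacobian_structure().pattern
        assert np.array_equal(pat, np.ones((2, 2), dtype=int))
        assert inet.sign_structure()[0, 1] == 1  # single type-2 step


class TestValidation:
    def test_duplicate_reaction_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ReactionNetwork(["A"], ["r", "r"], np.zeros((1, 2)), {})

    def test_unknown_dependency_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            ReactionNetwork(["A"], ["r"], np.array([[-1.0]]), {"r": {"Z"}})

    def test_superpathway_needs_distinct_endpoints(self):
        with pytest.raises(ValueError, match="distinct"):
            Superpathway("X", "X", [1])

    def test_superpathway_needs_steps(self):
        with pytest.raises(ValueError, match="at least one step"):
            Superpathway("X", "Y", [])
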