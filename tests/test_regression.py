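"""Constrained regression loss and the normalized R* matrix."""

import numpy as np
import pytest

from invjac.fluctuation import DiagonalSampler, TopologicalSampler
from invjac.lyapunov import solve_covariance, vectorize
from invjac.network import JacobianStructure
from invjac.regression import (
    ElementProjections,
    element_loss,
    minmax_normalize,
    regression_loss_matrix,
    sample_rhs_matrix,
    stack_rhs,
)


@pytest.fixture
def two_species_system():
    """Identifiable 2-species system where only J[0,1] changes."""
    pattern = JacobianStructure(np.array([[1, 1], [0, 1]]))
    J_h = np.array([[-2.0, 1.0], [0.0, -1.0]])
    J_d = np.array([[-2.0, 2.0], [0.0, -1.0]])
    D = np.diag([0.8, 0.6])
    C_h = solve_covariance(J_h, D)
    C_d = solve_covariance(J_d, D)
    return pattern, J_h, J_d, D, C_h, C_d


class TestElementLoss:
    def test_zero_for_identical_conditions(self, two_species_system):
        pattern, J_h, _, D, C_h, _ = two_species_system
        sys_h = vectorize(C_h, pattern)
        b_c = stack_rhs(D, D)
        for e in pattern.nonzeros():
            assert element_loss(sys_h, sys_h, b_c, e) < 1e-10

    def test_changed_element_has_largest_loss(self, two_species_system):
        pattern, _, _, D, C_h, C_d = two_species_system
        sys_h = vectorize(C_h, pattern)
        sys_d = vectorize(C_d, pattern)
        b_c = stack_rhs(D, D)
        losses = {e: element_loss(sys_h, sys_d, b_c, e)
                  for e in pattern.nonzeros()}
        assert max(losses, key=losses.get) == (0, 1)
        assert losses[(0, 1)] > 10 * max(
            v for e, v in losses.items() if e != (0, 1)
        )

    def test_loss_scales_linearly_with_joint_scaling(self, two_species_system):
        pattern, _, _, D, C_h, C_d = two_species_system
        s = 3.7
        base = element_loss(vectorize(C_h, pattern), vectorize(C_d, pattern),
                            stack_rhs(D, D), (0, 1))
        scaled = element_loss(
            vectorize(s * C_h, pattern), vectorize(s * C_d, pattern),
            s * stack_rhs(D, D), (0, 1),
        )
        assert scaled == pytest.approx(s * base, rel=1e-8)

    def test_element_outside_pattern_rejected(self, two_species_system):
        pattern, _, _, D, C_h, C_d = two_species_system
        with pytest.raises(ValueError, match="not in the Jacobian pattern"):
            element_loss(vectorize(C_h, pattern), vectorize(C_d, pattern),
                         stack_rhs(D, D), (1, 0))


class TestProjections:
    def test_projection_losses_equal_lstsq_residuals(self, two_species_system):
        pattern, _, _, D, C_h, C_d = two_species_system
        rng = np.random.default_rng(3)
        Dh = np.diag(rng.uniform(0, 1, 2))
        Dd = np.diag(rng.uniform(0, 1, 2))
        b_c = stack_rhs(Dh, Dd)
        proj = ElementProjections(C_h, C_d, pattern, include_diagonal=True)
        losses = proj.losses(b_c[:, None])
        sys_h = vectorize(C_h, pattern)
        sys_d = vectorize(C_d, pattern)
        for e, v in losses.items():
            assert v == pytest.approx(element_loss(sys_h, sys_d, b_c, e),
                                      abs=1e-10)

    def test_empty_support_rejected(self):
        pattern = JacobianStructure(np.eye(2, dtype=int))
        C = np.eye(2)
        with pytest.raises(ValueError, match="empty evaluated support"):
            ElementProjections(C, C, pattern, include_diagonal=False)


class TestRegressionLossMatrix:
    def test_identical_conditions_degenerate_all_zero(self, two_species_system):
        # with the generating D in the stream and no difference between
        # conditions, every loss is ~0 and the min-max convention maps the
        # (all-equal) losses to zero
        pattern, _, _, D, C_h, _ = two_species_system
        res = regression_loss_matrix(
            C_h, C_h, pattern, DiagonalSampler(2), n_samples=0, seed=0,
            include_diagonal=True, extra_samples=[(D, D)],
        )
        assert np.nanmax(res.raw) < 1e-9
        assert np.all(res.R[res.support] == 0.0)
        assert res.degenerate

    def test_normalized_range_and_mask(self, two_species_system):
        pattern, _, _, D, C_h, C_d = two_species_system
        res = regression_loss_matrix(
            C_h, C_d, pattern, DiagonalSampler(2), n_samples=50, seed=1,
            include_diagonal=True,
        )
        vals = res.R[res.support]
        assert vals.min() == 0.0 and vals.max() == 1.0
        assert np.isnan(res.R[~res.support]).all()

    def test_deterministic_given_seed(self, two_species_system):
        pattern, _, _, D, C_h, C_d = two_species_system
        kw = dict(n_samples=30, seed=9, include_diagonal=True)
        r1 = regression_loss_matrix(C_h, C_d, pattern, DiagonalSampler(2), **kw)
        r2 = regression_loss_matrix(C_h, C_d, pattern, DiagonalSampler(2), **kw)
        assert np.array_equal(r1.raw, r2.raw, equal_nan=True)

    def test_min_loss_nonincreasing_in_samples(self, two_species_system):
        """The sample stream is prefix-stable: more samples never raise the min."""
        pattern, _, _, D, C_h, C_d = two_species_system
        short = regression_loss_matrix(C_h, C_d, pattern, DiagonalSampler(2),
                                       n_samples=40, seed=5,
                                       include_diagonal=True)
        long = regression_loss_matrix(C_h, C_d, pattern, DiagonalSampler(2),
                                      n_samples=120, seed=5,
                                      include_diagonal=True)
        assert np.all(long.raw[long.support] <= short.raw[short.support] + 1e-15)

    def test_ranking_invariant_under_joint_covariance_rescaling(
        self, two_species_system
    ):
        pattern, _, _, D, C_h, C_d = two_species_system
        kw = dict(n_samples=50, seed=2, include_diagonal=True)
        base = regression_loss_matrix(C_h, C_d, pattern, DiagonalSampler(2), **kw)
        scaled = regression_loss_matrix(7.3 * C_h, 7.3 * C_d, pattern,
                                        DiagonalSampler(2), **kw)
        # scaling C rescales A's columns only: the residual is unchanged
        assert np.allclose(base.R[base.support], scaled.R[scaled.support])

    def test_true_sample_in_stream_pins_changed_element(self, two_species_system):
        pattern, _, _, D, C_h, C_d = two_species_system
        res = regression_loss_matrix(
            C_h, C_d, pattern, DiagonalSampler(2), n_samples=20, seed=4,
            include_diagonal=True, extra_samples=[(D, D)],
        )
        assert res.argmax() == (0, 1)
        assert res.R[0, 1] == 1.0


def test_minmax_normalize_degenerate_and_masking():
    M = np.array([[2.0, 2.0], [2.0, 2.0]])
    mask = np.array([[True, True], [False, False]])
    out = minmax_normalize(M, mask)
    assert np.all(out[mask] == 0.0)
    assert np.isnan(out[~mask]).all()


def test_sample_rhs_matrix_prefix_stability():
    sampler = DiagonalSampler(3)
    B1 = sample_rhs_matrix(sampler, 10, seed=8)
    B2 = sample_rhs_matrix(sampler, 25, seed=8)
    assert np.array_equal(B1, B2[:, :10])
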