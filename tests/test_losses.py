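"""Loss components against closed forms and brute-force window/derivative oracles."""

import numpy as np
import pytest

from lungwarp import (
    DisplacementField,
    LossWeights,
    Volume,
    grad_penalty,
    jac_penalty,
    jacobian_determinant_map,
    local_ncc,
    sim_loss,
    total_loss,
)
from lungwarp import autodiff as ad
from lungwarp.errors import ContractError
from lungwarp.losses import count_folding, sim_loss_t, total_loss_t
from lungwarp.warp import warp_trilinear_t

from oracles import (
    grad_penalty_loop,
    jac_penalty_from_dets,
    jacobian_det_loop,
    ncc_loop,
)


def linear_field(shape, a):
    """s(p) = (A - I) p so the full map is the affine map A."""
    base = np.moveaxis(np.indices(shape).astype(float), 0, -1)
    return base @ (a - np.eye(3)).T


class TestLocalNcc:
    def test_identical_volumes_near_one(self, rng):
        v = rng.random((12, 12, 12))
        assert local_ncc(v, v, window=5) > 0.999
        assert sim_loss(v, v, window=5) < 1e-3

    def test_positive_affine_intensity_invariance(self, rng):
        f = rng.random((10, 10, 10))
        w = 3.0 * f + 0.7
        assert abs(local_ncc(f, w, window=5) - local_ncc(f, f, window=5)) < 1e-3

    def test_anticorrelated_windows_still_similar(self, rng):
        """Eq's squared numerator makes perfectly anticorrelated images 'similar'."""
        f = rng.random((9, 9, 9))
        w = 1.0 - f
        assert sim_loss(f, w, window=5) < 1e-3
        assert abs(sim_loss(f, w, window=5) - (1 - ncc_loop(f.copy(), w, 5, 1e-5))) < 1e-6

    @pytest.mark.parametrize("window", [5, 11])
    def test_brute_force_oracle(self, rng, window):
        f = rng.random((12, 12, 12))
        m = rng.random((12, 12, 12))
        mine = local_ncc(f, m, window=window)
        assert abs(mine - ncc_loop(f, m, window, 1e-5)) < 1e-6

    def test_independent_noise_in_unit_interval(self, rng):
        f = rng.random((16, 16, 16))
        m = rng.random((16, 16, 16))
        val = local_ncc(f, m)
        assert 0.0 <= val <= 1.0
        assert 0.0 < sim_loss(f, m) <= 1.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ContractError):
            local_ncc(rng.random((8, 8, 8)), rng.random((8, 8, 7)))


class TestJacobian:
    def test_zero_field_det_one(self):
        det = jacobian_determinant_map(DisplacementField.zeros((6, 6, 6)))
        np.testing.assert_allclose(det.data, 1.0, atol=1e-12)

    def test_linear_field_det_two(self):
        a = np.diag([2.0, 1.0, 1.0])
        det = jacobian_determinant_map(
            DisplacementField(linear_field((8, 8, 8), a))
        )
        np.testing.assert_allclose(det.data, 2.0, atol=1e-10)

    def test_general_linear_field(self, rng):
        a = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
        det = jacobian_determinant_map(DisplacementField(linear_field((6, 6, 6), a)))
        np.testing.assert_allclose(det.data, np.linalg.det(a), atol=1e-10)

    def test_brute_force_oracle(self, rng, smooth_field):
        field = smooth_field((8, 8, 8), amplitude=1.0, seed=5)
        det = jacobian_determinant_map(DisplacementField(field))
        np.testing.assert_allclose(det.data, jacobian_det_loop(field), atol=1e-6)

    def test_slice_swap_produces_folding(self):
        field = np.zeros((8, 8, 8, 3))
        field[3, :, :, 0] = 1.0  # voxel 3 maps onto voxel 4
        field[4, :, :, 0] = -1.0  # voxel 4 maps onto voxel 3: local x-order flips
        det = jacobian_determinant_map(DisplacementField(field))
        assert det.data.min() <= 0.0


class TestJacPenalty:
    def test_zero_on_identity_and_smooth_fields(self, smooth_field):
        assert jac_penalty(DisplacementField.zeros((8, 8, 8))) == 0.0
        small = smooth_field((8, 8, 8), amplitude=0.1, seed=1)
        assert jac_penalty(DisplacementField(small)) == 0.0

    def test_single_negative_det_value(self):
        """One voxel at det = -0.5 contributes exactly 2*|det| = 1.0."""
        field = np.zeros((8, 8, 8, 3))
        field[4, 4, 4, 0] = -1.5  # forward diff at (3,4,4): det = 1 - 1.5 = -0.5
        dets = jacobian_determinant_map(DisplacementField(field)).data
        assert np.count_nonzero(dets < 0) == 1
        assert dets.min() == pytest.approx(-0.5)
        assert jac_penalty(DisplacementField(field)) == pytest.approx(1.0)

    def test_matches_det_map_formula(self, rng, smooth_field):
        field = smooth_field((8, 8, 8), amplitude=2.0, seed=7)
        dets = jacobian_determinant_map(DisplacementField(field)).data
        assert jac_penalty(DisplacementField(field)) == pytest.approx(
            jac_penalty_from_dets(dets), rel=1e-10
        )

    def test_vanishes_as_field_shrinks(self, smooth_field):
        field = smooth_field((8, 8, 8), amplitude=3.0, seed=8)
        penalties = [
            jac_penalty(DisplacementField(s * field)) for s in (1.0, 0.5, 0.25, 0.1)
        ]
        assert penalties[0] > 0
        assert all(a >= b for a, b in zip(penalties, penalties[1:]))
        assert penalties[-1] == 0.0

    def test_zero_iff_no_folding(self, smooth_field):
        for seed in range(4):
            field = smooth_field((8, 8, 8), amplitude=2.5, seed=seed)
            dets = jacobian_determinant_map(DisplacementField(field)).data
            pen = jac_penalty(DisplacementField(field))
            if np.all(dets > 0):
                assert pen == 0.0
                assert count_folding(np.moveaxis(field, -1, 0)) == 0
            if pen > 0:
                assert dets.min() < 0


class TestGradPenalty:
    def test_zero_and_constant_fields(self):
        assert grad_penalty(DisplacementField.zeros((6, 6, 6))) == 0.0
        const = np.full((6, 6, 6, 3), 2.5)
        assert grad_penalty(DisplacementField(const)) == 0.0

    def test_closed_form_linear_field(self):
        """dsx/dx = c everywhere gives c^2 * n^3 (c = 0.1, n = 8 -> 5.12)."""
        field = np.zeros((8, 8, 8, 3))
        field[..., 0] = 0.1 * np.arange(8)[:, None, None]
        assert grad_penalty(DisplacementField(field)) == pytest.approx(5.12)

    def test_brute_force_oracle(self, smooth_field):
        field = smooth_field((8, 8, 8), amplitude=1.2, seed=9)
        assert grad_penalty(DisplacementField(field)) == pytest.approx(
            grad_penalty_loop(field), rel=1e-9
        )

    def test_translation_invariance(self, smooth_field):
        field = smooth_field((7, 7, 7), amplitude=1.0, seed=3)
        shifted = field + np.array([4.0, -2.0, 1.0])
        assert grad_penalty(DisplacementField(field)) == pytest.approx(
            grad_penalty(DisplacementField(shifted)), rel=1e-9
        )
        assert jac_penalty(DisplacementField(field)) == pytest.approx(
            jac_penalty(DisplacementField(shifted)), abs=1e-9
        )


class TestTotalLoss:
    def test_identical_pair_zero_field(self, rng):
        v = rng.random((10, 10, 10))
        rep = total_loss(v, v, DisplacementField.zeros((10, 10, 10)),
                         LossWeights(ncc_window=5))
        assert rep.total < 1e-3
        assert rep.folding_count == 0
        assert rep.r_jac == 0.0
        assert rep.r_der == 0.0

    def test_component_arithmetic(self, rng, smooth_field):
        f = rng.random((10, 10, 10))
        m = rng.random((10, 10, 10))
        field = DisplacementField(smooth_field((10, 10, 10), amplitude=2.0, seed=4))
        w = LossWeights(alpha=1.0, beta=1e-5, ncc_window=5)
        rep = total_loss(f, m, field, w)
        assert rep.total == pytest.approx(
            rep.l_sim + w.beta * rep.r_jac + w.alpha * rep.r_der, rel=1e-12
        )

    def test_beta_zero_ignores_folding(self, rng, smooth_field):
        f = rng.random((8, 8, 8))
        m = rng.random((8, 8, 8))
        field = smooth_field((8, 8, 8), amplitude=3.0, seed=8)
        w0 = LossWeights(alpha=0.5, beta=0.0, ncc_window=5)
        rep = total_loss(f, m, DisplacementField(field), w0)
        assert rep.total == pytest.approx(rep.l_sim + 0.5 * rep.r_der, rel=1e-12)

    def test_report_serializes(self, rng):
        import json

        v = rng.random((8, 8, 8))
        rep = total_loss(v, v, DisplacementField.zeros((8, 8, 8)),
                         LossWeights(ncc_window=5))
        payload = json.loads(rep.to_json())
        assert set(payload) == {
            "l_sim", "r_jac", "r_der", "total", "folding_count",
            "alpha", "beta", "window",
        }

    def test_weight_validation(self):
        with pytest.raises(ContractError):
            LossWeights(ncc_window=4)
        with pytest.raises(ContractError):
            LossWeights(beta=-1.0)


class TestFieldOptimization:
    def test_gradient_descent_on_field_reduces_sim_loss(self, rng):
        """Registering a small translation by optimizing the field directly."""
        grid = np.stack(np.meshgrid(*[np.arange(16)] * 3, indexing="ij"), -1)
        blob = np.exp(-np.sum((grid - 8.0) ** 2, -1) / 18.0)
        shifted = np.exp(-np.sum((grid - np.array([9.5, 8, 8])) ** 2, -1) / 18.0)
        w = LossWeights(alpha=1.0 / 16**3, beta=1e-5, ncc_window=9)
        field = ad.Tensor(np.zeros((3, 16, 16, 16)), requires_grad=True)
        opt = ad.Adam([field], lr=0.05)
        initial = sim_loss_t(shifted, blob, w.ncc_window, w.epsilon).item()
        for _ in range(200):
            opt.zero_grad()
            warped = warp_trilinear_t(ad.Tensor(blob), field)
            loss, l_sim, _, _ = total_loss_t(shifted, warped, field, w)
            loss.backward()
            opt.step()
        assert l_sim.item() < initial
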