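"""Thin-plate-spline fitting, evaluation, warping and augmentation bookkeeping."""

import numpy as np
import pytest

from lungwarp import (
    Volume,
    build_augmented_dataset,
    evaluate_tps,
    fit_tps,
    random_grid_tps,
    warp_volume_tps,
)
from lungwarp.errors import ContractError, TpsSolveError
from lungwarp.fixtures import make_phantom
from lungwarp.tps3d import ImagePair, displacement_from_tps

from oracles import tps_eval_loop, trilinear_warp_loop


def grid_points(n=3):
    axis = np.linspace(0.0, 1.0, n)
    return np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), -1).reshape(-1, 3)


class TestFit:
    def test_identity(self):
        src = grid_points(3)
        t = fit_tps(src, src)
        assert np.abs(t.weights).max() < 1e-8
        np.testing.assert_allclose(t.affine[0], 0.0, atol=1e-8)
        np.testing.assert_allclose(t.affine[1:], np.eye(3), atol=1e-8)

    def test_pure_translation(self):
        src = grid_points(3)
        shift = np.array([0.1, -0.05, 0.2])
        t = fit_tps(src, src + shift)
        assert np.abs(t.weights).max() < 1e-8
        np.testing.assert_allclose(t.affine[0], shift, atol=1e-8)
        pts = np.array([[0.3, 0.7, 0.1]])
        np.testing.assert_allclose(evaluate_tps(t, pts), pts + shift, atol=1e-8)

    def test_interpolates_control_points(self, rng):
        src = grid_points(3)
        dst = src + rng.uniform(-0.08, 0.08, src.shape)
        t = fit_tps(src, dst)
        np.testing.assert_allclose(evaluate_tps(t, src), dst, atol=1e-8)

    def test_orthogonality_side_condition(self, rng):
        src = grid_points(3)
        dst = src + rng.uniform(-0.08, 0.08, src.shape)
        t = fit_tps(src, dst)
        p = np.hstack([np.ones((src.shape[0], 1)), src])
        assert np.abs(p.T @ t.weights).max() < 1e-6

    def test_affine_reproduction(self, rng):
        """TPS reproduces affine maps exactly: weights vanish, f = A x + b."""
        src = grid_points(3)
        a = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        b = rng.normal(size=3) * 0.1
        t = fit_tps(src, src @ a.T + b)
        pts = rng.random((20, 3))
        np.testing.assert_allclose(evaluate_tps(t, pts), pts @ a.T + b, atol=1e-6)

    def test_duplicate_points_rejected(self):
        src = grid_points(3)
        src[1] = src[0]
        with pytest.raises(TpsSolveError):
            fit_tps(src, src)

    def test_coplanar_points_rejected(self, rng):
        src = rng.random((10, 3))
        src[:, 2] = 0.25  # all points in one plane: affine part is rank-deficient
        with pytest.raises(TpsSolveError):
            fit_tps(src, src + rng.uniform(-0.05, 0.05, src.shape))

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ContractError):
            fit_tps(rng.random((4, 3)), rng.random((4, 3)))


class TestEvaluate:
    def test_brute_force_oracle(self, rng):
        src = grid_points(3)
        dst = src + rng.uniform(-0.08, 0.08, src.shape)
        t = fit_tps(src, dst)
        pts = rng.random((15, 3))
        np.testing.assert_allclose(
            evaluate_tps(t, pts), tps_eval_loop(t, pts), atol=1e-10
        )

    def test_u_zero_at_control_point(self, rng):
        src = grid_points(3)
        dst = src + rng.uniform(-0.05, 0.05, src.shape)
        t = fit_tps(src, dst)
        # evaluating exactly at a control point exercises U(0) = 0
        np.testing.assert_allclose(evaluate_tps(t, src[13:14]), dst[13:14], atol=1e-8)


class TestRandomGrid:
    def test_h_zero_identity(self, rng):
        t = random_grid_tps(4, 0.0, 0)
        pts = rng.random((10, 3))
        np.testing.assert_allclose(evaluate_tps(t, pts), pts, atol=1e-7)

    def test_seed_determinism(self):
        t1 = random_grid_tps(3, 0.05, 42)
        t2 = random_grid_tps(3, 0.05, 42)
        t3 = random_grid_tps(3, 0.05, 43)
        np.testing.assert_array_equal(t1.control_dst, t2.control_dst)
        assert np.abs(t1.control_dst - t3.control_dst).max() > 0

    def test_default_grid_gives_125_control_points(self):
        t = random_grid_tps(5, 0.02, 0)
        assert t.control_src.shape[0] == 125

    def test_perturbations_bounded_by_h(self):
        t = random_grid_tps(4, 0.07, 3)
        assert np.abs(t.control_dst - t.control_src).max() <= 0.07


class TestWarpVolume:
    def test_identity_transform_exact(self, rng):
        v = Volume(rng.random((8, 8, 8)))
        src = grid_points(3)
        out = warp_volume_tps(v, fit_tps(src, src))
        np.testing.assert_allclose(out.data, v.data, atol=1e-7)

    def test_one_voxel_translation_direction(self, rng):
        """Backward mapping: shifting the map by +1 voxel samples input at i+1."""
        n = 8
        v = Volume(rng.random((n, n, n)))
        src = grid_points(3)
        shift = np.array([1.0 / (n - 1), 0.0, 0.0])
        out = warp_volume_tps(v, fit_tps(src, src + shift))
        np.testing.assert_allclose(
            out.data[: n - 1], v.data[1:], atol=1e-7
        )

    def test_oracle_equivalence_smooth_phantom(self):
        vol, _ = make_phantom((16, 16, 16), n_blobs=5, seed=3)
        t = random_grid_tps(3, 0.05, 11)
        out = warp_volume_tps(vol, t)
        field = displacement_from_tps(t, vol.shape)
        expect = trilinear_warp_loop(vol.data, field)
        np.testing.assert_allclose(out.data, expect, atol=1e-6)

    def test_mask_warp_stays_binary(self):
        _, mask = make_phantom((12, 12, 12), n_blobs=3, seed=0)
        out = warp_volume_tps(mask, random_grid_tps(3, 0.08, 5))
        assert out.is_mask
        assert set(np.unique(out.data)) <= {0.0, 1.0}


class TestAugmentation:
    def _pairs(self, n, shape=(8, 8, 8), seed=0):
        r = np.random.default_rng(seed)
        return [
            ImagePair(f"p{i}", Volume(r.random(shape)), Volume(r.random(shape)))
            for i in range(n)
        ]

    def test_manifest_count_formula(self, tmp_path):
        man = build_augmented_dataset(
            self._pairs(2), 2, [0.02, 0.05], 3, 0, tmp_path / "aug"
        )
        # total = 2 * n_pairs * (1 + per_h * |h_values|)
        assert man.total_scans == 2 * 2 * (1 + 2 * 2)
        assert man.counts["originals"] == 4
        assert man.counts["simulated"] == man.total_scans - 4

    def test_zero_replicates_originals_only(self, tmp_path):
        man = build_augmented_dataset(self._pairs(1), 0, [0.05], 3, 0, tmp_path / "a0")
        assert man.total_scans == 2

    def test_replicate_counts_per_h(self, tmp_path):
        man = build_augmented_dataset(
            self._pairs(1), 3, [0.02, 0.1], 3, 0, tmp_path / "a1"
        )
        sim = man.records[man.records["replicate"] >= 0]
        assert sim.groupby("h").size().to_dict() == {0.02: 6, 0.1: 6}

    def test_written_files_exist_and_manifest_reloads(self, tmp_path):
        import pandas as pd

        out = tmp_path / "a2"
        man = build_augmented_dataset(self._pairs(1), 1, [0.05], 3, 0, out)
        for p in man.records["path"]:
            assert (out / p.split("/")[-1]).exists()
        reread = pd.read_csv(out / "manifest.csv", keep_default_na=False)
        assert len(reread) == man.total_scans

    def test_empty_pairs_rejected(self, tmp_path):
        with pytest.raises(ContractError):
            build_augmented_dataset([], 1, [0.05], 3, 0, tmp_path / "a3")
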