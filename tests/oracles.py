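"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain scalar/window loops, deliberately
avoiding the package's box-filter / vectorized code paths, so agreement is a
meaningful dual-route check.
"""

from __future__ import annotations

import math

import numpy as np


def ncc_loop(fixed: np.ndarray, warped: np.ndarray, window: int, eps: float) -> float:
    """Mean windowed squared NCC with border-clipped windows (triple loop)."""
    r = window // 2
    nx, ny, nz = fixed.shape
    total = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                sl = (
                    slice(max(0, i - r), min(nx, i + r + 1)),
                    slice(max(0, j - r), min(ny, j + r + 1)),
                    slice(max(0, k - r), min(nz, k + r + 1)),
                )
                f = fixed[sl].ravel()
                m = warped[sl].ravel()
                fc = f - f.mean()
                mc = m - m.mean()
                cross = float(fc @ mc)
                total += cross * cross / (float(fc @ fc) * float(mc @ mc) + eps)
    return total / fixed.size


def trilinear_warp_loop(vol: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Per-voxel trilinear resampler; field is (..., 3), clamped border."""
    dims = vol.shape
    out = np.zeros(dims)
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                c = np.array([i, j, k], dtype=float) + field[i, j, k]
                c = np.clip(c, 0.0, np.array(dims) - 1.0)
                c0 = np.minimum(np.floor(c), np.array(dims) - 2.0).astype(int)
                t = c - c0
                acc = 0.0
                for dx in (0, 1):
                    for dy in (0, 1):
                        for dz in (0, 1):
                            w = (
                                (t[0] if dx else 1 - t[0])
                                * (t[1] if dy else 1 - t[1])
                                * (t[2] if dz else 1 - t[2])
                            )
                            acc += w * vol[c0[0] + dx, c0[1] + dy, c0[2] + dz]
                out[i, j, k] = acc
    return out


def nearest_warp_loop(vol: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Per-voxel nearest-neighbor resampler with half-up rounding."""
    dims = vol.shape
    out = np.zeros(dims)
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                c = np.array([i, j, k], dtype=float) + field[i, j, k]
                idx = np.clip(
                    np.floor(c + 0.5).astype(int), 0, np.array(dims) - 1
                )
                out[i, j, k] = vol[idx[0], idx[1], idx[2]]
    return out


def tps_eval_loop(transform, points: np.ndarray) -> np.ndarray:
    """Direct per-point TPS evaluation summing every kernel term."""
    pts = np.atleast_2d(points)
    out = np.zeros((pts.shape[0], 3))
    for pi, p in enumerate(pts):
        for axis in range(3):
            val = (
                transform.affine[0, axis]
                + transform.affine[1, axis] * p[0]
                + transform.affine[2, axis] * p[1]
                + transform.affine[3, axis] * p[2]
            )
            for ci in range(transform.control_src.shape[0]):
                r = math.dist(transform.control_src[ci], p)
                if r > 0:
                    val += transform.weights[ci, axis] * r * r * math.log(r)
            out[pi, axis] = val
    return out


def jacobian_det_loop(field: np.ndarray) -> np.ndarray:
    """Per-voxel det(I + ds/dp) with forward/backward-at-border differences."""
    dims = field.shape[:3]
    out = np.zeros(dims)

    def fd(a, axis, idx):
        i = list(idx)
        if i[axis] < dims[axis] - 1:
            j = list(i)
            j[axis] += 1
            return a[tuple(j)] - a[tuple(i)]
        j = list(i)
        j[axis] -= 1
        return a[tuple(i)] - a[tuple(j)]

    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                jac = np.eye(3)
                for a in range(3):
                    for b in range(3):
                        jac[a, b] += fd(field[..., a], b, (i, j, k))
                out[i, j, k] = np.linalg.det(jac)
    return out


def grad_penalty_loop(field: np.ndarray) -> float:
    """Sum over voxels of the squared Frobenius norm of the field gradient."""
    dims = field.shape[:3]
    total = 0.0

    def fd(a, axis, idx):
        i = list(idx)
        if i[axis] < dims[axis] - 1:
            j = list(i)
            j[axis] += 1
            return a[tuple(j)] - a[tuple(i)]
        j = list(i)
        j[axis] -= 1
        return a[tuple(i)] - a[tuple(j)]

    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                for a in range(3):
                    for b in range(3):
                        total += fd(field[..., a], b, (i, j, k)) ** 2
    return total


def jac_penalty_from_dets(dets: np.ndarray) -> float:
    return float(np.sum(np.abs(dets) - dets))
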