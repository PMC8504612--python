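"""3D thin-plate-spline transforms and TPS-based data augmentation.

The TPS interpolant maps a point ``x`` in normalized coordinates [0,1]^3 to

    f(x) = a1 + a2 x + a3 y + a4 z + sum_i w_i U(|m_i - x|),  U(r) = r^2 log r

(one set of coefficients per output axis; natural logarithm; U(0) := 0 as the
continuous limit).  The coefficients solve the interpolation system

    K w + P a = V,    P^T w = 0

where K holds pairwise kernel values of the source control points m_i, P is
the homogeneous source-point matrix [1 | m], and V the destination points.

Augmentation draws control-point perturbations ``n_i = m_i + u(-h, h)`` on a
regular lattice (per-coordinate i.i.d. uniform), and warps both members of an
intrapatient pair with the same draw so the simulated pair stays
intrapatient-like.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import cdist

from .errors import ContractError, TpsSolveError
from .image_io import Volume, write_volume

log = logging.getLogger(__name__)


@dataclass
class TpsTransform:
    """A fitted 3D thin-plate-spline map in normalized [0,1]^3 coordinates.

    ``affine`` rows are the constant and the x/y/z linear coefficients
    (a1..a4), one column per output axis; ``weights`` are the radial
    coefficients w_i, one row per control point.
    """

    control_src: np.ndarray  # (N, 3)
    control_dst: np.ndarray  # (N, 3)
    weights: np.ndarray  # (N, 3)
    affine: np.ndarray  # (4, 3)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return evaluate_tps(self, points)


def _kernel(r: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r with U(0) = 0."""
    out = np.zeros_like(r)
    pos = r > 0
    rp = r[pos]
    out[pos] = rp * rp * np.log(rp)
    return out


def fit_tps(control_src: np.ndarray, control_dst: np.ndarray) -> TpsTransform:
    """Fit a 3D TPS interpolating ``control_src -> control_dst``.

    Solves the (N+4)x(N+4) bordered linear system once for all three output
    axes.  Raises :class:`TpsSolveError` with a condition-number diagnostic
    when the system is singular (duplicate or coplanar control points); a
    tiny diagonal regularization (1e-10) is attempted first and logged.
    """
    src = np.asarray(control_src, dtype=np.float64)
    dst = np.asarray(control_dst, dtype=np.float64)
    if src.ndim != 2 or src.shape[1] != 3 or src.shape != dst.shape:
        raise ContractError(f"control points must be matching (N,3), got {src.shape} / {dst.shape}")
    n = src.shape[0]
    if n < 5:
        raise ContractError(f"need at least 5 control points, got {n}")
    r = cdist(src, src)
    if np.min(r[~np.eye(n, dtype=bool)]) == 0.0:
        raise TpsSolveError("duplicate control points make the TPS system singular")
    k = _kernel(r)
    p = np.hstack([np.ones((n, 1)), src])
    lmat = np.zeros((n + 4, n + 4))
    lmat[:n, :n] = k
    lmat[:n, n:] = p
    lmat[n:, :n] = p.T
    rhs = np.vstack([dst, np.zeros((4, 3))])
    def _residual(sol):
        return float(np.max(np.abs(k @ sol[:n] + p @ sol[n:] - dst)))

    try:
        sol = np.linalg.solve(lmat, rhs)
    except np.linalg.LinAlgError:
        sol = None
    if sol is None or not np.all(np.isfinite(sol)) or _residual(sol) > 1e-8:
        # near-singular: retry once with a tiny ridge on K, and log it
        log.warning(
            "TPS system near-singular; retrying with 1e-10 diagonal "
            "regularization on K"
        )
        lmat[:n, :n] += 1e-10 * np.eye(n)
        try:
            sol = np.linalg.solve(lmat, rhs)
        except np.linalg.LinAlgError:
            sol = None
        if sol is None or not np.all(np.isfinite(sol)) or _residual(sol) > 1e-6:
            cond = np.linalg.cond(lmat)
            raise TpsSolveError(
                f"singular TPS system (condition number {cond:.3g}); "
                "control points may be duplicate or coplanar"
            )
    return TpsTransform(src, dst, weights=sol[:n], affine=sol[n:])


def evaluate_tps(t: TpsTransform, points: np.ndarray) -> np.ndarray:
    """Apply the TPS map to an (M, 3) array of normalized points."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    u = _kernel(cdist(pts, t.control_src))
    hom = np.hstack([np.ones((pts.shape[0], 1)), pts])
    return hom @ t.affine + u @ t.weights


def random_grid_tps(grid_n: int, h: float, seed) -> TpsTransform:
    """Draw a random TPS on a regular ``grid_n``^3 control lattice.

    Destination points are the lattice plus i.i.d. uniform(-h, h) offsets per
    coordinate (h in normalized units; h in [0.02, 0.1] avoids overstretching,
    and h = 0 yields the identity).  ``seed`` may be an int or a Generator.
    """
    if grid_n < 2:
        raise ContractError(f"grid_n must be >= 2, got {grid_n}")
    if h < 0:
        raise ContractError(f"h must be >= 0, got {h}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    axis = np.linspace(0.0, 1.0, grid_n)
    src = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    dst = src + rng.uniform(-h, h, size=src.shape)
    return fit_tps(src, dst)


def _tps_voxel_map(t: TpsTransform, shape: tuple[int, int, int]) -> np.ndarray:
    """Evaluate the TPS at every voxel of ``shape``; returns (3, *shape) voxel coords.

    Normalization maps voxel index i on an axis of length n to i/(n-1);
    evaluation is chunked along x to bound the kernel-distance matrix.
    """
    dims = np.asarray(shape, dtype=np.float64)
    out = np.empty((3,) + tuple(shape))
    yz = np.stack(
        np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij"), axis=-1
    ).reshape(-1, 2)
    chunk = max(1, int(2_000_000 // max(yz.shape[0], 1)))
    for x0 in range(0, shape[0], chunk):
        xs = np.arange(x0, min(x0 + chunk, shape[0]))
        pts = np.column_stack(
            [
                np.repeat(xs, yz.shape[0]),
                np.tile(yz[:, 0], xs.size),
                np.tile(yz[:, 1], xs.size),
            ]
        ).astype(np.float64)
        pts /= dims - 1.0
        mapped = evaluate_tps(t, pts) * (dims - 1.0)
        out[:, xs[0] : xs[-1] + 1] = (
            mapped.T.reshape(3, xs.size, shape[1], shape[2])
        )
    return out


def warp_volume_tps(v: Volume, t: TpsTransform) -> Volume:
    """Warp a volume by a TPS via backward mapping.

    Each output voxel's normalized coordinate is mapped through ``t`` and the
    input is sampled there — trilinearly for images, nearest-neighbor for
    masks; out-of-bounds samples clamp to the border.
    """
    coords = _tps_voxel_map(t, v.shape)
    order = 0 if v.is_mask else 1
    data = map_coordinates(v.data, coords.reshape(3, -1), order=order, mode="nearest")
    data = data.reshape(v.shape)
    if v.is_mask:
        data = (data > 0.5).astype(np.float64)
    return replace(v, data=data)


def displacement_from_tps(t: TpsTransform, shape: tuple[int, int, int]) -> np.ndarray:
    """Dense displacement (in voxel units, trailing component axis) induced by ``t``.

    ``s(p) = f(p_norm) * (dim - 1) - p`` on the fixed grid, so that warping by
    the returned field reproduces :func:`warp_volume_tps` exactly.
    """
    coords = _tps_voxel_map(t, shape)
    base = np.indices(shape, dtype=np.float64)
    return np.moveaxis(coords - base, 0, -1)


# -- augmentation ------------------------------------------------------------


@dataclass
class ImagePair:
    """An intrapatient fixed/moving pair, optionally with lung masks."""

    pair_id: str
    fixed: Volume
    moving: Volume
    fixed_mask: Volume | None = None
    moving_mask: Volume | None = None


@dataclass
class AugmentationManifest:
    """Bookkeeping for an augmented dataset: one record per written scan."""

    records: pd.DataFrame
    counts: dict

    @property
    def total_scans(self) -> int:
        return int(len(self.records))

    def write(self, out_dir: str | os.PathLike, config: dict | None = None) -> str:
        path = os.path.join(str(out_dir), "manifest.csv")
        self.records.to_csv(path, index=False)
        if config is not None:
            with open(os.path.join(str(out_dir), "augment_config.yaml"), "w") as fh:
                yaml.safe_dump(config, fh)
        return path


def build_augmented_dataset(
    pairs: list[ImagePair],
    per_h_replicates: int,
    h_values: list[float],
    grid_n: int,
    seed: int,
    out_dir: str | os.PathLike,
    split: str = "train",
) -> AugmentationManifest:
    """Write originals plus TPS-simulated replicates of each pair.

    For every original pair and every (h, replicate) combination one
    simulated pair is produced by warping both members (and masks, when
    present) with the same sampled TPS.  The manifest counts include the
    originals, so ``total = 2 * n_pairs * (1 + per_h_replicates * len(h_values))``
    — e.g. 30 pairs with 25 replicates at each of four h values give 6060
    scans.  Each record carries a derived seed (base seed + record index) so
    any single simulated scan is reproducible in isolation.
    """
    if not pairs:
        raise ContractError("pairs must be nonempty")
    if per_h_replicates < 0:
        raise ContractError("per_h_replicates must be >= 0")
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    record_idx = 0

    def _emit(pair_id, role, vol, mask, h, rep, rec_seed, stem):
        nonlocal record_idx
        path = os.path.join(out_dir, f"{stem}_{role}.nii")
        write_volume(vol, path)
        mask_path = ""
        if mask is not None:
            mask_path = os.path.join(out_dir, f"{stem}_{role}_mask.nii")
            write_volume(mask, mask_path)
        rows.append(
            {
                "split": split,
                "pair_id": pair_id,
                "role": role,
                "h": h,
                "replicate": rep,
                "seed": rec_seed,
                "path": path,
                "mask_path": mask_path,
                "landmarks_path": "",
            }
        )
        record_idx += 1

    for pair in pairs:
        _emit(pair.pair_id, "fixed", pair.fixed, pair.fixed_mask, 0.0, -1,
              seed, f"{pair.pair_id}_orig")
        _emit(pair.pair_id, "moving", pair.moving, pair.moving_mask, 0.0, -1,
              seed, f"{pair.pair_id}_orig")
        for h in h_values:
            for rep in range(per_h_replicates):
                rec_seed = int(seed) + record_idx
                t = random_grid_tps(grid_n, h, rec_seed)
                stem = f"{pair.pair_id}_h{h:g}_r{rep}"
                wf = warp_volume_tps(pair.fixed, t)
                wm = warp_volume_tps(pair.moving, t)
                wfm = (
                    warp_volume_tps(pair.fixed_mask, t)
                    if pair.fixed_mask is not None
                    else None
                )
                wmm = (
                    warp_volume_tps(pair.moving_mask, t)
                    if pair.moving_mask is not None
                    else None
                )
                _emit(pair.pair_id, "fixed", wf, wfm, h, rep, rec_seed, stem)
                _emit(pair.pair_id, "moving", wm, wmm, h, rep, rec_seed, stem)

    records = pd.DataFrame(rows)
    counts = {
        split: int(len(records)),
        "originals": 2 * len(pairs),
        "simulated": int(len(records)) - 2 * len(pairs),
    }
    manifest = AugmentationManifest(records=records, counts=counts)
    manifest.write(
        out_dir,
        config={
            "grid_n": grid_n,
            "h_values": [float(h) for h in h_values],
            "per_h_replicates": per_h_replicates,
            "seed": int(seed),
            "split": split,
        },
    )
    return manifest
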