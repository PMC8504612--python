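"""Synthetic intrapatient-like pairs with known ground-truth deformation.

The phantom emulates the two features of lung CT pairs the pipeline cares
about — a bright organ boundary and textured interior structure — with a
smooth sum of Gaussian blobs inside an ellipsoidal "lung field", plus a soft
shell term at the ellipsoid boundary.  A pair is formed by warping the
phantom with a randomly drawn thin-plate-spline deformation (the same family
used for data augmentation), so the ground-truth transform, the induced
dense displacement field, corresponding landmark sets and warped masks are
all known exactly (up to interpolation).

What the phantom does NOT emulate: CT noise and artifacts, airway/vessel
topology, sliding motion at the pleura, or intensity changes with lung
density during breathing.  Passing tests on fixtures therefore demonstrate
correctness of the machinery, not clinical-grade accuracy.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .image_io import LandmarkSet, Volume, write_landmarks, write_volume
from .tps3d import TpsTransform, displacement_from_tps, random_grid_tps, warp_volume_tps


@dataclass
class SyntheticPair:
    """A moving/fixed pair with ground truth: fixed = moving warped by gt_transform."""

    moving: Volume
    fixed: Volume
    gt_transform: TpsTransform
    moving_mask: Volume
    fixed_mask: Volume
    landmarks_fixed: LandmarkSet
    landmarks_moving: LandmarkSet
    seed: int

    def gt_field(self) -> np.ndarray:
        """Dense ground-truth displacement on the fixed grid (voxel units)."""
        return displacement_from_tps(self.gt_transform, self.fixed.shape)


def make_phantom(shape, n_blobs: int = 12, seed: int = 0) -> tuple[Volume, Volume]:
    """Smooth blob phantom in [0,1] with an ellipsoidal lung-field mask."""
    shape = tuple(int(d) for d in shape)
    if min(shape) < 8:
        raise ContractError(f"shape must be >= 8 per axis, got {shape}")
    rng = np.random.default_rng(seed)
    dims = np.asarray(shape, dtype=np.float64)
    grid = np.stack(np.meshgrid(*[np.arange(d) for d in shape], indexing="ij"), axis=-1)
    center = (dims - 1) / 2.0
    semi = 0.38 * dims
    rho = np.sqrt(np.sum(((grid - center) / semi) ** 2, axis=-1))
    mask = (rho <= 1.0).astype(np.float64)

    img = np.zeros(shape)
    # soft shell at the ellipsoid boundary: a lung-wall-like contour
    img += 0.6 * np.exp(-(((rho - 1.0) / 0.08) ** 2))
    for _ in range(n_blobs):
        while True:
            c = rng.uniform(0.15, 0.85, 3) * (dims - 1)
            if np.sum(((c - center) / semi) ** 2) <= 0.8:
                break
        sigma = rng.uniform(0.04, 0.10) * dims.min()
        amp = rng.uniform(0.3, 1.0)
        img += amp * np.exp(-np.sum((grid - c) ** 2, axis=-1) / (2 * sigma**2))
    hi = img.max()
    if hi > 0:
        img = img / hi
    return (
        Volume(img),
        Volume(mask, is_mask=True),
    )


def _select_landmarks(
    fixed: Volume, fixed_mask: Volume, n_landmarks: int, rng: np.random.Generator
) -> np.ndarray:
    """High-gradient in-mask sites, away from the border, without replacement."""
    gx, gy, gz = np.gradient(fixed.data)
    gradmag = np.sqrt(gx**2 + gy**2 + gz**2)
    valid = fixed_mask.data > 0
    border = 2
    interior = np.zeros_like(valid)
    interior[border:-border, border:-border, border:-border] = True
    valid &= interior
    if not valid.any():
        raise ContractError("mask has no interior voxels for landmarks")
    thresh = np.quantile(gradmag[valid], 0.6)
    sites = np.argwhere(valid & (gradmag >= thresh))
    if len(sites) < n_landmarks:
        warnings.warn(
            f"only {len(sites)} valid landmark sites (requested {n_landmarks})",
            stacklevel=2,
        )
        n_landmarks = len(sites)
    pick = rng.choice(len(sites), size=n_landmarks, replace=False)
    return sites[pick].astype(np.float64)


def make_pair(
    shape,
    h: float = 0.05,
    n_landmarks: int = 50,
    seed: int = 0,
    grid_n: int = 5,
    n_blobs: int = 12,
) -> SyntheticPair:
    """A synthetic intrapatient pair deformed by a random TPS of amplitude h.

    ``h`` is the control-point perturbation half-range in normalized
    coordinates (values up to 0.1 avoid overstretching; h = 0 gives an
    identical pair).  Landmarks are placed at high-intensity-gradient sites
    inside the fixed mask and their moving-image correspondences computed
    through the ground-truth transform.
    """
    moving, moving_mask = make_phantom(shape, n_blobs=n_blobs, seed=seed)
    gt = random_grid_tps(grid_n, h, seed=np.random.default_rng(seed + 1))
    fixed = warp_volume_tps(moving, gt)
    fixed_mask = warp_volume_tps(moving_mask, gt)
    rng = np.random.default_rng(seed + 2)
    xf = _select_landmarks(fixed, fixed_mask, n_landmarks, rng)
    dims = np.asarray(fixed.shape, dtype=np.float64)
    xm = gt(xf / (dims - 1)) * (dims - 1)
    inb = np.all((xm >= 0) & (xm <= dims - 1), axis=1)
    if not inb.all():
        warnings.warn(
            f"dropping {int((~inb).sum())} landmarks mapping out of bounds",
            stacklevel=2,
        )
        xf, xm = xf[inb], xm[inb]
    return SyntheticPair(
        moving=moving,
        fixed=fixed,
        gt_transform=gt,
        moving_mask=moving_mask,
        fixed_mask=fixed_mask,
        landmarks_fixed=LandmarkSet(xf, frame="fixed"),
        landmarks_moving=LandmarkSet(xm, frame="moving"),
        seed=seed,
    )


def make_suite(
    n_pairs: int,
    shape,
    h_values=(0.02, 0.05),
    seed: int = 0,
    out_dir: str | os.PathLike = "fixtures",
    val_pairs: int = 0,
    n_landmarks: int = 50,
) -> pd.DataFrame:
    """Write a suite of synthetic pairs and a manifest the pipeline can consume.

    Each pair cycles through ``h_values`` and gets a derived seed
    (base seed + pair index) so any single pair can be regenerated in
    isolation.  The last ``val_pairs`` pairs are assigned to the "val"
    split, the rest to "train"; the manifest rows (one per scan) carry the
    image, mask and landmark paths.
    """
    if n_pairs < 1:
        raise ContractError("n_pairs must be >= 1")
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(n_pairs):
        pair_seed = int(seed) + i
        h = float(h_values[i % len(h_values)])
        pair = make_pair(shape, h=h, n_landmarks=n_landmarks, seed=pair_seed)
        split = "val" if i >= n_pairs - val_pairs else "train"
        pid = f"pair{i:03d}"
        paths = {}
        for role, vol, mask, lms in (
            ("fixed", pair.fixed, pair.fixed_mask, pair.landmarks_fixed),
            ("moving", pair.moving, pair.moving_mask, pair.landmarks_moving),
        ):
            img_path = os.path.join(out_dir, f"{pid}_{role}.nii")
            mask_path = os.path.join(out_dir, f"{pid}_{role}_mask.nii")
            lm_path = os.path.join(out_dir, f"{pid}_{role}_landmarks.txt")
            write_volume(vol, img_path)
            write_volume(mask, mask_path)
            write_landmarks(lms, lm_path)
            paths[role] = (img_path, mask_path, lm_path)
            rows.append(
                {
                    "split": split,
                    "pair_id": pid,
                    "role": role,
                    "h": h,
                    "replicate": -1,
                    "seed": pair_seed,
                    "path": img_path,
                    "mask_path": mask_path,
                    "landmarks_path": lm_path,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def pairs_for_evaluation(manifest: pd.DataFrame | str) -> list[dict]:
    """Convert a fixture manifest into ``evaluate_testset``-style pair dicts."""
    df = manifest if isinstance(manifest, pd.DataFrame) else pd.read_csv(
        manifest, keep_default_na=False
    )
    out = []
    for pid, grp in df.groupby("pair_id", sort=True):
        roles = {r["role"]: r for _, r in grp.iterrows()}
        fx, mv = roles["fixed"], roles["moving"]
        out.append(
            {
                "pair_id": pid,
                "fixed": fx["path"],
                "moving": mv["path"],
                "fixed_mask": fx["mask_path"] or None,
                "moving_mask": mv["mask_path"] or None,
                "landmarks_fixed": fx["landmarks_path"] or None,
                "landmarks_moving": mv["landmarks_path"] or None,
            }
        )
    return out
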