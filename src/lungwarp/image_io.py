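"""Volume and landmark I/O, intensity normalization, crop-and-resample.

Conventions
-----------
* Arrays are indexed ``(x, y, z)`` with x fastest in the written files;
  all shape triples in the package use this order.
* Voxel indices are 0-based internally.  Landmark files are 1-based on disk
  by default (the convention of DIR-Lab-style distributions); readers and
  writers convert.
* Masks are stored as float arrays with values in {0, 1}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from .errors import (
    ContractError,
    DegenerateInputError,
    DimensionalityError,
    LandmarkParseError,
    VolumeFormatError,
)

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mhd", ".mha")


@dataclass
class Volume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array, axis order (x, y, z).
    spacing:
        Per-axis voxel size in mm, strictly positive.
    origin:
        Per-axis world offset of voxel (0,0,0) in mm.
    is_mask:
        If true, every value must be 0 or 1 and nearest-neighbor
        interpolation is used for any resampling.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    is_mask: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"volume payload must be 3D, got shape {self.data.shape}"
            )
        if min(self.data.shape) < 2:
            raise ContractError(f"every dimension must be >= 2, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ContractError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.is_mask:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ContractError("mask volumes must contain only {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LandmarkSet:
    """N corresponding landmark positions as continuous 0-based voxel indices.

    ``frame`` records which image grid ("fixed" or "moving") the indices
    refer to; fixed/moving sets used together must have equal N.
    """

    points: np.ndarray
    frame: str = "fixed"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ContractError(f"landmarks must be (N, 3), got {self.points.shape}")
        if self.frame not in ("fixed", "moving"):
            raise ContractError(f"frame must be 'fixed' or 'moving', got {self.frame!r}")

    def __len__(self) -> int:
        return self.points.shape[0]


def _suffix(path: str) -> str:
    p = str(path).lower()
    for s in _NIFTI_SUFFIXES + _META_SUFFIXES:
        if p.endswith(s):
            return s
    raise VolumeFormatError(f"unsupported volume format: {path}")


def read_volume(path: str | os.PathLike, kind: str = "image") -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha) volume.

    Spacing and origin come from the file header.  With ``kind='mask'`` the
    payload is binarized by thresholding at 0.5.
    """
    if kind not in ("image", "mask"):
        raise ContractError(f"kind must be 'image' or 'mask', got {kind!r}")
    suffix = _suffix(path)
    try:
        if suffix in _NIFTI_SUFFIXES:
            img = nib.load(str(path))
            data = np.asarray(img.dataobj, dtype=np.float64)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            origin = tuple(float(t) for t in img.affine[:3, 3])
        else:
            img = sitk.ReadImage(str(path))
            # SimpleITK arrays come back (z, y, x); transpose to (x, y, z).
            data = sitk.GetArrayFromImage(img).astype(np.float64).transpose(2, 1, 0)
            spacing = tuple(float(s) for s in img.GetSpacing())
            origin = tuple(float(o) for o in img.GetOrigin())
    except (DimensionalityError, ContractError):
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D payload, got shape {data.shape}"
        )
    if kind == "mask":
        data = (data > 0.5).astype(np.float64)
    return Volume(data, spacing=spacing, origin=origin, is_mask=(kind == "mask"))


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI or MetaImage, mirroring ``read_volume``."""
    suffix = _suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        affine = np.diag(list(v.spacing) + [1.0])
        affine[:3, 3] = v.origin
        nib.save(nib.Nifti1Image(v.data.astype(np.float32), affine), str(path))
    else:
        img = sitk.GetImageFromArray(v.data.astype(np.float32).transpose(2, 1, 0))
        img.SetSpacing(tuple(v.spacing))
        img.SetOrigin(tuple(v.origin))
        sitk.WriteImage(img, str(path))


def normalize_intensity(v: Volume) -> Volume:
    """Linearly rescale intensities to [0, 1] (min -> 0, max -> 1)."""
    if v.is_mask:
        raise ContractError("normalize_intensity is undefined for masks")
    lo = float(v.data.min())
    hi = float(v.data.max())
    if hi <= lo:
        raise DegenerateInputError("cannot normalize a constant volume")
    return replace(v, data=(v.data - lo) / (hi - lo))


def union_mask(a: Volume, b: Volume) -> Volume:
    """Voxelwise union of two binary masks on the same grid."""
    if not (a.is_mask and b.is_mask):
        raise ContractError("union_mask requires mask volumes")
    if a.shape != b.shape:
        raise ContractError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return replace(a, data=np.maximum(a.data, b.data))


def _resample_to_shape(data: np.ndarray, target_shape, order: int) -> np.ndarray:
    """Resample by pixel-center mapping so physical extent is preserved.

    Output index i on an axis of length t samples input coordinate
    (i + 0.5) * n / t - 0.5, i.e. the identity when t == n and exact
    spacing-doubling when t == n // 2.
    """
    n = data.shape
    axes = [
        (np.arange(t, dtype=np.float64) + 0.5) * n[d] / t - 0.5
        for d, t in enumerate(target_shape)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = map_coordinates(data, coords, order=order, mode="nearest")
    return out.reshape(tuple(target_shape))


def crop_resample(
    v: Volume,
    mask: Volume,
    target_shape: tuple[int, int, int],
    margin: int = 2,
) -> Volume:
    """Crop to the mask bounding box (plus margin) and resample to target_shape.

    The crop uses the bounding box of ``mask > 0`` expanded by ``margin``
    voxels and clipped to the volume.  Images are resampled trilinearly,
    masks nearest-neighbor, and the spacing is rescaled so the physical
    extent of the cropped region is preserved.
    """
    if v.shape != mask.shape:
        raise ContractError(f"volume/mask shapes differ: {v.shape} vs {mask.shape}")
    if any(t < 2 for t in target_shape):
        raise ContractError(f"target_shape components must be >= 2, got {target_shape}")
    nz = np.nonzero(mask.data > 0)
    if nz[0].size == 0:
        raise DegenerateInputError("empty mask: nothing to crop")
    lo = [max(int(idx.min()) - margin, 0) for idx in nz]
    hi = [min(int(idx.max()) + margin + 1, v.shape[d]) for d, idx in enumerate(nz)]
    cropped = v.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    order = 0 if v.is_mask else 1
    out = _resample_to_shape(cropped, target_shape, order=order)
    if v.is_mask:
        out = (out > 0.5).astype(np.float64)
    new_spacing = tuple(
        v.spacing[d] * cropped.shape[d] / target_shape[d] for d in range(3)
    )
    new_origin = tuple(v.origin[d] + lo[d] * v.spacing[d] for d in range(3))
    return Volume(out, spacing=new_spacing, origin=new_origin, is_mask=v.is_mask)


def read_landmarks(
    path: str | os.PathLike, frame: str = "fixed", one_based: bool = True
) -> LandmarkSet:
    """Read landmark triples (one per line, whitespace or comma separated).

    Input indices are 1-based by default (DIR-Lab distribution convention)
    and converted to the package's 0-based convention.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.replace(",", " ").strip()
            if not text or text.startswith("#"):
                continue
            fields = text.split()
            if len(fields) != 3:
                raise LandmarkParseError(
                    f"{path}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise LandmarkParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise LandmarkParseError(f"{path}: no landmark rows found")
    pts = np.asarray(rows, dtype=np.float64)
    if one_based:
        pts = pts - 1.0
    return LandmarkSet(pts, frame=frame)


def write_landmarks(
    lms: LandmarkSet, path: str | os.PathLike, one_based: bool = True
) -> None:
    """Write landmarks one triple per line, mirroring ``read_landmarks``."""
    pts = lms.points + (1.0 if one_based else 0.0)
    with open(path, "w") as fh:
        for p in pts:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
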