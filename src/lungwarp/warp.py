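"""Spatial transformation layer: warp a volume by a dense displacement field.

The displacement field ``s`` lives on the fixed grid in voxel units and the
full spatial map is ``phi(p) = p + s(p)``: each output voxel samples the
moving image at ``p + s(p)``.  Images are interpolated trilinearly (the
differentiable path used during training), masks nearest-neighbor with
half-up rounding; sample coordinates clamp to the volume border.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from . import autodiff as ad
from .errors import ContractError
from .image_io import Volume


@dataclass
class DisplacementField:
    """Per-voxel 3-vector offsets on the fixed grid, in voxel units.

    ``vectors`` has the fixed volume's shape plus a trailing component axis
    of size 3 (components ordered x, y, z).
    """

    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ContractError(
                f"field must be (D, H, W, 3), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ContractError("field components must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    @classmethod
    def zeros(cls, shape: tuple[int, int, int]) -> "DisplacementField":
        return cls(np.zeros(tuple(shape) + (3,)))

    def channel_first(self) -> np.ndarray:
        return np.moveaxis(self.vectors, -1, 0)


def _check_shapes(vol: Volume, field: DisplacementField) -> None:
    if vol.shape != field.grid_shape:
        raise ContractError(
            f"field grid {field.grid_shape} does not match volume {vol.shape}"
        )


def sample_coordinates(field: DisplacementField) -> np.ndarray:
    """(3, D, H, W) array of source sample coordinates p + s(p)."""
    base = np.indices(field.grid_shape, dtype=np.float64)
    return base + field.channel_first()


def warp_trilinear(moving: Volume, field: DisplacementField) -> Volume:
    """Warp an image by the field with trilinear interpolation (clamped border)."""
    _check_shapes(moving, field)
    coords = sample_coordinates(field)
    data = map_coordinates(
        moving.data, coords.reshape(3, -1), order=1, mode="nearest"
    ).reshape(moving.shape)
    return replace(moving, data=data)


def warp_nearest(mask: Volume, field: DisplacementField) -> Volume:
    """Warp a binary mask by the field with nearest-neighbor sampling.

    Rounding is half-up per axis so mask warps are bit-reproducible.
    """
    if not mask.is_mask:
        raise ContractError("warp_nearest expects a mask volume")
    _check_shapes(mask, field)
    coords = sample_coordinates(field)
    idx = [
        np.clip(np.floor(coords[a] + 0.5).astype(np.intp), 0, mask.shape[a] - 1)
        for a in range(3)
    ]
    data = mask.data[idx[0], idx[1], idx[2]]
    return replace(mask, data=data)


def warp_trilinear_t(moving: ad.Tensor, field_cf: ad.Tensor) -> ad.Tensor:
    """Differentiable trilinear warp on autodiff tensors.

    ``moving`` is (D, H, W) and ``field_cf`` channel-first (3, D, H, W);
    identical semantics to :func:`warp_trilinear` (tested equivalent).
    """
    return ad.grid_warp_trilinear(moving, field_cf)
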