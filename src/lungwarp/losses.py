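"""The composite registration objective and its components.

* ``Lsim`` — one minus the mean windowed squared normalized cross-correlation
  between the fixed and the warped moving image.  Window statistics (default
  11^3) are mean-subtracted; the squared covariance is divided by the product
  of the two windowed sums of squares plus a stabilizing epsilon, so each
  voxel's score lies in [0, 1) and the mean over the volume is in [0, 1].
  Windows are clipped at the volume border (in-bounds counts).
* ``Rjac`` — the folding penalty ``sum_p (|det J(p)| - det J(p))`` where
  ``J(p) = I + d s / d p`` is the Jacobian of the full map phi = id + s;
  zero iff all determinants are >= 0, and activated by any transformation
  with a negative determinant.
* ``Rder`` — first-derivative smoothness ``sum_p ||grad s(p)||_F^2`` (all
  nine partials, same finite-difference scheme as the Jacobian: forward
  differences with a backward fallback at the far border).
* total = Lsim + beta * Rjac + alpha * Rder.

All components are implemented once on autodiff tensors — the training loop
differentiates through the very same code the public (float-returning)
functions call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .errors import ContractError
from .image_io import Volume
from .warp import DisplacementField


@dataclass
class LossWeights:
    """Hyperparameters of the training objective.

    ``alpha`` weights the smoothness term (default 1), ``beta`` the folding
    penalty (useful range 1e-5..1e-2: smaller beta favors accuracy, larger
    beta suppresses folding), ``ncc_window`` is the odd cubic window edge in
    voxels, and ``epsilon`` stabilizes the NCC denominator.
    """

    alpha: float = 1.0
    beta: float = 1e-5
    ncc_window: int = 11
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        self.alpha = float(self.alpha)
        self.beta = float(self.beta)
        self.ncc_window = int(self.ncc_window)
        self.epsilon = float(self.epsilon)
        if self.ncc_window < 3 or self.ncc_window % 2 == 0:
            raise ContractError(f"ncc_window must be odd and >= 3, got {self.ncc_window}")
        if min(self.alpha, self.beta, self.epsilon) < 0:
            raise ContractError("alpha, beta and epsilon must be >= 0")


@dataclass
class LossReport:
    """Loss components for one pair; total = l_sim + beta*r_jac + alpha*r_der."""

    l_sim: float
    r_jac: float
    r_der: float
    total: float
    folding_count: int
    weights: LossWeights = field(default_factory=LossWeights)

    def to_json(self) -> str:
        return json.dumps(
            {
                "l_sim": self.l_sim,
                "r_jac": self.r_jac,
                "r_der": self.r_der,
                "total": self.total,
                "folding_count": self.folding_count,
                "alpha": self.weights.alpha,
                "beta": self.weights.beta,
                "window": self.weights.ncc_window,
            }
        )


def _as_array(v) -> np.ndarray:
    if isinstance(v, Volume):
        return v.data
    return np.asarray(v, dtype=np.float64)


def _as_field_cf(f) -> np.ndarray:
    """Channel-first (3, D, H, W) view of a displacement field argument."""
    if isinstance(f, DisplacementField):
        return f.channel_first()
    arr = np.asarray(f, dtype=np.float64)
    if arr.ndim == 4 and arr.shape[-1] == 3:
        return np.moveaxis(arr, -1, 0)
    if arr.ndim == 4 and arr.shape[0] == 3:
        return arr
    raise ContractError(f"cannot interpret shape {arr.shape} as a displacement field")


# -- similarity --------------------------------------------------------------


def local_ncc_t(fixed, warped, window: int = 11, epsilon: float = 1e-5) -> ad.Tensor:
    """Mean windowed squared NCC as an autodiff scalar.

    For each voxel p the mean-subtracted window covariance is squared and
    divided by the product of the two windowed sums of squares (plus
    epsilon); the result is averaged over all voxels.
    """
    f = ad.as_tensor(fixed)
    m = ad.as_tensor(warped)
    if f.shape != m.shape:
        raise ContractError(f"shape mismatch: {f.shape} vs {m.shape}")
    if window % 2 == 0:
        raise ContractError(f"window must be odd, got {window}")
    counts = ad.box_sum(ad.Tensor(np.ones(f.shape)), window)  # in-bounds voxels
    sf = ad.box_sum(f, window)
    sm = ad.box_sum(m, window)
    sff = ad.box_sum(f * f, window)
    smm = ad.box_sum(m * m, window)
    sfm = ad.box_sum(f * m, window)
    cross = sfm - sf * sm / counts
    var_f = sff - sf * sf / counts
    var_m = smm - sm * sm / counts
    cc = cross * cross / (var_f * var_m + epsilon)
    return cc.mean()


def sim_loss_t(fixed, warped, window: int = 11, epsilon: float = 1e-5) -> ad.Tensor:
    """Lsim = 1 - NCC (autodiff scalar)."""
    return 1.0 - local_ncc_t(fixed, warped, window, epsilon)


def local_ncc(fixed, warped, window: int = 11, epsilon: float = 1e-5) -> float:
    """Mean windowed squared NCC of two volumes, in [0, 1]."""
    return local_ncc_t(_as_array(fixed), _as_array(warped), window, epsilon).item()


def sim_loss(fixed, warped, window: int = 11, epsilon: float = 1e-5) -> float:
    """Similarity loss 1 - NCC, in [0, 1]."""
    return 1.0 - local_ncc(fixed, warped, window, epsilon)


# -- regularizers ------------------------------------------------------------


def jacobian_det_t(field_cf) -> ad.Tensor:
    """Per-voxel determinant of J(p) = I + ds/dp (autodiff tensor).

    ``field_cf`` is channel-first (3, D, H, W).  Partials use forward finite
    differences with a backward fallback at the last index of each axis; the
    identity (zero) field yields 1.0 everywhere.
    """
    s = ad.as_tensor(field_cf)
    if s.ndim != 4 or s.shape[0] != 3:
        raise ContractError(f"expected (3, D, H, W) field, got {s.shape}")
    if min(s.shape[1:]) < 2:
        raise ContractError("field must have at least 2 voxels per axis")
    j = [[ad.fdiff(s[a], axis=b) for b in range(3)] for a in range(3)]
    for a in range(3):
        j[a][a] = j[a][a] + 1.0
    return (
        j[0][0] * (j[1][1] * j[2][2] - j[1][2] * j[2][1])
        - j[0][1] * (j[1][0] * j[2][2] - j[1][2] * j[2][0])
        + j[0][2] * (j[1][0] * j[2][1] - j[1][1] * j[2][0])
    )


def jac_penalty_t(field_cf) -> ad.Tensor:
    """Rjac = sum_p (|det J(p)| - det J(p)) as an autodiff scalar."""
    det = jacobian_det_t(field_cf)
    return (ad.absolute(det) - det).sum()


def grad_penalty_t(field_cf) -> ad.Tensor:
    """Rder = sum_p ||grad s(p)||_F^2 (all nine partials) as an autodiff scalar."""
    s = ad.as_tensor(field_cf)
    if s.ndim != 4 or s.shape[0] != 3:
        raise ContractError(f"expected (3, D, H, W) field, got {s.shape}")
    total = None
    for a in range(3):
        for b in range(3):
            d = ad.fdiff(s[a], axis=b)
            term = (d * d).sum()
            total = term if total is None else total + term
    return total


def jacobian_determinant_map(field) -> Volume:
    """Per-voxel Jacobian determinant of the full map, as a Volume."""
    det = jacobian_det_t(_as_field_cf(field)).data
    return Volume(det)


def jac_penalty(field) -> float:
    """Folding penalty; 0 iff every determinant is >= 0."""
    return jac_penalty_t(_as_field_cf(field)).item()


def grad_penalty(field) -> float:
    """First-derivative smoothness penalty (sum of squared partials)."""
    return grad_penalty_t(_as_field_cf(field)).item()


def count_folding(field) -> int:
    """Number of voxels with determinant <= 0 (folding criterion)."""
    det = jacobian_det_t(_as_field_cf(field)).data
    return int(np.count_nonzero(det <= 0))


# -- composite ---------------------------------------------------------------


def total_loss_t(fixed, warped, field_cf, w: LossWeights):
    """Autodiff total loss and its component scalars.

    Returns ``(loss, l_sim, r_jac, r_der)`` as autodiff tensors sharing one
    graph, so a single ``backward()`` covers every term.
    """
    l_sim = sim_loss_t(fixed, warped, w.ncc_window, w.epsilon)
    r_jac = jac_penalty_t(field_cf)
    r_der = grad_penalty_t(field_cf)
    loss = l_sim + w.beta * r_jac + w.alpha * r_der
    return loss, l_sim, r_jac, r_der


def total_loss(fixed, warped, field, w: LossWeights | None = None) -> LossReport:
    """Evaluate the full objective for one pair and report all components."""
    w = w or LossWeights()
    field_cf = _as_field_cf(field)
    loss, l_sim, r_jac, r_der = total_loss_t(
        _as_array(fixed), _as_array(warped), field_cf, w
    )
    return LossReport(
        l_sim=l_sim.item(),
        r_jac=r_jac.item(),
        r_der=r_der.item(),
        total=loss.item(),
        folding_count=count_folding(field_cf),
        weights=w,
    )
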