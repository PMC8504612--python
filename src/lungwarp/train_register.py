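"""Unsupervised training loop and one-shot pairwise registration.

Training follows the unsupervised registration recipe: each (moving, fixed)
pair is concatenated into a two-channel volume, the network predicts a dense
displacement field, the moving image is warped through the differentiable
trilinear layer, and the composite loss (windowed NCC + beta*Rjac +
alpha*Rder) is minimized with Adam.  Defaults: learning rate 1e-4, batch
size 1, 20 epochs.  With batch sizes above 1 gradients are accumulated over
that many pairs before each optimizer step.

Once trained, a pair of unseen preprocessed volumes is registered in a
single forward pass.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .errors import ContractError, ManifestError
from .image_io import Volume, read_volume
from .losses import LossReport, LossWeights, count_folding, total_loss_t
from .network import (
    DisplacementNet,
    NetworkConfig,
    build_network,
    load_checkpoint,
    save_checkpoint,
)
from .warp import DisplacementField, warp_trilinear_t


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the training recipe)."""

    learning_rate: float = 1e-4
    epochs: int = 20
    batch_size: int = 1
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    checkpoint_dir: str = "checkpoints"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ContractError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ContractError("epochs and batch_size must be >= 1")


@dataclass
class RegistrationResult:
    """Output of one-shot registration of a preprocessed pair."""

    field: DisplacementField
    warped: Volume
    report: LossReport


def _pairs_from_manifest(manifest) -> pd.DataFrame:
    """Normalize a manifest argument into a one-row-per-pair table."""
    if hasattr(manifest, "records"):
        df = manifest.records
    elif isinstance(manifest, pd.DataFrame):
        df = manifest
    else:
        df = pd.read_csv(manifest, keep_default_na=False)
    required = {"split", "pair_id", "role", "path"}
    if not required.issubset(df.columns):
        raise ManifestError(f"manifest must have columns {sorted(required)}")
    key_cols = [c for c in ("pair_id", "h", "replicate") if c in df.columns]
    rows = []
    for key, grp in df.groupby(key_cols, sort=True):
        roles = dict(zip(grp["role"], grp["path"]))
        if "fixed" not in roles or "moving" not in roles:
            raise ManifestError(f"pair {key} lacks a fixed/moving role")
        rows.append(
            {
                "pair_key": "_".join(str(k) for k in (key if isinstance(key, tuple) else (key,))),
                "split": grp["split"].iloc[0],
                "fixed_path": roles["fixed"],
                "moving_path": roles["moving"],
            }
        )
    return pd.DataFrame(rows)


class _VolumeCache:
    """Read-through cache of normalized training volumes (desk-scale sizes)."""

    def __init__(self):
        self._store: dict[str, np.ndarray] = {}

    def get(self, path: str) -> np.ndarray:
        if path not in self._store:
            self._store[path] = read_volume(path).data
        return self._store[path]


def _pair_loss(model: DisplacementNet, moving: np.ndarray, fixed: np.ndarray,
               w: LossWeights, with_grad: bool):
    """Forward pass + composite loss for one pair.

    Returns the scalar loss tensor (graph attached only when ``with_grad``).
    """
    x = ad.Tensor(np.stack([moving, fixed]))
    field = model(x)
    if not with_grad:
        field = ad.Tensor(field.data)  # detach: validation never backprops
    mov = ad.Tensor(moving)
    warped = warp_trilinear_t(mov, field)
    loss, _, _, _ = total_loss_t(fixed, warped, field, w)
    return loss


def train(manifest, cfg: TrainConfig, net_cfg: NetworkConfig) -> str:
    """Train the displacement network on the manifest's train/val splits.

    Per-epoch mean training and validation losses are appended to
    ``curve.csv`` in the checkpoint directory; the checkpoint with the best
    validation loss (training loss when the manifest has no validation
    split) is retained as ``best.npz`` and its path returned.  All
    randomness (initialization, data order) derives from ``cfg.seed``.
    """
    pairs = _pairs_from_manifest(manifest)
    missing = [
        p for p in pd.concat([pairs["fixed_path"], pairs["moving_path"]])
        if not os.path.exists(p)
    ]
    if missing:
        raise ManifestError(f"manifest references missing files: {missing[:5]}")
    train_pairs = pairs[pairs["split"] == "train"].reset_index(drop=True)
    val_pairs = pairs[pairs["split"] == "val"].reset_index(drop=True)
    if len(train_pairs) == 0:
        raise ManifestError("manifest has no training pairs")

    os.makedirs(cfg.checkpoint_dir, exist_ok=True)
    model = build_network(net_cfg, seed=cfg.seed)
    opt = ad.Adam(model.parameters(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    cache = _VolumeCache()
    w = cfg.loss_weights

    best_path = os.path.join(cfg.checkpoint_dir, "best.npz")
    curve_rows = []
    best_score = np.inf
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(train_pairs))
        epoch_losses = []
        pending = 0
        opt.zero_grad()
        for idx in order:
            row = train_pairs.iloc[idx]
            moving = cache.get(row["moving_path"])
            fixed = cache.get(row["fixed_path"])
            loss = _pair_loss(model, moving, fixed, w, with_grad=True)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss on pair {row['pair_key']} (epoch {epoch})"
                )
            loss.backward()
            epoch_losses.append(loss.item())
            pending += 1
            if pending >= cfg.batch_size:
                opt.step()
                opt.zero_grad()
                pending = 0
        if pending:
            opt.step()
            opt.zero_grad()
        train_loss = float(np.mean(epoch_losses))
        if len(val_pairs):
            val_losses = [
                _pair_loss(
                    model,
                    cache.get(r["moving_path"]),
                    cache.get(r["fixed_path"]),
                    w,
                    with_grad=False,
                ).item()
                for _, r in val_pairs.iterrows()
            ]
            val_loss = float(np.mean(val_losses))
            score = val_loss
        else:
            val_loss = np.nan
            score = train_loss
        curve_rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if score < best_score:
            best_score = score
            save_checkpoint(
                model,
                best_path,
                extra={
                    "train": {
                        "learning_rate": cfg.learning_rate,
                        "epochs": cfg.epochs,
                        "batch_size": cfg.batch_size,
                        "seed": cfg.seed,
                        "best_epoch": epoch,
                    },
                    "loss_weights": {
                        "alpha": w.alpha,
                        "beta": w.beta,
                        "ncc_window": w.ncc_window,
                        "epsilon": w.epsilon,
                    },
                },
            )
    pd.DataFrame(curve_rows).to_csv(
        os.path.join(cfg.checkpoint_dir, "curve.csv"), index=False
    )
    return best_path


def _weights_from_meta(meta: dict) -> LossWeights:
    lw = meta.get("loss_weights", {})
    return LossWeights(
        alpha=float(lw.get("alpha", 1.0)),
        beta=float(lw.get("beta", 1e-5)),
        ncc_window=int(lw.get("ncc_window", 11)),
        epsilon=float(lw.get("epsilon", 1e-5)),
    )


def register_pair(checkpoint: str, moving: Volume, fixed: Volume) -> RegistrationResult:
    """Register a preprocessed pair in one forward pass.

    Both volumes must match the checkpoint's input shape and share a grid.
    """
    model, meta = load_checkpoint(checkpoint)
    expected = tuple(model.cfg.input_shape)
    if moving.shape != fixed.shape:
        raise ContractError(f"pair shapes differ: {moving.shape} vs {fixed.shape}")
    if tuple(moving.shape) != expected:
        raise ContractError(
            f"volume shape {moving.shape} does not match checkpoint input {expected}"
        )
    w = _weights_from_meta(meta)
    x = ad.Tensor(np.stack([moving.data, fixed.data]))
    field_t = model(x)
    vectors = np.moveaxis(field_t.data, 0, -1)
    field = DisplacementField(vectors)
    warped_t = warp_trilinear_t(ad.Tensor(moving.data), ad.Tensor(field_t.data))
    warped = Volume(warped_t.data, spacing=fixed.spacing, origin=fixed.origin)
    loss, l_sim, r_jac, r_der = total_loss_t(
        fixed.data, warped_t.data, field_t.data, w
    )
    report = LossReport(
        l_sim=l_sim.item(),
        r_jac=r_jac.item(),
        r_der=r_der.item(),
        total=loss.item(),
        folding_count=count_folding(field_t.data),
        weights=w,
    )
    return RegistrationResult(field=field, warped=warped, report=report)


def content_hash(paths) -> str:
    """Stable content hash of a list of input files (for run records)."""
    digest = hashlib.sha256()
    for p in sorted(str(p) for p in paths):
        digest.update(p.encode())
        if os.path.exists(p):
            with open(p, "rb") as fh:
                digest.update(fh.read())
    return digest.hexdigest()[:16]
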