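"""Displacement-predicting ConvNet: encoder-decoder with inception skip paths.

The network maps a two-channel volume (moving and fixed concatenated) to a
three-channel dense displacement field of the same spatial shape.  The
encoder applies three stride-2 3x3x3 convolutions (spatial reduction to
(1/2)^3); each feature map that is about to be downsampled — the two-channel
input and the first two encoder outputs — also passes through an inception
module (parallel convolutions with different kernel sizes, concatenated and
reduced by a 1x1x1 convolution) on its skip path before being concatenated
into the decoder.  The decoder upsamples three times with stride-2 transposed
convolutions (zero-insertion followed by a 3x3x3 convolution).  Every
convolution block is followed by per-channel spatial normalization (batch
normalization at batch size 1) and LeakyReLU, except the final linear 3x3x3
convolution whose output may take any sign.  The final convolution is
initialized near zero so the untrained network starts close to the identity
map.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import autodiff as ad
from .errors import ContractError


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``enc_channels`` gives the width of each of the three encoder stages;
    widths are exposed so the full-scale model (input 224x144x192) and toy
    desk-scale models share one code path.
    """

    input_shape: tuple[int, int, int] = (224, 144, 192)
    enc_channels: tuple[int, int, int] = (16, 32, 64)
    inception_branch_kernels: tuple[int, ...] = (1, 3, 5)
    inception_branch_channels: int = 4
    leaky_slope: float = 0.2
    use_batch_norm: bool = True

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(d) for d in self.input_shape)
        self.enc_channels = tuple(int(c) for c in self.enc_channels)
        self.inception_branch_kernels = tuple(
            int(k) for k in self.inception_branch_kernels
        )
        if len(self.enc_channels) != 3:
            raise ContractError("exactly three stride-2 encoder stages are required")
        if any(d % 8 != 0 for d in self.input_shape):
            raise ContractError(
                f"every input dimension must be divisible by 8, got {self.input_shape}"
            )
        if any(k % 2 == 0 for k in self.inception_branch_kernels):
            raise ContractError("inception branch kernels must all be odd")

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "enc_channels": list(self.enc_channels),
            "inception_branch_kernels": list(self.inception_branch_kernels),
            "inception_branch_channels": self.inception_branch_channels,
            "leaky_slope": self.leaky_slope,
            "use_batch_norm": self.use_batch_norm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(
            input_shape=tuple(d["input_shape"]),
            enc_channels=tuple(d["enc_channels"]),
            inception_branch_kernels=tuple(d["inception_branch_kernels"]),
            inception_branch_channels=int(d["inception_branch_channels"]),
            leaky_slope=float(d["leaky_slope"]),
            use_batch_norm=bool(d["use_batch_norm"]),
        )


class Conv3d:
    """3x3x3 (or kxkxk) convolution layer with He-style initialization."""

    def __init__(self, name, cin, cout, k=3, stride=1, rng=None, w_scale=None,
                 bias=True):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k**3
        scale = w_scale if w_scale is not None else np.sqrt(2.0 / fan_in)
        self.w = ad.Tensor(rng.normal(0.0, scale, (cout, cin, k, k, k)), requires_grad=True)
        self.b = ad.Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride = stride
        self.name = name

    def __call__(self, x):
        return ad.conv3d(x, self.w, self.b, stride=self.stride)

    def params(self):
        out = [(f"{self.name}.w", self.w)]
        if self.b is not None:
            out.append((f"{self.name}.b", self.b))
        return out


class SpatialNorm:
    """Learnable per-channel spatial normalization (BN at batch size 1)."""

    def __init__(self, name, channels):
        self.gamma = ad.Tensor(np.ones((channels, 1, 1, 1)), requires_grad=True)
        self.beta = ad.Tensor(np.zeros((channels, 1, 1, 1)), requires_grad=True)
        self.name = name

    def __call__(self, x):
        return ad.spatial_norm(x, self.gamma, self.beta)

    def params(self):
        return [(f"{self.name}.gamma", self.gamma), (f"{self.name}.beta", self.beta)]


class ConvBlock:
    """conv -> (norm) -> LeakyReLU."""

    def __init__(self, name, cin, cout, k=3, stride=1, rng=None, cfg: NetworkConfig = None):
        self.conv = Conv3d(f"{name}.conv", cin, cout, k=k, stride=stride, rng=rng)
        self.norm = SpatialNorm(f"{name}.norm", cout) if cfg.use_batch_norm else None
        self.slope = cfg.leaky_slope

    def __call__(self, x):
        y = self.conv(x)
        if self.norm is not None:
            y = self.norm(y)
        return ad.leaky_relu(y, self.slope)

    def params(self):
        out = self.conv.params()
        if self.norm is not None:
            out += self.norm.params()
        return out


class Inception:
    """Parallel multi-kernel convolutions, concatenated, then 1x1x1 reduced.

    Channel-preserving: the reduce convolution maps the concatenated branch
    outputs back to the input channel count so skip concatenation widths stay
    predictable.
    """

    def __init__(self, name, channels, rng, cfg: NetworkConfig):
        b = cfg.inception_branch_channels
        self.branches = [
            ConvBlock(f"{name}.branch{k}", channels, b, k=k, rng=rng, cfg=cfg)
            for k in cfg.inception_branch_kernels
        ]
        nb = b * len(cfg.inception_branch_kernels)
        self.reduce = ConvBlock(f"{name}.reduce", nb, channels, k=1, rng=rng, cfg=cfg)

    def __call__(self, x):
        y = ad.concat([br(x) for br in self.branches], axis=0)
        return self.reduce(y)

    def params(self):
        out = []
        for br in self.branches:
            out += br.params()
        out += self.reduce.params()
        return out


class UpBlock:
    """Stride-2 transposed convolution: zero-insertion + 3x3x3 conv block."""

    def __init__(self, name, cin, cout, rng, cfg: NetworkConfig):
        self.block = ConvBlock(f"{name}.conv", cin, cout, k=3, rng=rng, cfg=cfg)

    def __call__(self, x):
        return self.block(ad.upsample_zeros(x))

    def params(self):
        return self.block.params()


class DisplacementNet:
    """Encoder-decoder displacement network with inception skip paths."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c1, c2, c3 = cfg.enc_channels
        self.enc1 = ConvBlock("enc1", 2, c1, stride=2, rng=rng, cfg=cfg)
        self.enc2 = ConvBlock("enc2", c1, c2, stride=2, rng=rng, cfg=cfg)
        self.enc3 = ConvBlock("enc3", c2, c3, stride=2, rng=rng, cfg=cfg)
        self.skip0 = Inception("skip0", 2, rng, cfg)
        self.skip1 = Inception("skip1", c1, rng, cfg)
        self.skip2 = Inception("skip2", c2, rng, cfg)
        self.up3 = UpBlock("up3", c3, c2, rng, cfg)
        self.mix2 = ConvBlock("mix2", 2 * c2, c2, rng=rng, cfg=cfg)
        self.up2 = UpBlock("up2", c2, c1, rng, cfg)
        self.mix1 = ConvBlock("mix1", 2 * c1, c1, rng=rng, cfg=cfg)
        self.up1 = UpBlock("up1", c1, c1, rng, cfg)
        self.mix0 = ConvBlock("mix0", c1 + 2, c1, rng=rng, cfg=cfg)
        # near-identity start: tiny weights so the initial field is ~0
        self.head = Conv3d("head", c1, 3, k=3, rng=rng, w_scale=1e-5)
        self._layers = [
            self.enc1, self.enc2, self.enc3,
            self.skip0, self.skip1, self.skip2,
            self.up3, self.mix2, self.up2, self.mix1, self.up1, self.mix0,
            self.head,
        ]

    def __call__(self, x) -> ad.Tensor:
        """Map a (2, D, H, W) input tensor to a (3, D, H, W) field tensor."""
        x = ad.as_tensor(x)
        if x.ndim != 4 or x.shape[0] != 2:
            raise ContractError(f"expected (2, D, H, W) input, got {x.shape}")
        if any(d % 8 != 0 for d in x.shape[1:]):
            raise ContractError(f"spatial dims must be divisible by 8, got {x.shape[1:]}")
        e1 = self.enc1(x)
        e2 = self.enc2(e1)
        e3 = self.enc3(e2)
        d2 = self.mix2(ad.concat([self.up3(e3), self.skip2(e2)], axis=0))
        d1 = self.mix1(ad.concat([self.up2(d2), self.skip1(e1)], axis=0))
        d0 = self.mix0(ad.concat([self.up1(d1), self.skip0(x)], axis=0))
        return self.head(d0)  # linear activation: any sign possible

    def named_parameters(self):
        out = []
        for layer in self._layers:
            out += layer.params()
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]


def build_network(cfg: NetworkConfig, seed: int = 0) -> DisplacementNet:
    """Construct a displacement network from a validated config."""
    return DisplacementNet(cfg, seed=seed)


def count_parameters(model: DisplacementNet) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))


def summary(model: DisplacementNet) -> str:
    """Plain-text layer table with per-parameter sizes and the total count."""
    lines = [f"{'parameter':40s} {'shape':>20s} {'count':>10s}"]
    for name, p in model.named_parameters():
        lines.append(f"{name:40s} {str(p.data.shape):>20s} {p.data.size:>10d}")
    lines.append(f"{'total':40s} {'':>20s} {count_parameters(model):>10d}")
    return "\n".join(lines)


def save_checkpoint(model: DisplacementNet, path: str, extra: dict | None = None) -> None:
    """Save weights (npz) plus a YAML sidecar with the architecture config."""
    arrays = {name: p.data for name, p in model.named_parameters()}
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    meta = {"network": model.cfg.to_dict()}
    if extra:
        meta.update(extra)
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def _sidecar_path(path: str) -> str:
    base = path[:-4] if path.endswith(".npz") else path
    return base + ".yaml"


def load_checkpoint(path: str) -> tuple[DisplacementNet, dict]:
    """Load a checkpoint; returns the model and the sidecar metadata."""
    npz_path = path if path.endswith(".npz") else path + ".npz"
    if not os.path.exists(npz_path):
        raise FileNotFoundError(npz_path)
    with open(_sidecar_path(path)) as fh:
        meta = yaml.safe_load(fh)
    model = DisplacementNet(NetworkConfig.from_dict(meta["network"]))
    weights = np.load(npz_path)
    for name, p in model.named_parameters():
        p.data = np.asarray(weights[name], dtype=np.float64)
    return model, meta
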