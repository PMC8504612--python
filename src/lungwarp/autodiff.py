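"""Reverse-mode automatic differentiation over numpy arrays.

This is the package's numerical core: a small tape-based tensor type with
exactly the operations the registration pipeline needs — elementwise
arithmetic, reductions, 3D convolution (stride 1 and 2) and zero-insertion
upsampling, LeakyReLU, per-channel spatial normalization, window (box) sums
for the local NCC, finite differences for the Jacobian/smoothness penalties,
and a trilinear grid warp differentiable with respect to both the image and
the displacement field.  Every operation's gradient is validated against
central finite differences in the test suite.

Tensors are plain ``float64`` numpy arrays; convolutional feature maps use
channel-first layout ``(C, D, H, W)``.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.ndimage import uniform_filter


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd machinery -------------------------------------------------
    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape), dtype=np.float64)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self):
        return reduce_sum(self)

    def mean(self, axis=None, keepdims: bool = False):
        return reduce_mean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- elementwise arithmetic ------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _node(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    out_data = a.data**p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * 0.5 / np.maximum(out_data, 1e-300))

    return _node(out_data, (a,), backward)


def absolute(a) -> Tensor:
    """|x| with sign subgradient (0 at 0)."""
    a = as_tensor(a)
    out_data = np.abs(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.sign(a.data))

    return _node(out_data, (a,), backward)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, slope * a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.where(mask, 1.0, slope))

    return _node(out_data, (a,), backward)


# -- reductions, indexing, concatenation ------------------------------------


def reduce_sum(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.asarray(a.data.sum())

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _node(out_data, (a,), backward)


def reduce_mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = np.asarray(a.data.mean(axis=axis, keepdims=keepdims))
    count = a.data.size / max(out_data.size, 1)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g / count, a.data.shape).copy())

    return _node(out_data, (a,), backward)


def take(a, idx) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            buf = np.zeros_like(a.data)
            np.add.at(buf, idx, g)
            a._accumulate(buf)

    return _node(np.array(out_data), (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _node(out_data, tuple(tensors), backward)


# -- 3D convolution ----------------------------------------------------------


def conv3d(x, w, b=None, stride: int = 1) -> Tensor:
    """'Same'-padded 3D convolution (cross-correlation).

    ``x``: (C_in, D, H, W); ``w``: (C_out, C_in, k, k, k) with odd k;
    ``b``: (C_out,) or None.  With stride s the output spatial size is
    ceil(dim / s) for even dims.
    """
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    cout, cin, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    if x.data.shape[0] != cin:
        raise ValueError(f"conv3d: expected {cin} input channels, got {x.data.shape[0]}")
    if k % 2 != 1:
        raise ValueError("conv3d kernels must be odd")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
    do, ho, wo = (-(-d // stride) for d in x.data.shape[1:])
    # offset-loop formulation: cheaper than materializing im2col windows
    out_data = np.zeros((cout, do, ho, wo))
    for a_, b_, c_ in itertools.product(range(k), repeat=3):
        sl = xp[
            :,
            a_ : a_ + stride * do : stride,
            b_ : b_ + stride * ho : stride,
            c_ : c_ + stride * wo : stride,
        ]
        out_data += np.tensordot(w.data[:, :, a_, b_, c_], sl, axes=([1], [0]))
    if b is not None:
        out_data = out_data + b.data[:, None, None, None]

    def backward(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for a_, b_, c_ in itertools.product(range(k), repeat=3):
                sl = xp[
                    :,
                    a_ : a_ + stride * do : stride,
                    b_ : b_ + stride * ho : stride,
                    c_ : c_ + stride * wo : stride,
                ]
                gw[:, :, a_, b_, c_] = np.tensordot(
                    g, sl, axes=([1, 2, 3], [1, 2, 3])
                )
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for a_, b_, c_ in itertools.product(range(k), repeat=3):
                t = np.tensordot(w.data[:, :, a_, b_, c_], g, axes=([0], [0]))
                gxp[
                    :,
                    a_ : a_ + stride * do : stride,
                    b_ : b_ + stride * ho : stride,
                    c_ : c_ + stride * wo : stride,
                ] += t
            d, h, ww = x.data.shape[1:]
            x._accumulate(gxp[:, p : p + d, p : p + h, p : p + ww])

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def upsample_zeros(x) -> Tensor:
    """Zero-insertion 2x upsampling along the three spatial axes.

    Followed by a stride-1 ``conv3d`` this realizes a stride-2 transposed
    convolution.
    """
    x = as_tensor(x)
    c, d, h, w = x.data.shape
    out_data = np.zeros((c, 2 * d, 2 * h, 2 * w))
    out_data[:, ::2, ::2, ::2] = x.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g[:, ::2, ::2, ::2])

    return _node(out_data, (x,), backward)


def spatial_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes with affine rescale.

    At batch size 1 (the training regime here) this is what batch
    normalization degenerates to, computed from the current sample.
    Implemented as a composite of primitive ops so gradients come for free.
    """
    x = as_tensor(x)
    mu = x.mean(axis=(1, 2, 3), keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=(1, 2, 3), keepdims=True)
    inv = div(1.0, sqrt(var + eps))
    return xc * inv * gamma + beta


# -- windowed sums and finite differences ------------------------------------


def box_sum(x, window: int) -> Tensor:
    """Sum over a centered cubic window, zero beyond the border.

    The operator is self-adjoint (symmetric kernel, zero padding), so the
    backward pass is the same filter applied to the incoming gradient.
    """
    x = as_tensor(x)
    scale = float(window) ** x.data.ndim
    out_data = uniform_filter(x.data, size=window, mode="constant") * scale

    def backward(g):
        if x.requires_grad:
            x._accumulate(uniform_filter(g, size=window, mode="constant") * scale)

    return _node(out_data, (x,), backward)


def _fd_forward(a: np.ndarray, axis: int) -> np.ndarray:
    a2 = np.moveaxis(a, axis, 0)
    d = np.empty_like(a2)
    d[:-1] = a2[1:] - a2[:-1]
    d[-1] = a2[-1] - a2[-2]
    return np.moveaxis(d, 0, axis)


def _fd_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g2 = np.moveaxis(g, axis, 0)
    out = np.zeros_like(g2)
    out[1:] += g2[:-1]
    out[:-1] -= g2[:-1]
    out[-1] += g2[-1]
    out[-2] -= g2[-1]
    return np.moveaxis(out, 0, axis)


def fdiff(x, axis: int) -> Tensor:
    """Forward finite difference along ``axis``; backward at the last index."""
    x = as_tensor(x)
    out_data = _fd_forward(x.data, axis)

    def backward(g):
        if x.requires_grad:
            x._accumulate(_fd_adjoint(g, axis))

    return _node(out_data, (x,), backward)


# -- trilinear warp ----------------------------------------------------------


def grid_warp_trilinear(moving, field) -> Tensor:
    """Warp ``moving`` (D,H,W) by ``field`` (3,D,H,W) in voxel units.

    ``out(p) = moving(p + s(p))`` with trilinear interpolation; sample
    coordinates clamp to the volume border.  Differentiable with respect to
    both inputs (the coordinate gradient is zeroed where clamping is active).
    """
    moving, field = as_tensor(moving), as_tensor(field)
    shape = moving.data.shape
    if field.data.shape != (3,) + shape:
        raise ValueError(
            f"field shape {field.data.shape} incompatible with volume {shape}"
        )
    base = np.indices(shape, dtype=np.float64)
    coords = base + field.data
    dims = np.array(shape, dtype=np.float64)
    inside = [
        (coords[a] > 0.0) & (coords[a] < dims[a] - 1.0) for a in range(3)
    ]  # clamp ⇒ zero coordinate gradient outside
    cl = np.stack([np.clip(coords[a], 0.0, dims[a] - 1.0) for a in range(3)])
    c0 = np.minimum(np.floor(cl), dims[:, None, None, None] - 2.0).astype(np.intp)
    t = cl - c0
    corner_vals = {}
    corner_wgts = {}
    out_data = np.zeros(shape)
    for dx, dy, dz in itertools.product((0, 1), repeat=2 + 1):
        vals = moving.data[c0[0] + dx, c0[1] + dy, c0[2] + dz]
        wx = t[0] if dx else 1.0 - t[0]
        wy = t[1] if dy else 1.0 - t[1]
        wz = t[2] if dz else 1.0 - t[2]
        wgt = wx * wy * wz
        corner_vals[(dx, dy, dz)] = vals
        corner_wgts[(dx, dy, dz)] = wgt
        out_data += wgt * vals

    def backward(g):
        if moving.requires_grad:
            gm = np.zeros_like(moving.data)
            for (dx, dy, dz), wgt in corner_wgts.items():
                np.add.at(gm, (c0[0] + dx, c0[1] + dy, c0[2] + dz), wgt * g)
            moving._accumulate(gm)
        if field.requires_grad:
            gf = np.zeros_like(field.data)
            for (dx, dy, dz), vals in corner_vals.items():
                wx = t[0] if dx else 1.0 - t[0]
                wy = t[1] if dy else 1.0 - t[1]
                wz = t[2] if dz else 1.0 - t[2]
                sx = 1.0 if dx else -1.0
                sy = 1.0 if dy else -1.0
                sz = 1.0 if dz else -1.0
                gf[0] += g * vals * sx * wy * wz
                gf[1] += g * vals * wx * sy * wz
                gf[2] += g * vals * wx * wy * sz
            for a in range(3):
                gf[a] *= inside[a]
            field._accumulate(gf)

    return _node(out_data, (moving, field), backward)


# -- optimizer ---------------------------------------------------------------


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
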