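"""Trainable layers built on the autodiff engine.

Wraps the array-level operations of :mod:`rp2gauge.gauge_conv` and
:mod:`rp2gauge.padding` as differentiable layers, and adds the plain 3D
convolution, optimizer and learning-rate scheduler used by the residual
architectures.  The array-level functions remain the single source of truth
for the gauge layer semantics; the layers here share their expansion index
tables so both paths are numerically identical.
"""

from __future__ import annotations

import numpy as np

from . import gauge_conv as gc
from .atlas import AtlasGrid
from .autodiff import Tensor, einsum2, relu, tensor

__all__ = [
    "Parameter",
    "pad_scalar_op",
    "pad_regular_op",
    "hex_patches_op",
    "vertex_scatter_op",
    "Conv3d",
    "GaugeLift",
    "GaugeRegular",
    "GroupBatchNorm",
    "orientation_pool_op",
    "Adam",
    "ReduceLROnPlateau",
    "mse_loss",
]


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


# ---------------------------------------------------------------------------
# custom linear ops

def pad_scalar_op(atlas: AtlasGrid, x: Tensor) -> Tensor:
    """Differentiable scalar padding over ``x[..., H, W]``."""
    H, W = atlas.flat_layout
    zero, dst, src = atlas.zero_mask, atlas.pad_dst, atlas.pad_src

    def back(g):
        if not x.requires_grad:
            return
        gf = g.reshape(g.shape[:-2] + (H * W,)).copy()
        add = gf[..., dst]
        gf[..., dst] = 0.0
        gf[..., zero] = 0.0
        np.add.at(gf, (..., src), add)
        x._accumulate(gf.reshape(x.shape))

    from .padding import pad_scalar_values
    return Tensor(pad_scalar_values(atlas, x.data), _backward=back,
                  _parents=(x,))


def pad_regular_op(atlas: AtlasGrid, x: Tensor) -> Tensor:
    """Differentiable gauge-aware padding over ``x[..., 12, H, W]``."""
    H, W = atlas.flat_layout
    zero, dst, src, perm = (atlas.zero_mask, atlas.pad_dst, atlas.pad_src,
                            atlas.pad_perm)

    def back(g):
        if not x.requires_grad:
            return
        gf = g.reshape(g.shape[:-3] + (12, H * W)).copy()
        add = gf[..., dst]                      # [..., 12, n_pad]
        gf[..., dst] = 0.0
        gf[..., zero] = 0.0
        # forward: out[..., j, dst_t] = in[..., perm[t, j], src_t]
        np.add.at(gf, (..., perm.T, src[None, :]), add)
        x._accumulate(gf.reshape(x.shape))

    from .padding import pad_regular_values
    return Tensor(pad_regular_values(atlas, x.data), _backward=back,
                  _parents=(x,))


def hex_patches_op(x: Tensor) -> Tensor:
    """Differentiable 7-sample stencil stack ``[..., H, W] -> [..., 7, H, W]``."""
    H, W = x.shape[-2:]

    def back(g):
        if not x.requires_grad:
            return
        gp = np.zeros(x.shape[:-2] + (H + 2, W + 2), dtype=g.dtype)
        for j, (dr, dc) in enumerate(gc.STENCIL_CELLS):
            gp[..., 1 + dr:1 + dr + H, 1 + dc:1 + dc + W] += g[..., j, :, :]
        x._accumulate(gp[..., 1:1 + H, 1:1 + W])

    return Tensor(gc.hex_patches(x.data), _backward=back, _parents=(x,))


def vertex_scatter_op(atlas: AtlasGrid, x: Tensor) -> Tensor:
    """Broadcast per-vertex values ``[..., n_signal]`` to the flat layout."""
    H, W = atlas.flat_layout
    live = ~atlas.zero_mask
    sig = atlas.signal_vertex_ids
    # position -> index into the signal-vertex list
    sig_index = np.full(atlas.n_vertices, -1, dtype=np.intp)
    sig_index[sig] = np.arange(len(sig))
    pos_sig = sig_index[atlas.position_vertex[live]]

    def back(g):
        if not x.requires_grad:
            return
        gf = g.reshape(g.shape[:-2] + (H * W,))
        gx = np.zeros(x.shape, dtype=g.dtype)
        np.add.at(gx, (..., pos_sig), gf[..., live])
        x._accumulate(gx)

    out = np.zeros(x.shape[:-1] + (H * W,), dtype=x.data.dtype)
    out[..., live] = x.data[..., pos_sig]
    return Tensor(out.reshape(x.shape[:-1] + (H, W)), _backward=back,
                  _parents=(x,))


def _im2col3d(x: Tensor) -> Tensor:
    """3x3x3 neighbourhoods with zero padding:
    ``[B, C, D, H, W] -> [B, C, 27, D, H, W]``."""
    B, C, D, H, W = x.shape
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]

    def back(g):
        if not x.requires_grad:
            return
        gp = np.zeros((B, C, D + 2, H + 2, W + 2), dtype=g.dtype)
        for n, (i, j, k) in enumerate(offs):
            gp[:, :, 1 + i:1 + i + D, 1 + j:1 + j + H, 1 + k:1 + k + W] += \
                g[:, :, n]
        x._accumulate(gp[:, :, 1:1 + D, 1:1 + H, 1:1 + W])

    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    cols = np.empty((B, C, 27, D, H, W), dtype=x.data.dtype)
    for n, (i, j, k) in enumerate(offs):
        cols[:, :, n] = xp[:, :, 1 + i:1 + i + D, 1 + j:1 + j + H,
                           1 + k:1 + k + W]
    return Tensor(cols, _backward=back, _parents=(x,))


# ---------------------------------------------------------------------------
# layers

def _hex_conv(xp: Tensor, weight: Tensor, kind: str) -> Tensor:
    """Fused hexagonal group convolution on a padded flat map.

    ``kind='scalar'``: ``xp [B, Ci, H, W]``, ``weight [Co, Ci, 7]`` ->
    ``[B, Co, 12, H, W]``.  ``kind='regular'``: ``xp [B, Ci, 12, H, W]``,
    ``weight [Co, Ci, 12, 7]`` -> ``[B, Co, 12, H, W]``.  Iterates over the
    seven stencil cells on shifted views of the padded array, avoiding the
    memory blow-up of materialized patch stacks; numerically identical to the
    array-level layers in :mod:`rp2gauge.gauge_conv`.
    """
    H, W = xp.shape[-2:]
    spatial = [(0, 0), (1, 1)]  # pad rows/cols by one on each side

    pad_spec = [(0, 0)] * (xp.data.ndim - 2) + [(1, 1), (1, 1)]
    if kind == "scalar":
        smap = gc.scalar_expansion_map()
        copies = weight.data[:, :, smap]                # [Co, Ci, 12, 7]
    elif kind == "regular":
        rmap = gc.regular_expansion_map()
        co, ci = weight.shape[:2]
        copies = weight.data.reshape(co, ci, 84)[:, :, rmap]  # [Co,Ci,12,12,7]
    else:  # pragma: no cover
        raise ValueError(kind)

    PD = np.pad(xp.data, pad_spec)

    def view(arr, j):
        dr, dc = gc.STENCIL_CELLS[j]
        return arr[..., 1 + dr:1 + dr + H, 1 + dc:1 + dc + W]

    # contractions use tensordot (BLAS-backed) with channel/orientation axes
    y = None
    for j in range(7):
        if kind == "scalar":
            # [B,Ci,H,W] x [Co,Ci,12] -> [B,H,W,Co,12]
            term = np.tensordot(view(PD, j), copies[..., j], axes=([1], [1]))
        else:
            # [B,Ci,12,H,W] x [Co,Ci,12,12] -> [B,H,W,Co,12]
            term = np.tensordot(view(PD, j), copies[..., j],
                                axes=([1, 2], [1, 3]))
        y = term if y is None else y + term
    y = np.ascontiguousarray(np.moveaxis(y, (3, 4), (1, 2)))  # [B,Co,12,H,W]

    def back(g):
        if xp.requires_grad:
            gp = np.zeros_like(PD)
            for j in range(7):
                if kind == "scalar":
                    gx = np.tensordot(g, copies[..., j], axes=([1, 2], [0, 2]))
                    view(gp, j)[...] += np.moveaxis(gx, 3, 1)
                else:
                    gx = np.tensordot(g, copies[..., j], axes=([1, 2], [0, 2]))
                    view(gp, j)[...] += np.moveaxis(gx, (3, 4), (1, 2))
            xp._accumulate(gp[..., 1:1 + H, 1:1 + W])
        if weight.requires_grad:
            if kind == "scalar":
                # g [B,Co,12,H,W] x view [B,Ci,H,W] -> [Co,12,Ci]
                gcop = np.stack(
                    [np.tensordot(g, view(PD, j), axes=([0, 3, 4], [0, 2, 3]))
                     for j in range(7)], axis=-1)
                gcop = np.moveaxis(gcop, 2, 1)          # [Co,Ci,12,7]
                gw = np.zeros(weight.shape, dtype=np.float64)
                np.add.at(gw, (..., smap), gcop)
            else:
                # g [B,Co,12,H,W] x view [B,Ci,12,H,W] -> [Co,12,Ci,12]
                gcop = np.stack(
                    [np.tensordot(g, view(PD, j), axes=([0, 3, 4], [0, 3, 4]))
                     for j in range(7)], axis=-1)
                gcop = np.moveaxis(gcop, 2, 1)          # [Co,Ci,12,12,7]
                gw = np.zeros((co, ci, 84), dtype=np.float64)
                np.add.at(gw, (..., rmap), gcop)
                gw = gw.reshape(weight.shape)
            weight._accumulate(gw.astype(weight.data.dtype))

    return Tensor(y, _backward=back, _parents=(xp, weight))


class Conv3d:
    """3x3x3 convolution with zero 'same' padding and optional ReLU.

    ``passthrough`` optionally maps each output channel to an input channel
    through the kernel centre on top of a down-scaled random init — an
    identity-style initialization that lets residual trunks propagate their
    inputs from the first step.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 activation: str = "relu", zero_init: bool = False,
                 passthrough: np.ndarray | None = None):
        scale = 0.0 if zero_init else np.sqrt(2.0 / (c_in * 27))
        if passthrough is not None:
            scale *= 0.1
        w = scale * rng.standard_normal((c_out, c_in, 27))
        if passthrough is not None:
            w[np.arange(c_out), np.asarray(passthrough, dtype=np.intp), 13] += 1.0
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out))
        self.activation = activation

    def params(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        cols = _im2col3d(x)                              # [B, C, 27, D, H, W]
        y = einsum2("bcndhw,ocn->bodhw", cols, self.weight)
        y = y + self.bias.reshape(1, -1, 1, 1, 1)
        return relu(y) if self.activation == "relu" else y


class GaugeLift:
    """Trainable lifting convolution (scalar -> 12-slot regular field)."""

    def __init__(self, atlas: AtlasGrid, c_in: int, c_out: int,
                 rng: np.random.Generator, activation: str = "relu",
                 zero_init: bool = False):
        self.atlas = atlas
        scale = 0.0 if zero_init else np.sqrt(2.0 / (c_in * 7))
        self.weight = Parameter(scale * rng.standard_normal((c_out, c_in, 7)))
        self.bias = Parameter(np.zeros(c_out))
        self.activation = activation

    def params(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        """``x [B, C_in, H, W]`` (unpadded) -> ``[B, C_out, 12, H, W]``."""
        xp = pad_scalar_op(self.atlas, x)
        y = _hex_conv(xp, self.weight, "scalar")
        y = y + self.bias.reshape(1, -1, 1, 1, 1)
        return relu(y) if self.activation == "relu" else y


class GaugeRegular:
    """Trainable regular (group) convolution on 12-slot fields."""

    def __init__(self, atlas: AtlasGrid, c_in: int, c_out: int,
                 rng: np.random.Generator, activation: str = "relu",
                 zero_init: bool = False):
        self.atlas = atlas
        scale = 0.0 if zero_init else np.sqrt(2.0 / (c_in * 12 * 7))
        self.weight = Parameter(
            scale * rng.standard_normal((c_out, c_in, 12, 7)))
        self.bias = Parameter(np.zeros(c_out))
        self.activation = activation

    def params(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        """``x [B, C_in, 12, H, W]`` (unpadded) -> ``[B, C_out, 12, H, W]``."""
        xp = pad_regular_op(self.atlas, x)
        y = _hex_conv(xp, self.weight, "regular")
        y = y + self.bias.reshape(1, -1, 1, 1, 1)
        return relu(y) if self.activation == "relu" else y


class GroupBatchNorm:
    """Per-channel batch norm over (batch, orientation, space)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        axes = (0, 2, 3, 4)
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            inv = (var + self.eps).pow_const(-0.5)
            y = xc * inv
        else:
            shape = (1, -1, 1, 1, 1)
            y = (x - self.running_mean.reshape(shape)) \
                * (self.running_var.reshape(shape) + self.eps) ** -0.5
        shape = (1, -1, 1, 1, 1)
        return y * self.gamma.reshape(shape) + self.beta.reshape(shape)


def orientation_pool_op(x: Tensor, mode: str = "mean") -> Tensor:
    """Collapse the orientation axis of ``[B, C, 12, H, W]``."""
    if mode != "mean":
        raise ValueError("only mean pooling is differentiable here")
    return x.mean(axis=2)


def mse_loss(pred: Tensor, target: np.ndarray,
             weight: np.ndarray | None = None) -> Tensor:
    """Mean squared error, optionally restricted by a 0/1 weight array."""
    diff = pred - tensor(target)
    if weight is None:
        return (diff * diff).mean()
    w = np.asarray(weight, dtype=float)
    return (diff * diff * w).sum() * (1.0 / w.sum())


# ---------------------------------------------------------------------------
# optimization

class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
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
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer learning rate when the monitored
    loss stops improving for ``patience`` consecutive checks."""

    def __init__(self, optimizer: Adam, factor: float = 0.5,
                 patience: int = 2, min_lr: float = 1e-8,
                 threshold: float = 1e-4):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = np.inf
        self.bad = 0

    def step(self, loss: float) -> bool:
        """Returns True if the learning rate was reduced."""
        if loss < self.best * (1 - self.threshold):
            self.best = loss
            self.bad = 0
            return False
        self.bad += 1
        if self.bad > self.patience:
            self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
            self.bad = 0
            return True
        return False
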