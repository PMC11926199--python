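"""Gauge-equivariant convolution layers with hexagonal filters.

A hexagonal filter has 7 free weights (centre + 6 ring).  The lifting layer
convolves a scalar field with all 12 rotated/reflected copies of the filter,
producing a feature map with a 12-slot orientation axis; deeper ("regular")
layers use filters with 7 x 12 free weights whose expanded form has a 12 x 12
block structure: the spatial stencil is transformed by the acting element
while the orientation argument is translated, rotations permuting within the
rotation/reflection blocks and reflections swapping the blocks.

With ``act_g`` the action of ``g`` on ring directions and ``s(m)`` the stencil
slot of ring direction ``m``, the layers computed here are

    lift:     y(x, g)   = sum_c sum_v I_c(x + g.v) P_c(v)
    regular:  y(x, g)   = sum_c sum_h sum_v z_c(x + g.v, h) P_c(v, g^{-1} h)

summed over the 7-point stencil v; these are the discrete group correlations
of the feature map with the filter and satisfy the equivariant-kernel
constraint  K(g^{-1} v) = rho(g^{-1}) K(v) rho(g)  for the regular
representation rho, which makes every layer commute with gauge
transformations of the input.

Both layers require padded inputs (see :mod:`rp2gauge.padding`); outputs are
valid on the owner pixels and must be re-padded before the next layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import d6
from .atlas import RING_STEPS
from .padding import RegularFeatureMap, ScalarFeatureMap

__all__ = [
    "HexKernelScalar",
    "HexKernelRegular",
    "ExpandedKernel",
    "embed_hex",
    "extract_hex",
    "scalar_expansion_map",
    "regular_expansion_map",
    "expand_scalar_kernel",
    "expand_regular_kernel",
    "hex_patches",
    "lift_conv",
    "regular_conv",
    "GroupBatchNorm",
    "orientation_pool",
]

# 3x3 cell of each stencil slot [centre, d_0..d_5]; the two remaining corners
# of the square kernel, (-1,-1) and (+1,+1) in (drow, dcol), are masked.
STENCIL_CELLS: tuple[tuple[int, int], ...] = ((0, 0),) + RING_STEPS
MASKED_CELLS: tuple[tuple[int, int], ...] = ((-1, -1), (1, 1))


@dataclass
class HexKernelScalar:
    """Lifting-layer kernel: ``weights [C_out, C_in, 7]``, bias per channel."""

    weights: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.weights.shape[-1] != 7:
            raise ValueError("hexagonal kernels have 7 weights")
        if self.bias is None:
            self.bias = np.zeros(self.weights.shape[0], dtype=self.weights.dtype)


@dataclass
class HexKernelRegular:
    """Regular-layer kernel: ``weights [C_out, C_in, 12, 7]``, bias per channel."""

    weights: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.weights.shape[-2:] != (12, 7):
            raise ValueError("regular hexagonal kernels have 12 x 7 weights")
        if self.bias is None:
            self.bias = np.zeros(self.weights.shape[0], dtype=self.weights.dtype)


@dataclass
class ExpandedKernel:
    """All rotated/reflected kernel copies, as masked 3x3 spatial kernels.

    ``blocks`` has shape ``[12*C_out, C_in, 3, 3]`` (scalar case) or
    ``[12*C_out, 12*C_in, 3, 3]`` (regular case, input slots stacked into the
    channel axis).  The expansion is linear in the free weights and the two
    masked corners are exactly zero.
    """

    blocks: np.ndarray


def embed_hex(weights7: np.ndarray) -> np.ndarray:
    """Place 7 canonical hex weights ``[..., 7]`` into a masked 3x3 kernel."""
    if weights7.shape[-1] != 7:
        raise ValueError("expected 7 weights in canonical order")
    out = np.zeros(weights7.shape[:-1] + (3, 3), dtype=weights7.dtype)
    for j, (dr, dc) in enumerate(STENCIL_CELLS):
        out[..., 1 + dr, 1 + dc] = weights7[..., j]
    return out


def extract_hex(kernel33: np.ndarray) -> np.ndarray:
    """Inverse of :func:`embed_hex` on its support."""
    out = np.empty(kernel33.shape[:-2] + (7,), dtype=kernel33.dtype)
    for j, (dr, dc) in enumerate(STENCIL_CELLS):
        out[..., j] = kernel33[..., 1 + dr, 1 + dc]
    return out


def scalar_expansion_map() -> np.ndarray:
    """Index table ``m[12, 7]``: copy ``g`` of a 7-weight kernel is
    ``w[m[g]]`` in stencil-slot order (stencil slot of ``g . d_m`` holds ring
    weight ``m``)."""
    table = np.zeros((12, 7), dtype=np.intp)
    for s, g in enumerate(d6.ALL_ELEMENTS):
        for m in range(6):
            table[s, 1 + d6.act_on_direction(g, m)] = 1 + m
    return table


def regular_expansion_map() -> np.ndarray:
    """Index table ``m[12, 12, 7]`` into the flattened ``12*7`` free weights:
    block ``(g, h)`` of the expanded kernel takes its stencil slot
    ``s(g . d_m)`` from free weight ``(g^{-1} h, m)``."""
    table = np.zeros((12, 12, 7), dtype=np.intp)
    for sg, g in enumerate(d6.ALL_ELEMENTS):
        ginv = d6.inverse(g)
        for sh, h in enumerate(d6.ALL_ELEMENTS):
            src_slot = d6.slot_index(d6.compose(ginv, h))
            table[sg, sh, 0] = src_slot * 7
            for m in range(6):
                table[sg, sh, 1 + d6.act_on_direction(g, m)] = src_slot * 7 + 1 + m
    return table


_SCALAR_MAP = scalar_expansion_map()
_REGULAR_MAP = regular_expansion_map()


def expand_scalar_kernel(k: HexKernelScalar) -> ExpandedKernel:
    """12 rotated/reflected copies of each scalar kernel, stacked as
    ``[12*C_out, C_in, 3, 3]`` with copy order equal to the slot order."""
    w = k.weights  # [Co, Ci, 7]
    copies = w[:, :, _SCALAR_MAP]            # [Co, Ci, 12, 7]
    blocks = embed_hex(np.transpose(copies, (0, 2, 1, 3)))  # [Co, 12, Ci, 3, 3]
    co, _, ci = blocks.shape[:3]
    return ExpandedKernel(blocks.reshape(co * 12, ci, 3, 3))


def expand_regular_kernel(k: HexKernelRegular) -> ExpandedKernel:
    """12 x 12 block expansion of a regular kernel as
    ``[12*C_out, 12*C_in, 3, 3]``."""
    co, ci = k.weights.shape[:2]
    flat = k.weights.reshape(co, ci, 12 * 7)
    copies = flat[:, :, _REGULAR_MAP]        # [Co, Ci, 12, 12, 7]
    blocks = embed_hex(np.transpose(copies, (0, 2, 1, 3, 4)))  # [Co,12,Ci,12,3,3]
    return ExpandedKernel(blocks.reshape(co * 12, ci * 12, 3, 3))


def hex_patches(values: np.ndarray) -> np.ndarray:
    """Stack the 7 stencil samples of ``values[..., H, W]`` as
    ``[..., 7, H, W]`` (out-of-array samples are zero; real borders are
    handled by the atlas padding, which owns every valid output pixel)."""
    H, W = values.shape[-2:]
    padded = np.pad(values, [(0, 0)] * (values.ndim - 2) + [(1, 1), (1, 1)])
    out = np.empty(values.shape[:-2] + (7, H, W), dtype=values.dtype)
    for j, (dr, dc) in enumerate(STENCIL_CELLS):
        out[..., j, :, :] = padded[..., 1 + dr:1 + dr + H, 1 + dc:1 + dc + W]
    return out


def _apply_nonlinearity(y: np.ndarray, nonlinearity: str) -> np.ndarray:
    if nonlinearity == "relu":
        return np.maximum(y, 0.0)
    if nonlinearity == "identity":
        return y
    raise ValueError(f"unknown nonlinearity {nonlinearity!r}")


def lift_conv(m: ScalarFeatureMap, k: HexKernelScalar,
              nonlinearity: str = "relu") -> RegularFeatureMap:
    """Lifting convolution: scalar field -> 12-slot orientation field.

    Applies all 12 transformed kernel copies, adds the per-channel bias
    (shared across orientation slots) and the pointwise nonlinearity.
    """
    if not m.padded:
        raise ValueError("lift_conv requires a padded input map")
    w = k.weights
    copies = w[:, :, _SCALAR_MAP]                       # [Co, Ci, 12, 7]
    patches = hex_patches(m.values)                    # [B, Ci, 7, H, W]
    y = np.einsum("bcjhw,ocgj->boghw", patches, copies, optimize=True)
    y = y + k.bias[None, :, None, None, None]
    return RegularFeatureMap(_apply_nonlinearity(y, nonlinearity), m.atlas)


def regular_conv(m: RegularFeatureMap, k: HexKernelRegular,
                 nonlinearity: str = "relu") -> RegularFeatureMap:
    """Group convolution of a 12-slot field with a regular hexagonal kernel."""
    if not m.padded:
        raise ValueError("regular_conv requires a padded input map")
    co, ci = k.weights.shape[:2]
    flat = k.weights.reshape(co, ci, 12 * 7)
    copies = flat[:, :, _REGULAR_MAP]                  # [Co, Ci, 12, 12, 7]
    patches = hex_patches(m.values)                    # [B, Ci, 12, 7, H, W]
    y = np.einsum("bchjyx,ocghj->bogyx", patches, copies, optimize=True)
    y = y + k.bias[None, :, None, None, None]
    return RegularFeatureMap(_apply_nonlinearity(y, nonlinearity), m.atlas)


@dataclass
class GroupBatchNorm:
    """Batch normalization treating the orientation axis as a spatial axis.

    Statistics are per channel over (batch, orientation, height, width), which
    keeps the layer exactly equivariant under orientation permutations; the
    affine parameters are per channel.
    """

    num_channels: int
    eps: float = 1e-5
    momentum: float = 0.1
    gamma: np.ndarray = field(default=None)
    beta: np.ndarray = field(default=None)
    running_mean: np.ndarray = field(default=None)
    running_var: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        c = self.num_channels
        if self.gamma is None:
            self.gamma = np.ones(c)
        if self.beta is None:
            self.beta = np.zeros(c)
        if self.running_mean is None:
            self.running_mean = np.zeros(c)
        if self.running_var is None:
            self.running_var = np.ones(c)

    def __call__(self, m: RegularFeatureMap, train: bool = True) -> RegularFeatureMap:
        axes = (0, 2, 3, 4)
        if train:
            mean = m.values.mean(axis=axes)
            var = m.values.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        y = (m.values - mean.reshape(shape)) / np.sqrt(var.reshape(shape) + self.eps)
        y = y * self.gamma.reshape(shape) + self.beta.reshape(shape)
        return RegularFeatureMap(y, m.atlas, padded=False)


def orientation_pool(m: RegularFeatureMap, mode: str = "mean") -> ScalarFeatureMap:
    """Collapse the orientation axis into a gauge-invariant scalar field."""
    if mode == "mean":
        v = m.values.mean(axis=-3)
    elif mode == "max":
        v = m.values.max(axis=-3)
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    return ScalarFeatureMap(v, m.atlas, padded=False)
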