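"""Feature maps on the flattened atlas and their gauge-aware padding.

Feature values live on the stacked padded rectangle of the five charts
(``6 x 30`` at refinement 2).  Padding copies every duplicated or strip pixel
from the single "owner" position of its grid point — the position where the
hexagonal convolution produces a valid output — applying the D6 gauge
transition to the orientation axis of regular feature maps.  The copy tables
are precomputed by :func:`rp2gauge.atlas.build_atlas`, so padding is a single
gather and is exactly idempotent.

Cone-point pixels (the 11 masked corners) carry no value and are forced to
zero; zero is gauge-invariant, so this keeps every layer equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import AtlasGrid

__all__ = [
    "ScalarFeatureMap",
    "RegularFeatureMap",
    "pad_scalar",
    "pad_regular",
    "pad_scalar_values",
    "pad_regular_values",
    "scalar_from_vertex_values",
    "vertex_values_from_map",
]


@dataclass
class ScalarFeatureMap:
    """Scalar field on the flat layout: values ``[batch, channels, H, W]``."""

    values: np.ndarray
    atlas: AtlasGrid
    padded: bool = False

    def __post_init__(self) -> None:
        if self.values.shape[-2:] != self.atlas.flat_layout:
            raise ValueError(
                f"values shape {self.values.shape} does not match flat layout "
                f"{self.atlas.flat_layout}")


@dataclass
class RegularFeatureMap:
    """Field with a 12-slot orientation axis: ``[batch, channels, 12, H, W]``.

    Slot ordering follows :mod:`rp2gauge.d6`: rotations ``R^0..R^5`` then
    reflections ``S_t0..S_t5``; the axis transforms by the regular
    representation of D6 under gauge transformations.
    """

    values: np.ndarray
    atlas: AtlasGrid
    padded: bool = False

    def __post_init__(self) -> None:
        if self.values.shape[-3] != 12 or self.values.shape[-2:] != self.atlas.flat_layout:
            raise ValueError(
                f"values shape {self.values.shape} incompatible with a regular "
                f"map on flat layout {self.atlas.flat_layout}")


def pad_scalar_values(atlas: AtlasGrid, values: np.ndarray) -> np.ndarray:
    """Array-level scalar padding: ``values[..., H, W] -> padded copy``."""
    H, W = atlas.flat_layout
    out = values.reshape(*values.shape[:-2], H * W).copy()
    out[..., atlas.zero_mask] = 0.0
    out[..., atlas.pad_dst] = out[..., atlas.pad_src]
    return out.reshape(values.shape)


def pad_regular_values(atlas: AtlasGrid, values: np.ndarray) -> np.ndarray:
    """Array-level regular padding: ``values[..., 12, H, W] -> padded copy``.

    Each copied pixel takes orientation slot ``h`` from slot ``g . h`` of its
    owner, where ``g`` is the gauge transition of that pixel pair.
    """
    H, W = atlas.flat_layout
    out = values.reshape(*values.shape[:-3], 12, H * W).copy()
    out[..., atlas.zero_mask] = 0.0
    # gathered[..., j, t] = out[..., perm[t, j], src[t]]
    gathered = out[..., atlas.pad_perm.T, atlas.pad_src[None, :]]
    out[..., atlas.pad_dst] = gathered
    return out.reshape(values.shape)


def pad_scalar(m: ScalarFeatureMap) -> ScalarFeatureMap:
    """Fill strips and duplicated pixels of a scalar map from their owners."""
    return ScalarFeatureMap(pad_scalar_values(m.atlas, m.values), m.atlas, padded=True)


def pad_regular(m: RegularFeatureMap) -> RegularFeatureMap:
    """Gauge-aware padding of a map with a 12-slot orientation axis."""
    return RegularFeatureMap(pad_regular_values(m.atlas, m.values), m.atlas, padded=True)


def scalar_from_vertex_values(atlas: AtlasGrid, vertex_values: np.ndarray) -> ScalarFeatureMap:
    """Broadcast per-vertex values ``[..., n_signal_vertices]`` onto the flat
    layout (every position of a vertex gets its value; cones stay zero)."""
    sig = atlas.signal_vertex_ids
    if vertex_values.shape[-1] != len(sig):
        raise ValueError(
            f"expected {len(sig)} vertex values, got {vertex_values.shape[-1]}")
    full = np.zeros(vertex_values.shape[:-1] + (atlas.n_vertices,),
                    dtype=vertex_values.dtype)
    full[..., sig] = vertex_values
    H, W = atlas.flat_layout
    flat = np.zeros(vertex_values.shape[:-1] + (H * W,), dtype=vertex_values.dtype)
    live = ~atlas.zero_mask
    flat[..., live] = full[..., atlas.position_vertex[live]]
    shape = vertex_values.shape[:-1] + (H, W)
    return ScalarFeatureMap(flat.reshape(shape), atlas, padded=True)


def vertex_values_from_map(m: ScalarFeatureMap) -> np.ndarray:
    """Read one value per signal vertex from its owner position."""
    atlas = m.atlas
    H, W = atlas.flat_layout
    flat = m.values.reshape(*m.values.shape[:-2], H * W)
    return flat[..., atlas.vertex_owner_flat[atlas.signal_vertex_ids]]
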