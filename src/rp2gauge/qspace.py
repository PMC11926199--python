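"""Projection of q-space measurements onto the icosahedral grid.

Single-shell diffusion measurements are samples of an antipodally symmetric
function of the gradient direction.  This module interpolates per-direction
values onto the vertices of the half-icosahedron grid with inverse distance
weighting (IDW) on the folded angular distance ``arccos |v . g|``, which makes
the result invariant under flipping the sign of any gradient direction —
equivalent to averaging antipodal samples before interpolation.

The IDW uses power 2 over all input directions (no nearest-neighbour cutoff):
with as few as six directions a cutoff would introduce discontinuities as
directions move across Voronoi boundaries.  An epsilon guard returns the exact
sample value when a vertex coincides with an input direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import AtlasGrid
from .padding import ScalarFeatureMap, scalar_from_vertex_values

__all__ = [
    "GradientScheme",
    "folded_angle",
    "interpolation_weights",
    "project_to_grid",
    "sample_at_vertices",
]

_UNIT_TOL = 1e-6
_EXACT_EPS = 1e-9


@dataclass
class GradientScheme:
    """Unit gradient directions and their b-values (s/mm^2)."""

    directions: np.ndarray   # (n, 3)
    bvalues: np.ndarray      # (n,)

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.bvalues = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        if self.directions.shape[0] != self.bvalues.shape[0]:
            raise ValueError("directions and bvalues must have matching length")
        if self.directions.shape[0] == 0:
            raise ValueError("empty gradient scheme")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("gradient directions must be unit vectors")

    def __len__(self) -> int:
        return len(self.bvalues)

    def subset(self, n: int) -> "GradientScheme":
        return GradientScheme(self.directions[:n], self.bvalues[:n])

    # -- FSL-dialect gradient tables ------------------------------------
    @classmethod
    def from_fsl(cls, bvec_path, bval_path) -> "GradientScheme":
        """Read 3xN bvec and 1xN bval whitespace text files; directions are
        normalized on load."""
        bvec = np.loadtxt(bvec_path)
        bval = np.loadtxt(bval_path)
        if bvec.shape[0] != 3:
            bvec = bvec.T
        dirs = bvec.T
        norms = np.linalg.norm(dirs, axis=1)
        norms[norms == 0] = 1.0
        return cls(dirs / norms[:, None], np.atleast_1d(bval))

    def to_fsl(self, bvec_path, bval_path) -> None:
        np.savetxt(bvec_path, self.directions.T, fmt="%.10f")
        np.savetxt(bval_path, self.bvalues[None, :], fmt="%.2f")


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(np.abs(np.linalg.norm(v, axis=-1) - 1.0) > _UNIT_TOL):
        raise ValueError(f"{name} must be unit-norm")
    return v


def folded_angle(v: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Angular distance on the projective sphere: ``arccos |v . g|`` in
    ``[0, pi/2]``; antipodal directions are at distance zero."""
    v = _check_unit(v, "v")
    g = _check_unit(g, "g")
    dot = np.abs(np.sum(v * g, axis=-1))
    return np.arccos(np.clip(dot, -1.0, 1.0))


def interpolation_weights(atlas: AtlasGrid, scheme: GradientScheme,
                          power: float = 2.0) -> np.ndarray:
    """IDW weight matrix ``[n_signal_vertices, n_directions]``.

    Rows are nonnegative and sum to one; a row collapses to an indicator when
    the vertex coincides (within fold) with an input direction.
    """
    verts = atlas.vertices[atlas.signal_vertex_ids]
    ang = np.arccos(np.clip(np.abs(verts @ scheme.directions.T), -1.0, 1.0))
    w = np.zeros_like(ang)
    exact = ang.min(axis=1) < _EXACT_EPS
    if exact.any():
        hit = ang[exact].argmin(axis=1)
        w[np.nonzero(exact)[0], hit] = 1.0
    rest = ~exact
    w[rest] = ang[rest] ** (-power)
    w[rest] /= w[rest].sum(axis=1, keepdims=True)
    return w


def project_to_grid(values: np.ndarray, scheme: GradientScheme,
                    atlas: AtlasGrid, power: float = 2.0) -> ScalarFeatureMap:
    """Interpolate per-direction values ``[..., n_directions]`` onto the grid
    and flatten to the atlas layout (returned map is padded)."""
    if values.shape[-1] != len(scheme):
        raise ValueError("values last axis must match the number of directions")
    w = interpolation_weights(atlas, scheme, power=power)
    vert = values @ w.T
    return scalar_from_vertex_values(atlas, vert)


def sample_at_vertices(signal, atlas: AtlasGrid) -> ScalarFeatureMap:
    """Evaluate a direction-wise signal closure exactly at the grid vertices.

    ``signal`` maps an array of unit directions ``(m, 3)`` to values
    ``(..., m)``; used to build training labels from a fitted tensor model.
    """
    verts = atlas.vertices[atlas.signal_vertex_ids]
    vals = np.asarray(signal(verts))
    return scalar_from_vertex_values(atlas, vals)
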