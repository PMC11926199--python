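"""Exact algebra of the dihedral group D6 acting on the hexagonal grid.

D6 is the structure group ("gauge group") of the hexagonal grids used
throughout this package: the 6 rotations by multiples of 60 degrees and the
6 reflections of a hexagon.  Every element has a canonical form ``R^rot S^ref``
where ``R`` is the counter-clockwise rotation by 60 degrees and ``S`` the
reflection across the 0-degree axis; the element acts on a vector by applying
``S`` first (if ``ref``) and then ``R`` ``rot`` times.

Reflections are written ``S_{theta_i} = R^i S``; note ``S_{theta_i}`` reflects
across the axis at angle ``theta_i / 2``, not ``theta_i``.

Hexagonal lattice displacements use axial coordinates ``(q, r)`` in the basis
``e1 = d_0`` (unit vector at 0 degrees) and ``e2 = d_2`` (unit vector at
120 degrees).  The six unit ring directions are ``d_m`` at angle ``60 m``
degrees; in axial coordinates::

    d_0=(1,0)  d_1=(1,1)  d_2=(0,1)  d_3=(-1,0)  d_4=(-1,-1)  d_5=(0,-1)

Feature maps with an orientation axis use 12 slots ordered
``[R^0..R^5, R^0 S..R^5 S]`` (rotations first, then reflections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroupElement",
    "IDENTITY",
    "ALL_ELEMENTS",
    "RING_AXIAL",
    "compose",
    "inverse",
    "act_on_direction",
    "act_on_offset",
    "slot_index",
    "element_from_slot",
    "orientation_permutation",
    "matrix_of",
    "axial_to_xy",
]


@dataclass(frozen=True, order=True)
class GroupElement:
    """Element ``R^rot S^ref`` of D6.

    rot is the power of the 60-degree rotation (0..5), ref flags whether the
    reflection across the 0-degree axis is applied (before the rotation).
    """

    rot: int
    ref: int

    def __post_init__(self) -> None:
        if not (0 <= self.rot <= 5 and self.ref in (0, 1)):
            raise ValueError(f"invalid D6 element ({self.rot}, {self.ref})")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.ref:
            return f"S_t{self.rot}" if self.rot else "S"
        return f"R{self.rot}" if self.rot else "E"


IDENTITY = GroupElement(0, 0)

#: The 12 elements in orientation-slot order: rotations R^0..R^5, then
#: reflections S_{theta_0}..S_{theta_5}.
ALL_ELEMENTS: tuple[GroupElement, ...] = tuple(
    GroupElement(i, s) for s in (0, 1) for i in range(6)
)

#: Axial coordinates of the six ring directions d_0..d_5.
RING_AXIAL: tuple[tuple[int, int], ...] = (
    (1, 0), (1, 1), (0, 1), (-1, 0), (-1, -1), (0, -1),
)


def compose(a: GroupElement, b: GroupElement) -> GroupElement:
    """Return the canonical form of ``a * b`` (apply ``b`` first)."""
    if a.ref == 0:
        return GroupElement((a.rot + b.rot) % 6, b.ref)
    # S R^b = R^{-b} S, hence R^a S R^b S^t = R^{a-b} S^{1+t}
    return GroupElement((a.rot - b.rot) % 6, 1 - b.ref)


def inverse(a: GroupElement) -> GroupElement:
    """Group inverse; every reflection is its own inverse."""
    if a.ref:
        return a
    return GroupElement((-a.rot) % 6, 0)


def act_on_direction(g: GroupElement, m: int) -> int:
    """Index of ``g . d_m`` among the ring directions."""
    m = m % 6
    return (g.rot - m) % 6 if g.ref else (g.rot + m) % 6


def act_on_offset(g: GroupElement, offset: tuple[int, int]) -> tuple[int, int]:
    """Action of ``g`` on an axial displacement ``(q, r)``.

    R(q, r) = (q - r, q) and S(q, r) = (q - r, -r); these are the unique
    integer maps agreeing with the 2x2 orthogonal representation in the
    120-degree axial basis.
    """
    q, r = offset
    if g.ref:
        q, r = q - r, -r
    for _ in range(g.rot):
        q, r = q - r, q
    return (q, r)


def slot_index(g: GroupElement) -> int:
    """Orientation slot (0..11) of ``g``: rotations 0-5, reflections 6-11."""
    return g.rot + 6 * g.ref


def element_from_slot(slot: int) -> GroupElement:
    return ALL_ELEMENTS[slot]


def orientation_permutation(g: GroupElement) -> np.ndarray:
    """Left-translation permutation of the 12 orientation slots.

    Returns the integer array ``p`` with ``p[slot(h)] = slot(g * h)``.  The map
    ``g -> p`` is a group homomorphism into S12 under the composition
    ``p_{gh} = p_g[p_h]``; it is the permutation underlying the regular
    representation of D6 on the orientation axis of feature maps.
    """
    return np.array([slot_index(compose(g, h)) for h in ALL_ELEMENTS], dtype=np.intp)


_SQ3 = np.sqrt(3.0)


def matrix_of(g: GroupElement) -> np.ndarray:
    """2x2 orthogonal matrix of ``g`` in Cartesian coordinates."""
    c, s = np.cos(np.pi / 3 * g.rot), np.sin(np.pi / 3 * g.rot)
    rot = np.array([[c, -s], [s, c]])
    if g.ref:
        rot = rot @ np.diag([1.0, -1.0])
    return rot


def axial_to_xy(offset: tuple[int, int]) -> np.ndarray:
    """Cartesian coordinates of the axial displacement ``q e1 + r e2``."""
    q, r = offset
    return np.array([q - 0.5 * r, 0.5 * _SQ3 * r])
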