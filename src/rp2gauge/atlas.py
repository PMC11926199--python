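"""Five-chart atlas of the hexagonal grid on the half icosahedron.

The angular domain of single-shell diffusion MRI is the real projective plane
(antipodal directions are equivalent).  It is modelled here as the top half of
an icosahedron: ten triangular faces whose boundary seam is glued to itself by
the antipodal map.  A hexagonal grid is obtained by subdividing each face
``r`` times ("refinement") and projecting to the unit sphere.

The grid is covered by five square charts.  Chart ``k`` is the rhombus with
corners ``pole -> u_k`` (rows) and ``pole -> u_{k+1}`` (columns), where ``u_k``
are the five upper-ring icosahedron vertices and ``l_k`` the lower-ring ones;
the rhombus consists of one pole face and one middle-band face and carries a
``(2^r+1) x (2^r+1)`` pixel grid.  Charts are stored side by side in a padded
``(2^r+2) x 5(2^r+2)`` rectangle, with a one-pixel strip on the left (filled
from the neighbouring chart) and the bottom (filled through the antipodal
identification).  Where two charts meet, their hexagonal frames differ by an
element of the dihedral group D6 — the gauge transition — which this module
derives combinatorially by matching hex-neighbour vertices, rather than from
hand-written case rules.

The 11 original icosahedron corners are cone points of the grid (five grid
neighbours instead of six); they belong to no chart and are masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import d6
from .d6 import GroupElement, IDENTITY

__all__ = [
    "AtlasGrid",
    "ChartRecord",
    "build_atlas",
    "gauge_transition",
    "antipodal_partner",
    "flatten_index",
    "unflatten_index",
    "save_atlas",
    "load_atlas",
]

#: chart-grid step (drow, dcol) of each hex ring direction d_0..d_5
RING_STEPS: tuple[tuple[int, int], ...] = tuple(
    (-r, q) for (q, r) in d6.RING_AXIAL
)

_ROUND = 9


def _key(v: np.ndarray) -> tuple:
    return tuple(np.round(v, _ROUND) + 0.0)


def _fold_key(v: np.ndarray) -> tuple:
    """Canonical key of the antipodal class {v, -v}."""
    return max(_key(v), _key(-v))


def _representative(v: np.ndarray) -> np.ndarray:
    """Upper-hemisphere representative of the class of ``v``.

    Points with z < 0 are mapped antipodally; on the z = 0 ring the
    representative with first nonzero coordinate > 0 is taken.
    """
    w = np.asarray(v, dtype=float)
    if abs(w[2]) > 1e-12:
        return w if w[2] > 0 else -w
    for c in w:
        if abs(c) > 1e-12:
            return w if c > 0 else -w
    raise ValueError("zero vector")


@dataclass
class ChartRecord:
    """Pixel bookkeeping of one padded chart.

    ``pixel_to_vertex[pr, pc]`` gives the antipodal-class vertex id at padded
    pixel ``(pr, pc)``, or -1 for dead pixels (padded-frame positions with no
    grid point, and the masked cone corners).  Interior pixels are the
    ``(2^r+1)^2`` chart pixels; exterior pixels are the left/bottom strips.
    """

    index: int
    pixel_to_vertex: np.ndarray
    interior_mask: np.ndarray
    exterior_mask: np.ndarray


@dataclass
class AtlasGrid:
    """Refined half-icosahedron grid with charts, transitions and layout."""

    refinement: int
    vertices: np.ndarray            # (n_vertices, 3) class representatives
    cone_ids: np.ndarray            # glued ids of the cone-point classes
    charts: list[ChartRecord]
    n_surface_points: int           # distinct grid points of the unglued surface
    n_uncovered_corners: int        # surface points in no chart (t = 11)
    flat_layout: tuple[int, int]
    # per-position tables over the flat array (row-major H x W)
    position_vertex: np.ndarray     # (H*W,) vertex id or -1
    zero_mask: np.ndarray           # (H*W,) bool: dead + cone positions
    vertex_owner_flat: np.ndarray   # (n_vertices,) flat idx of owner, -1 cones
    # padding gather: dst takes value from src, orientation slot j from perm[j]
    pad_dst: np.ndarray             # (n_pad,) flat indices
    pad_src: np.ndarray             # (n_pad,) flat indices
    pad_perm: np.ndarray            # (n_pad, 12) slot gather indices
    pad_elements: np.ndarray        # (n_pad,) slot index of the D6 transition
    # internal geometry caches
    _grid_vid: np.ndarray = field(repr=False, default=None)       # (5,N+1,N+1)
    _grid_pos: np.ndarray = field(repr=False, default=None)       # (5,N+1,N+1,3)
    _ext_vid: dict = field(repr=False, default_factory=dict)
    _edge_tris: dict = field(repr=False, default_factory=dict)

    # -- convenience -------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def chart_width(self) -> int:
        return 2 ** self.refinement + 2

    @property
    def signal_vertex_ids(self) -> np.ndarray:
        """Ids of the non-cone vertices that carry signal values."""
        mask = np.ones(self.n_vertices, dtype=bool)
        mask[self.cone_ids] = False
        return np.nonzero(mask)[0]


def _icosahedron_corners() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pole = np.array([0.0, 0.0, 1.0])
    zc = 1.0 / np.sqrt(5.0)
    rc = 2.0 / np.sqrt(5.0)
    lon_u = np.deg2rad(72.0 * np.arange(5))
    lon_l = np.deg2rad(72.0 * np.arange(5) + 36.0)
    u = np.stack([rc * np.cos(lon_u), rc * np.sin(lon_u), np.full(5, zc)], axis=1)
    l = np.stack([rc * np.cos(lon_l), rc * np.sin(lon_l), np.full(5, -zc)], axis=1)
    return pole, u, l


def _chart_positions(refinement: int) -> np.ndarray:
    """Unglued 3D grid positions pos[k, a, b] of the five chart rhombi."""
    n = 2 ** refinement
    pole, u, l = _icosahedron_corners()
    pos = np.zeros((5, n + 1, n + 1, 3))
    for k in range(5):
        ck = [pole, u[k], u[(k + 1) % 5], l[k]]
        for a in range(n + 1):
            for b in range(n + 1):
                if a + b <= n:
                    p = ((n - a - b) * ck[0] + a * ck[1] + b * ck[2]) / n
                else:
                    p = ((n - b) * ck[1] + (n - a) * ck[2] + (a + b - n) * ck[3]) / n
                pos[k, a, b] = p / np.linalg.norm(p)
    return pos


def build_atlas(refinement: int = 2) -> AtlasGrid:
    """Construct the five-chart atlas at the given refinement level.

    ``refinement`` is the number of grid-subdivision steps; the default 2
    yields 5x5 charts padded to 6x6 and stacked to a 6x30 flat layout, with
    5*4^2 + 1 = 81 distinct grid points.
    """
    if refinement < 1:
        raise ValueError("refinement must be >= 1")
    n = 2 ** refinement
    pos = _chart_positions(refinement)

    # --- glued (antipodal-class) vertex registry -------------------------
    class_of: dict[tuple, int] = {}
    reps: list[np.ndarray] = []
    grid_vid = np.zeros((5, n + 1, n + 1), dtype=np.intp)
    for k in range(5):
        for a in range(n + 1):
            for b in range(n + 1):
                key = _fold_key(pos[k, a, b])
                if key not in class_of:
                    class_of[key] = len(reps)
                    reps.append(_representative(pos[k, a, b]))
                grid_vid[k, a, b] = class_of[key]
    vertices = np.array(reps)

    # cone points: the 11 original icosahedron corners (6 glued classes)
    pole, u, l = _icosahedron_corners()
    cone_ids = np.array(sorted({class_of[_fold_key(v)]
                                for v in [pole, *u, *l]}), dtype=np.intp)
    cone_set = set(cone_ids.tolist())

    # --- unglued surface registry (for the corner-coverage count) -------
    surf_of: dict[tuple, int] = {}
    covered: set[int] = set()
    for k in range(5):
        for a in range(n + 1):
            for b in range(n + 1):
                key = _key(pos[k, a, b])
                if key not in surf_of:
                    surf_of[key] = len(surf_of)
                corner = (a in (0, n)) and (b in (0, n))
                if not corner:
                    covered.add(surf_of[key])
    n_surface = len(surf_of)
    n_uncovered = n_surface - len(covered)

    # --- glued triangulation (for across-edge resolution) ---------------
    edge_tris: dict[frozenset, set[tuple]] = {}
    for k in range(5):
        for a in range(n):
            for b in range(n):
                sq = (grid_vid[k, a, b], grid_vid[k, a + 1, b],
                      grid_vid[k, a, b + 1], grid_vid[k, a + 1, b + 1])
                for tri in ((sq[0], sq[1], sq[2]), (sq[1], sq[2], sq[3])):
                    t = tuple(sorted(tri))
                    for e in ((t[0], t[1]), (t[0], t[2]), (t[1], t[2])):
                        edge_tris.setdefault(frozenset(e), set()).add(t)

    # --- extended pixel resolution (strips) ------------------------------
    def resolve(k: int, a: int, b: int) -> int:
        """Vertex id at chart pixel (a, b), extended one step outside; -1 if
        the pixel corresponds to no grid point."""
        if 0 <= a <= n and 0 <= b <= n:
            return int(grid_vid[k, a, b])
        if (k, a, b) in ext_cache:
            return ext_cache[(k, a, b)]
        # Find two cyclically adjacent ring directions whose endpoints P1, P2
        # are in-chart; {P1, P2} is then a boundary edge of the chart and the
        # outside pixel is the across-edge triangle flip of the inside flank
        # point P1 + P2 - X (the other common hex neighbour of P1 and P2).
        vid = -1
        for m in range(6):
            da1, db1 = RING_STEPS[m]
            da2, db2 = RING_STEPS[(m + 1) % 6]
            a1, b1 = a + da1, b + db1
            a2, b2 = a + da2, b + db2
            ai, bi = a1 + a2 - a, b1 + b2 - b
            if not (0 <= a1 <= n and 0 <= b1 <= n and 0 <= a2 <= n
                    and 0 <= b2 <= n and 0 <= ai <= n and 0 <= bi <= n):
                continue
            v1, v2 = int(grid_vid[k, a1, b1]), int(grid_vid[k, a2, b2])
            v_in = int(grid_vid[k, ai, bi])
            tris = edge_tris.get(frozenset((v1, v2)), set())
            others = [set(t) - {v1, v2} for t in tris if v_in not in t]
            if len(others) == 1 and len(others[0]) == 1:
                vid = int(others[0].pop())
                break
        ext_cache[(k, a, b)] = vid
        return vid

    ext_cache: dict[tuple, int] = {}

    # --- flat layout and per-position tables -----------------------------
    cw = n + 2
    H, W = cw, 5 * cw
    position_vertex = np.full(H * W, -1, dtype=np.intp)
    charts: list[ChartRecord] = []
    for k in range(5):
        p2v = np.full((cw, cw), -1, dtype=np.intp)
        interior = np.zeros((cw, cw), dtype=bool)
        exterior = np.zeros((cw, cw), dtype=bool)
        for pr in range(cw):
            for pc in range(cw):
                a, b = pr, pc - 1
                in_chart = 0 <= a <= n and 0 <= b <= n
                if in_chart:
                    interior[pr, pc] = True
                else:
                    exterior[pr, pc] = True
                vid = resolve(k, a, b)
                if vid >= 0:
                    p2v[pr, pc] = vid
                flat = pr * W + k * cw + pc
                position_vertex[flat] = p2v[pr, pc]
        charts.append(ChartRecord(k, p2v, interior, exterior))

    cone_mask_flat = np.zeros(H * W, dtype=bool)
    for i, vid in enumerate(position_vertex):
        if vid in cone_set:
            cone_mask_flat[i] = True
    zero_mask = (position_vertex < 0) | cone_mask_flat

    # --- owner assignment -------------------------------------------------
    # owner = a position whose convolution output is valid: chart rows 1..n,
    # chart cols 0..n-1 (padded pc 1..n), not a cone pixel
    vertex_owner = np.full((len(vertices), 3), -1, dtype=np.intp)
    for k in range(5):
        for a in range(1, n + 1):
            for b in range(0, n):
                vid = int(grid_vid[k, a, b])
                if vid in cone_set or vertex_owner[vid, 0] >= 0:
                    continue
                vertex_owner[vid] = (k, a, b)
    missing = [v for v in range(len(vertices))
               if vertex_owner[v, 0] < 0 and v not in cone_set]
    if missing:
        raise AssertionError(f"vertices without owner position: {missing}")
    vertex_owner_flat = np.full(len(vertices), -1, dtype=np.intp)
    for vid, (k, a, b) in enumerate(vertex_owner):
        if k >= 0:
            vertex_owner_flat[vid] = a * W + k * cw + (b + 1)

    # --- gauge transitions and the padding gather -------------------------
    def neighbours(k: int, a: int, b: int) -> list[int]:
        out = []
        for da, db in RING_STEPS:
            aa, bb = a + da, b + db
            if -1 <= aa <= n + 1 and -1 <= bb <= n + 1:
                out.append(resolve(k, aa, bb))
            else:
                out.append(-1)
        return out

    def match_element(nb_i: list[int], nb_j: list[int]) -> GroupElement:
        """D6 element g with direction m in frame i = direction g.m in frame j."""
        hits = []
        for g in d6.ALL_ELEMENTS:
            ok = True
            known = 0
            for m in range(6):
                if nb_i[m] < 0:
                    continue
                known += 1
                if nb_j[d6.act_on_direction(g, m)] != nb_i[m]:
                    ok = False
                    break
            if ok and known >= 2:
                hits.append(g)
        if len(hits) != 1:
            raise AssertionError(f"ambiguous gauge transition: {hits}")
        return hits[0]

    pad_dst, pad_src, pad_perm, pad_elem = [], [], [], []
    for k in range(5):
        for pr in range(cw):
            for pc in range(cw):
                flat = pr * W + k * cw + pc
                vid = int(position_vertex[flat])
                if vid < 0 or vid in cone_set:
                    continue
                ko, ao, bo = (int(x) for x in vertex_owner[vid])
                if (ko, ao, bo) == (k, pr, pc - 1):
                    continue
                g = match_element(neighbours(k, pr, pc - 1),
                                  neighbours(ko, ao, bo))
                pad_dst.append(flat)
                pad_src.append(int(vertex_owner_flat[vid]))
                pad_perm.append(d6.orientation_permutation(g))
                pad_elem.append(d6.slot_index(g))

    atlas = AtlasGrid(
        refinement=refinement,
        vertices=vertices,
        cone_ids=cone_ids,
        charts=charts,
        n_surface_points=n_surface,
        n_uncovered_corners=n_uncovered,
        flat_layout=(H, W),
        position_vertex=position_vertex,
        zero_mask=zero_mask,
        vertex_owner_flat=vertex_owner_flat,
        pad_dst=np.array(pad_dst, dtype=np.intp),
        pad_src=np.array(pad_src, dtype=np.intp),
        pad_perm=np.array(pad_perm, dtype=np.intp),
        pad_elements=np.array(pad_elem, dtype=np.intp),
        _grid_vid=grid_vid,
        _grid_pos=pos,
        _ext_vid=ext_cache,
        _edge_tris=edge_tris,
    )
    # structural invariants
    assert len(vertices) == 5 * 4 ** refinement + 1
    assert atlas.n_uncovered_corners == 11
    return atlas


# ---------------------------------------------------------------------------
# queries

def _positions_of(atlas: AtlasGrid, vid: int, chart: int) -> list[tuple[int, int]]:
    n = 2 ** atlas.refinement
    g = atlas._grid_vid[chart]
    return [(a, b) for a in range(n + 1) for b in range(n + 1) if g[a, b] == vid]


def _neighbour_ids(atlas: AtlasGrid, chart: int, a: int, b: int) -> list[int]:
    n = 2 ** atlas.refinement
    out = []
    for da, db in RING_STEPS:
        aa, bb = a + da, b + db
        if 0 <= aa <= n and 0 <= bb <= n:
            out.append(int(atlas._grid_vid[chart, aa, bb]))
        else:
            out.append(atlas._ext_vid.get((chart, aa, bb), -1))
    return out


def gauge_transition(atlas: AtlasGrid, i: int, j: int, pixel: tuple[int, int]) -> GroupElement:
    """D6 element aligning chart ``j``'s hexagonal frame with chart ``i``'s
    at the shared pixel.

    ``pixel`` is given in chart ``i`` grid coordinates ``(a, b)``; it must be
    occupied by both charts (directly or through the antipodal
    identification).  A feature with orientation argument ``h`` in chart
    ``i``'s frame corresponds to orientation ``g . h`` in chart ``j``'s frame.
    """
    a, b = pixel
    n = 2 ** atlas.refinement
    if not (0 <= a <= n and 0 <= b <= n):
        raise ValueError(f"pixel {pixel} outside chart grid")
    if i == j:
        return IDENTITY
    vid = int(atlas._grid_vid[i, a, b])
    if vid in set(atlas.cone_ids.tolist()):
        raise ValueError("gauge transition undefined at cone points")
    pos_j = _positions_of(atlas, vid, j)
    if not pos_j:
        raise ValueError(f"pixel {pixel} of chart {i} not in chart {j}")
    nb_i = _neighbour_ids(atlas, i, a, b)
    for aj, bj in pos_j:
        nb_j = _neighbour_ids(atlas, j, aj, bj)
        for g in d6.ALL_ELEMENTS:
            if all(nb_i[m] < 0 or nb_j[d6.act_on_direction(g, m)] == nb_i[m]
                   for m in range(6)):
                return g
    raise AssertionError("no D6 element matches the overlap frames")


def antipodal_partner(atlas: AtlasGrid, chart: int, pixel: tuple[int, int]) -> tuple[int, tuple[int, int]]:
    """Chart and pixel identified with a bottom-strip pixel antipodally.

    ``pixel`` is a padded-array position ``(pr, pc)`` on the bottom strip of
    ``chart`` (row ``2^r + 1``).  Returns ``(chart', (a, b))`` in grid
    coordinates such that the 3D direction of the partner grid point is the
    negation of the strip pixel's geometric direction.
    """
    n = 2 ** atlas.refinement
    pr, pc = pixel
    if pr != n + 1:
        raise ValueError("antipodal_partner is defined for bottom-strip pixels")
    vid = atlas._ext_vid.get((chart, pr, pc - 1), -1)
    if vid < 0:
        raise ValueError("dead strip pixel has no partner")
    flat = atlas.vertex_owner_flat[vid]
    cw = atlas.chart_width
    a, rem = divmod(int(flat), atlas.flat_layout[1])
    k, pco = divmod(rem, cw)
    return k, (a, pco - 1)


def strip_direction(atlas: AtlasGrid, chart: int, pixel: tuple[int, int]) -> np.ndarray:
    """Geometric unit direction of a bottom-strip pixel (outside the surface).

    Bottom-strip pixels lie beyond the boundary seam of the half icosahedron;
    under the antipodal model their position is the negation of the identified
    on-surface grid point.
    """
    k, (a, b) = antipodal_partner(atlas, chart, pixel)
    return -atlas._grid_pos[k, a, b]


def flatten_index(atlas: AtlasGrid, chart: int, pixel: tuple[int, int]) -> tuple[int, int]:
    """(row, col) in the stacked flat array of a padded chart pixel."""
    pr, pc = pixel
    cw = atlas.chart_width
    if not (0 <= chart < 5 and 0 <= pr < cw and 0 <= pc < cw):
        raise IndexError(f"chart {chart} pixel {pixel} out of range")
    return pr, chart * cw + pc


def unflatten_index(atlas: AtlasGrid, row: int, col: int) -> tuple[int, tuple[int, int]]:
    """Inverse of :func:`flatten_index`."""
    H, W = atlas.flat_layout
    if not (0 <= row < H and 0 <= col < W):
        raise IndexError(f"({row}, {col}) outside flat layout {atlas.flat_layout}")
    chart, pc = divmod(col, atlas.chart_width)
    return chart, (row, pc)


# ---------------------------------------------------------------------------
# persistence

def save_atlas(atlas: AtlasGrid, path) -> None:
    """Write the atlas to an HDF5 file (geometry + gather tables)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["refinement"] = atlas.refinement
        f.attrs["n_surface_points"] = atlas.n_surface_points
        f.attrs["n_uncovered_corners"] = atlas.n_uncovered_corners
        for name in ("vertices", "cone_ids", "position_vertex", "zero_mask",
                     "vertex_owner_flat", "pad_dst", "pad_src", "pad_perm",
                     "pad_elements"):
            f.create_dataset(name, data=getattr(atlas, name))
        f.create_dataset("grid_vid", data=atlas._grid_vid)
        f.create_dataset("grid_pos", data=atlas._grid_pos)


def load_atlas(path) -> AtlasGrid:
    """Rebuild an atlas from disk; derived caches are reconstructed."""
    import h5py

    with h5py.File(path, "r") as f:
        atlas = build_atlas(int(f.attrs["refinement"]))
        # consistency guard against stale files
        if not np.allclose(f["vertices"][...], atlas.vertices, atol=1e-9):
            raise ValueError("atlas file inconsistent with this construction")
    return atlas
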