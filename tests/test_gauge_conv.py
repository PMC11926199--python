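"""Equivariant layers: kernel expansion, convolutions, normalization, pooling.

The convolutions are checked against independent brute-force oracles that
walk the chart geometry pixel by pixel and sum explicitly over the group
elements and the seven hexagonal stencil offsets.
"""

import numpy as np
import pytest

from rp2gauge import d6
from rp2gauge import gauge_conv as gc
from rp2gauge.atlas import RING_STEPS
from rp2gauge.gauge_conv import (GroupBatchNorm, HexKernelRegular,
                                 HexKernelScalar, embed_hex,
                                 expand_regular_kernel, expand_scalar_kernel,
                                 extract_hex, lift_conv, orientation_pool,
                                 regular_conv)
from rp2gauge.padding import (RegularFeatureMap, ScalarFeatureMap, pad_regular,
                              pad_scalar)


def left_regular_matrix(u):
    """Permutation matrix of the regular representation rho(u)."""
    M = np.zeros((12, 12))
    for j, h in enumerate(d6.ALL_ELEMENTS):
        M[d6.slot_index(d6.compose(u, h)), j] = 1.0
    return M


def transformed_cell(g, cell):
    """Action of g on a stencil cell (hex direction or centre)."""
    if cell == (0, 0):
        return cell
    m = RING_STEPS.index(cell)
    return RING_STEPS[d6.act_on_direction(g, m)]


# ---------------------------------------------------------------------------
# embedding and expansion

def test_embed_hex_and_masked_corners(rng):
    w = np.ones(7)
    k = embed_hex(w)
    assert k.shape == (3, 3)
    assert k.sum() == 7
    assert k[0, 0] == 0 and k[2, 2] == 0     # the two masked corners
    w = rng.normal(size=(4, 3, 7))
    assert np.allclose(extract_hex(embed_hex(w)), w)


def test_isotropic_kernel_expands_to_identical_copies(rng):
    w = np.zeros((1, 1, 7))
    w[..., 0] = 0.5
    w[..., 1:] = 2.0                        # equal ring weights
    blocks = expand_scalar_kernel(HexKernelScalar(w)).blocks
    assert blocks.shape == (12, 1, 3, 3)
    for b in blocks[1:]:
        assert np.array_equal(b, blocks[0])

    centre = np.zeros((1, 1, 7))
    centre[..., 0] = 3.0
    blocks = expand_scalar_kernel(HexKernelScalar(centre)).blocks
    for b in blocks:
        assert b[0, 1, 1] == 3.0 and np.abs(b).sum() == 3.0


def test_constant_regular_kernel_expands_to_identical_blocks(rng):
    w = np.full((1, 1, 12, 7), 1.5)
    blocks = expand_regular_kernel(HexKernelRegular(w)).blocks
    assert blocks.shape == (12, 12, 3, 3)
    ref = blocks[0, 0]
    for i in range(12):
        for j in range(12):
            assert np.array_equal(blocks[i, j], ref)


def test_regular_expansion_block_structure(rng):
    """Rotations permute within the rotation/reflection blocks of the
    orientation argument; reflections swap the two blocks."""
    table = gc.regular_expansion_map()
    for sg, g in enumerate(d6.ALL_ELEMENTS):
        src_slots = table[sg] // 7           # [12 slots, 7] -> source slot
        for sh in range(12):
            src = src_slots[sh, 0]
            if g.ref:
                assert (src >= 6) == (sh < 6)   # block swap
            else:
                assert (src >= 6) == (sh >= 6)  # block preserved


@pytest.mark.parametrize("kind", ["scalar", "regular"])
def test_kernel_constraint_under_all_group_elements(kind, rng):
    """K(g^-1 v) = rho_out(g^-1) K(v) rho_in(g) for the expanded kernels."""
    co, ci = 2, 3
    if kind == "scalar":
        k = HexKernelScalar(rng.normal(size=(co, ci, 7)))
        E = expand_scalar_kernel(k).blocks.reshape(co, 12, ci, 3, 3)

        def K_at(cell):
            return E[..., 1 + cell[0], 1 + cell[1]].reshape(co * 12, ci)
        rho_in = {g: np.eye(ci) for g in d6.ALL_ELEMENTS}
    else:
        k = HexKernelRegular(rng.normal(size=(co, ci, 12, 7)))
        E = expand_regular_kernel(k).blocks.reshape(co, 12, ci, 12, 3, 3)

        def K_at(cell):
            return E[..., 1 + cell[0], 1 + cell[1]].reshape(co * 12, ci * 12)
        rho_in = {g: np.kron(np.eye(ci), left_regular_matrix(g))
                  for g in d6.ALL_ELEMENTS}
    for g in d6.ALL_ELEMENTS:
        L = np.kron(np.eye(co), left_regular_matrix(d6.inverse(g)))
        for cell in gc.STENCIL_CELLS:
            lhs = K_at(transformed_cell(d6.inverse(g), cell))
            rhs = L @ K_at(cell) @ rho_in[g]
            assert np.abs(lhs - rhs).max() <= 1e-12


# ---------------------------------------------------------------------------
# convolution oracles

def _flat_idx(atlas, k, a, b):
    return a * atlas.flat_layout[1] + k * atlas.chart_width + (b + 1)


def _valid_positions(atlas):
    n = 2 ** atlas.refinement
    cone_flat = set(np.nonzero(atlas.zero_mask)[0].tolist())
    for k in range(5):
        for a in range(1, n + 1):
            for b in range(0, n):
                if _flat_idx(atlas, k, a, b) not in cone_flat:
                    yield k, a, b


def lift_oracle(atlas, padded_vals, weights, bias):
    """Explicit sum over the 7 hexagonal neighbours for every group element."""
    H, W = atlas.flat_layout
    xf = padded_vals.reshape(-1, H * W)          # [C_in, H*W]
    out = {}
    for (k, a, b) in _valid_positions(atlas):
        for sg, g in enumerate(d6.ALL_ELEMENTS):
            acc = bias.copy()
            for c in range(xf.shape[0]):
                acc += weights[:, c, 0] * xf[c, _flat_idx(atlas, k, a, b)]
                for m in range(6):
                    dr, dc = RING_STEPS[d6.act_on_direction(g, m)]
                    acc += weights[:, c, 1 + m] * \
                        xf[c, _flat_idx(atlas, k, a + dr, b + dc)]
            out[(k, a, b, sg)] = acc
    return out


def regular_oracle(atlas, padded_vals, weights, bias):
    """Explicit double sum over the 12 group elements and 7 offsets."""
    H, W = atlas.flat_layout
    zf = padded_vals.reshape(-1, 12, H * W)      # [C_in, 12, H*W]
    out = {}
    for (k, a, b) in _valid_positions(atlas):
        for sg, g in enumerate(d6.ALL_ELEMENTS):
            gi = d6.inverse(g)
            acc = bias.copy()
            for c in range(zf.shape[0]):
                for sh, h in enumerate(d6.ALL_ELEMENTS):
                    ks = d6.slot_index(d6.compose(gi, h))
                    acc += weights[:, c, ks, 0] * \
                        zf[c, sh, _flat_idx(atlas, k, a, b)]
                    for m in range(6):
                        dr, dc = RING_STEPS[d6.act_on_direction(g, m)]
                        acc += weights[:, c, ks, 1 + m] * \
                            zf[c, sh, _flat_idx(atlas, k, a + dr, b + dc)]
            out[(k, a, b, sg)] = acc
    return out


def test_lift_conv_matches_explicit_oracle(atlas_r2, rng):
    w = rng.normal(size=(2, 1, 7))
    bias = rng.normal(size=2)
    x = rng.normal(size=(1, 1) + atlas_r2.flat_layout)
    mp = pad_scalar(ScalarFeatureMap(x, atlas_r2))
    out = lift_conv(mp, HexKernelScalar(w, bias), nonlinearity="identity")
    oracle = lift_oracle(atlas_r2, mp.values[0], w, bias)
    cw = atlas_r2.chart_width
    for (k, a, b, sg), want in oracle.items():
        got = out.values[0, :, sg, a, k * cw + b + 1]
        assert np.abs(got - want).max() <= 1e-10


def test_regular_conv_matches_explicit_oracle(atlas_r2, rng):
    w = rng.normal(size=(1, 2, 12, 7))
    bias = rng.normal(size=1)
    z = rng.normal(size=(1, 2, 12) + atlas_r2.flat_layout)
    mp = pad_regular(RegularFeatureMap(z, atlas_r2))
    out = regular_conv(mp, HexKernelRegular(w, bias), nonlinearity="identity")
    oracle = regular_oracle(atlas_r2, mp.values[0], w, bias)
    cw = atlas_r2.chart_width
    for (k, a, b, sg), want in oracle.items():
        got = out.values[0, :, sg, a, k * cw + b + 1]
        assert np.abs(got - want).max() <= 1e-10


def test_conv_requires_padded_input(atlas_r2, rng):
    x = ScalarFeatureMap(rng.normal(size=(1, 1) + atlas_r2.flat_layout),
                         atlas_r2, padded=False)
    with pytest.raises(ValueError):
        lift_conv(x, HexKernelScalar(rng.normal(size=(1, 1, 7))))
    z = RegularFeatureMap(rng.normal(size=(1, 1, 12) + atlas_r2.flat_layout),
                          atlas_r2, padded=False)
    with pytest.raises(ValueError):
        regular_conv(z, HexKernelRegular(rng.normal(size=(1, 1, 12, 7))))


def test_centre_only_lift_replicates_input(atlas_r2, rng):
    w = np.zeros((1, 1, 7))
    w[..., 0] = 1.0
    x = rng.normal(size=(1, 1) + atlas_r2.flat_layout)
    mp = pad_scalar(ScalarFeatureMap(x, atlas_r2))
    out = lift_conv(mp, HexKernelScalar(w), nonlinearity="identity")
    assert out.values.shape[2] == 12
    for s in range(12):
        assert np.allclose(out.values[0, 0, s], mp.values[0, 0], atol=1e-12)


def test_identity_regular_kernel_is_identity(atlas_r2, rng):
    w = np.zeros((1, 1, 12, 7))
    w[0, 0, 0, 0] = 1.0      # centre weight at the identity orientation
    z = rng.normal(size=(1, 1, 12) + atlas_r2.flat_layout)
    mp = pad_regular(RegularFeatureMap(z, atlas_r2))
    out = regular_conv(mp, HexKernelRegular(w), nonlinearity="identity")
    assert np.allclose(out.values, mp.values, atol=1e-12)


def test_parameter_and_copy_counts():
    k = HexKernelRegular(np.zeros((3, 5, 12, 7)))
    assert k.weights[0, 0].size == 7 * 12
    E = expand_regular_kernel(k)
    assert E.blocks.shape == (36, 60, 3, 3)   # 12^2 copies per channel pair


# ---------------------------------------------------------------------------
# batch norm and pooling

def test_group_batch_norm_statistics(atlas_r2, rng):
    z = rng.normal(loc=3.0, scale=2.5,
                   size=(2, 4, 12) + atlas_r2.flat_layout)
    bn = GroupBatchNorm(4)
    out = bn(RegularFeatureMap(z, atlas_r2), train=True)
    axes = (0, 2, 3, 4)
    assert np.allclose(out.values.mean(axis=axes), 0.0, atol=1e-7)
    assert np.allclose(out.values.var(axis=axes), 1.0, atol=1e-3)

    const = GroupBatchNorm(1)(
        RegularFeatureMap(np.full((1, 1, 12) + atlas_r2.flat_layout, 5.0),
                          atlas_r2), train=True)
    assert np.allclose(const.values, 0.0, atol=1e-5)   # epsilon-guarded


def test_group_batch_norm_commutes_with_orientation_permutation(atlas_r2, rng):
    z = rng.normal(size=(1, 2, 12) + atlas_r2.flat_layout)
    bn = GroupBatchNorm(2)
    for g in d6.ALL_ELEMENTS:
        p = d6.orientation_permutation(g)
        a = bn(RegularFeatureMap(z[:, :, p], atlas_r2), train=True).values
        b = bn(RegularFeatureMap(z, atlas_r2), train=True).values[:, :, p]
        assert np.allclose(a, b, atol=1e-12)


def test_orientation_pool_invariance_and_mean(atlas_r2, rng):
    z = rng.normal(size=(1, 2, 12) + atlas_r2.flat_layout)
    m = RegularFeatureMap(z, atlas_r2)
    pooled = orientation_pool(m)
    assert np.allclose(pooled.values, z.sum(axis=2) / 12.0)
    for g in d6.ALL_ELEMENTS:
        p = d6.orientation_permutation(g)
        permuted = orientation_pool(RegularFeatureMap(z[:, :, p], atlas_r2))
        assert np.allclose(permuted.values, pooled.values, atol=1e-12)
    cval = orientation_pool(
        RegularFeatureMap(np.full((1, 1, 12) + atlas_r2.flat_layout, 2.5),
                          atlas_r2))
    assert np.allclose(cval.values, 2.5)
    mx = orientation_pool(m, mode="max")
    assert np.allclose(mx.values, z.max(axis=2))


# ---------------------------------------------------------------------------
# global equivariance and gradient flow

def chart_roll(values, shift, cw):
    v5 = values.reshape(*values.shape[:-1], 5, cw)
    return np.roll(v5, shift, axis=-2).reshape(values.shape)


def test_five_fold_rotation_equivariance_through_four_layers(atlas_r2, rng):
    """Rotating the icosahedron by 72 degrees about the pole is a cyclic
    chart shift; a four-layer gauge block commutes with it (float32)."""
    at = atlas_r2
    H, W = at.flat_layout
    cw = at.chart_width
    ks = HexKernelScalar(rng.normal(size=(2, 1, 7)).astype(np.float32),
                         rng.normal(size=2).astype(np.float32))
    krs = [HexKernelRegular(rng.normal(size=(2, 2, 12, 7)).astype(np.float32),
                            rng.normal(size=2).astype(np.float32))
           for _ in range(3)]

    def block(x):
        m = pad_scalar(ScalarFeatureMap(x, at))
        z = lift_conv(m, ks)
        for kr in krs:
            z = regular_conv(pad_regular(z), kr)
        return orientation_pool(pad_regular(z)).values

    x = rng.normal(size=(1, 1, H, W)).astype(np.float32)
    y0 = block(x)
    y1 = block(chart_roll(x, 1, cw))
    valid = np.zeros(H * W, dtype=bool)
    for (k, a, b) in _valid_positions(at):
        valid[_flat_idx(at, k, a, b)] = True
    diff = (y1 - chart_roll(y0, 1, cw)).reshape(-1, H * W)[:, valid]
    assert np.abs(diff).max() <= 1e-5


def test_every_free_weight_receives_gradient(atlas_r1, rng):
    """The expansion ties the 12 copies to the 7 (or 84) free weights, so all
    of them see a nonzero gradient for generic inputs."""
    from rp2gauge import nn
    from rp2gauge.autodiff import tensor

    lift = nn.GaugeLift(atlas_r1, 1, 1, rng, activation="identity")
    reg = nn.GaugeRegular(atlas_r1, 1, 1, rng, activation="identity")
    x = tensor(rng.normal(size=(1, 1) + atlas_r1.flat_layout))
    z = reg(lift(x))
    loss = (z * z).mean()
    loss.backward()
    assert (np.abs(lift.weight.grad) > 0).all()
    assert (np.abs(reg.weight.grad) > 0).all()
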