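"""Joint channel-spatial attention: descriptor shapes, pooled statistics
against axis-reduction oracles, interaction MLP behaviour, gate
boundedness, and the C3k2 substitution block's layer inventory."""

import numpy as np
import pytest

from rdblocks import autograd as ag, nn
from rdblocks.autograd import Tensor
from rdblocks.blocks import C3k2, C3k2CSCBAM, CSCBAM


def test_descriptor_shapes(rng):
    cs = CSCBAM(8, spatial_tokens=4)
    pair = cs.compress(rng.standard_normal((8, 4, 4)).astype(np.float32))
    assert pair.channel_descriptor.shape == (8,)
    assert pair.spatial_descriptor.shape == (4, 4)


def test_constant_input_pools_agree(rng):
    """Max and average pooling of a constant map coincide, so the fused
    channel descriptor equals twice one MLP pass."""
    cs = CSCBAM(6, spatial_tokens=3)
    x = Tensor(np.full((1, 6, 3, 3), 1.7, np.float32))
    with ag.no_grad():
        cd, _ = cs._compress_tensors(x)
        one = cs._shared_mlp(Tensor(np.full((1, 6), 1.7, np.float32)))
    assert np.allclose(cd.numpy(), 2 * one.numpy(), atol=1e-6)


def test_pooled_statistics_match_axis_reduction_oracle(rng):
    """Channel/spatial descriptors derive from brute-force max/mean over
    the stated axes (2x2x2 toy recomputed in plain numpy)."""
    cs = CSCBAM(2, spatial_tokens=2)
    x = rng.standard_normal((1, 2, 2, 2)).astype(np.float32)
    with ag.no_grad():
        cd, sd = cs._compress_tensors(Tensor(x))
        # oracle for the channel path: numpy reductions through the same MLP
        mx = x.max(axis=(2, 3))
        av = x.mean(axis=(2, 3))
        want_cd = (cs._shared_mlp(Tensor(mx)) + cs._shared_mlp(Tensor(av))).numpy()
        # oracle for the spatial path: stacked channel max/mean through the conv
        smax = x.max(axis=1, keepdims=True)
        smean = x.mean(axis=1, keepdims=True)
        want_sd = cs.spatial_fuse(Tensor(np.concatenate([smax, smean], 1))).numpy()
    assert np.allclose(cd.numpy(), want_cd, atol=1e-6)
    assert np.allclose(sd.numpy(), want_sd, atol=1e-6)


def test_joint_descriptor_length_is_hw_plus_c(rng):
    cs = CSCBAM(8, spatial_tokens=4)
    pair = cs.compress(rng.standard_normal((8, 4, 4)).astype(np.float32))
    joint = cs.interact(pair)
    assert joint.values.shape == (4 * 4 + 8,)


def test_identity_interaction_passes_raw_concatenation(rng):
    """An MLP wired as x -> relu(x), -relu(-x) -> sum is the identity, so
    the joint descriptor equals the raw concatenation."""
    cs = CSCBAM(8, spatial_tokens=2, interact_hidden_ratio=2.0)
    n = 2 * 2 + 8
    eye = np.eye(n, dtype=np.float32)
    cs.inter1.weight.data = np.concatenate([eye, -eye], axis=1)
    cs.inter1.bias.data[:] = 0
    cs.inter2.weight.data = np.concatenate([eye, -eye], axis=0)
    cs.inter2.bias.data[:] = 0
    pair = cs.compress(rng.standard_normal((8, 2, 2)).astype(np.float32))
    joint = cs.interact(pair)
    raw = np.concatenate([np.asarray(pair.spatial_descriptor).ravel(),
                          pair.channel_descriptor])
    assert np.allclose(joint.values, raw, atol=1e-5)


def test_zero_interaction_mlp_gives_zero_joint_and_quarter_gain(rng):
    cs = CSCBAM(4, spatial_tokens=3)
    for lin in (cs.inter1, cs.inter2):
        lin.weight.data[:] = 0
        lin.bias.data[:] = 0
    pair = cs.compress(rng.standard_normal((4, 3, 3)).astype(np.float32))
    assert np.all(cs.interact(pair).values == 0)
    # both gates sigmoid(0) = 0.5 -> output is 0.25 * input
    x = rng.standard_normal((1, 4, 3, 3)).astype(np.float32)
    with ag.no_grad():
        out = cs(Tensor(x)).numpy()
    assert np.allclose(out, 0.25 * x, atol=1e-6)


def test_gates_bound_output_by_input(rng):
    cs = CSCBAM(4, spatial_tokens=6)
    x = rng.standard_normal((1, 4, 6, 6)).astype(np.float32)
    with ag.no_grad():
        out = cs(Tensor(x)).numpy()
    assert (np.abs(out) <= np.abs(x) + 1e-7).all()
    assert out.shape == x.shape


def test_end_to_end_matches_scalar_reference(rng):
    """Full compress -> interact -> separate recomputed with plain numpy
    on a fixed-seed 4x6x6 input."""
    cs = CSCBAM(4, spatial_tokens=6)
    x = np.random.default_rng(42).standard_normal((1, 4, 6, 6)).astype(np.float32)
    with ag.no_grad():
        out = cs(Tensor(x)).numpy()

    def mlp(v, l1, l2):
        h = np.maximum(v @ l1.weight.data + l1.bias.data, 0)
        return h @ l2.weight.data + l2.bias.data

    sigmoid = lambda z: 1.0 / (1.0 + np.exp(-z))
    cd = (mlp(x.max(axis=(2, 3)), cs.mlp1, cs.mlp2)
          + mlp(x.mean(axis=(2, 3)), cs.mlp1, cs.mlp2))
    stack = np.concatenate([x.max(axis=1, keepdims=True),
                            x.mean(axis=1, keepdims=True)], axis=1)
    wsf = cs.spatial_fuse.weight.data
    sd = np.zeros((1, 1, 6, 6), np.float32)
    pad = np.pad(stack, ((0, 0), (0, 0), (3, 3), (3, 3)))
    for i in range(6):
        for j in range(6):
            sd[0, 0, i, j] = (pad[0, :, i:i + 7, j:j + 7] * wsf[0]).sum()
    joint = mlp(np.concatenate([sd.reshape(1, 36), cd], axis=1), cs.inter1, cs.inter2)
    sgate = sigmoid(joint[:, :36]).reshape(1, 1, 6, 6)
    cgate = sigmoid(joint[:, 36:]).reshape(1, 4, 1, 1)
    want = x * cgate * sgate
    assert np.allclose(out, want, atol=1e-5)


# -- C3k2-CSCBAM ----------------------------------------------------------


def test_block_has_exactly_one_bn_and_one_relu():
    inv = C3k2CSCBAM(128, 128).layer_inventory()
    assert inv.get("BatchNorm2d") == 1
    assert inv.get("ReLU") == 1


def test_block_shape_contract(rng):
    block = C3k2CSCBAM(128, 96).eval()
    out = block(Tensor(rng.standard_normal((1, 128, 20, 20)).astype(np.float32)))
    assert out.shape == (1, 96, 20, 20)


def test_block_parameters_below_plain_c3k2():
    nn.seed_all(0)
    ours = C3k2CSCBAM(128, 128).num_parameters()
    nn.seed_all(0)
    base = C3k2(128, 128, n=1).num_parameters()
    assert ours < base
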