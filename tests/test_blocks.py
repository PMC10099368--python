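"""Block-level contracts: shape arithmetic, residual identities, attention
against a brute-force oracle, and closed-form parameter counts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uwdet import nn
from uwdet.blocks import (BlockConfig, BoT, BoT3, C3, ChannelAttention,
                          ConfigurationError, ConvBnAct, CSPLayer,
                          CSPNeXtBlock, MHSA, SPPF)
from uwdet.tensor import Tensor


def rand_fm(rng, c, h, w, n=1):
    return Tensor(rng.normal(size=(n, c, h, w)))


def zero_batchnorm(module):
    """Zero every batch-norm scale inside a module (branch kill switch)."""
    for m in module.modules():
        if isinstance(m, nn.BatchNorm2d):
            m.weight.data[:] = 0.0
            m.bias.data[:] = 0.0


# -- ConvBnAct ---------------------------------------------------------------

def test_conv_bn_act_stride_two_halves_spatial(rng):
    blk = ConvBnAct(3, 40, 3, 2, rng=rng).eval()
    out = blk(rand_fm(rng, 3, 416, 416))
    assert out.shape == (1, 40, 208, 208)


def test_conv_bn_act_zero_input_fixed_point(rng):
    blk = ConvBnAct(4, 8, 3, 1, rng=rng).eval()   # BN at identity in eval
    out = blk(Tensor(np.zeros((1, 4, 7, 7))))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


def test_conv_matches_sliding_window_oracle(rng):
    x = rng.normal(size=(1, 1, 5, 5))
    w = rng.normal(size=(2, 1, 3, 3))
    out = Tensor(x).conv2d(Tensor(w), stride=1, padding=1).data
    xp = np.pad(x[0, 0], 1)
    expected = np.zeros((2, 5, 5))
    for o in range(2):
        for i in range(5):
            for j in range(5):
                expected[o, i, j] = (xp[i:i + 3, j:j + 3] * w[o, 0]).sum()
    np.testing.assert_allclose(out[0], expected, atol=1e-10)


def test_conv_channel_mismatch_is_configuration_error(rng):
    blk = ConvBnAct(4, 8, 3, rng=rng)
    with pytest.raises(ConfigurationError):
        blk(rand_fm(rng, 3, 8, 8))


# -- CSPNeXt block -----------------------------------------------------------

def test_cspnext_residual_identity_with_zeroed_branch(rng):
    blk = CSPNeXtBlock(16, 16, add=True, rng=rng).eval()
    zero_batchnorm(blk)
    x = rand_fm(rng, 16, 9, 9)
    np.testing.assert_allclose(blk(x).data, x.data, atol=1e-12)


def test_cspnext_second_conv_uses_large_kernel(rng):
    blk = CSPNeXtBlock(8, 8, rng=rng)
    assert blk.conv2.conv.kernel == 5
    assert blk.conv2.conv.groups == 1      # dense convolution by default
    dw = CSPNeXtBlock(8, 8, depthwise=True, rng=rng)
    assert dw.conv2.conv.groups == 8


def test_cspnext_parameter_count_closed_form(rng):
    blk = CSPNeXtBlock(64, 64, rng=rng)
    convs = 3 * 3 * 64 * 64 + 5 * 5 * 64 * 64
    bns = 2 * (2 * 64)                      # two affine batch-norms
    assert blk.num_parameters() == convs + bns
    # element-enumeration oracle over the actual arrays
    enumerated = sum(p.data.size for p in blk.parameters())
    assert enumerated == convs + bns


def test_cspnext_add_needs_matching_channels():
    with pytest.raises(ConfigurationError):
        CSPNeXtBlock(8, 16, add=True)
    with pytest.raises(ConfigurationError):
        BlockConfig(8, 16, add_flag=True)


# -- channel attention -------------------------------------------------------

def test_channel_attention_never_amplifies(rng):
    attn = ChannelAttention(6, rng=rng)
    x = rand_fm(rng, 6, 5, 5, n=2)
    out = attn(x)
    assert (np.abs(out.data) <= np.abs(x.data) + 1e-12).all()


def test_channel_attention_pools_constants_exactly(rng):
    attn = ChannelAttention(3, rng=rng)
    c = np.array([0.3, -1.2, 2.0])
    x = Tensor(np.broadcast_to(c[None, :, None, None], (1, 3, 4, 4)).copy())
    pooled = x.mean(axis=(2, 3), keepdims=True).data
    np.testing.assert_allclose(pooled.ravel(), c, atol=1e-14)


def test_channel_attention_hard_sigmoid_closed_form(rng):
    attn = ChannelAttention(2, rng=rng)
    # identity projection, zero bias: gate = hardsigmoid(pooled)
    attn.fc.weight.data = np.eye(2).reshape(2, 2, 1, 1)
    attn.fc.bias.data[:] = 0.0
    x = Tensor(np.full((1, 2, 3, 3), 3.0))
    gate = attn.gate(x).data.ravel()
    np.testing.assert_allclose(gate, min(max(3 / 6 + 0.5, 0), 1))  # = 1.0


# -- CSPLayer ----------------------------------------------------------------

def test_csplayer_defaults_to_one_block_and_keeps_shape(rng):
    layer = CSPLayer(160, 160, rng=rng).eval()
    assert len(layer.blocks) == 1
    out = layer(rand_fm(rng, 160, 52, 52))
    assert out.shape == (1, 160, 52, 52)


def test_csplayer_concat_width_is_twice_hidden(rng):
    layer = CSPLayer(32, 48, rng=rng)
    # shape-propagation oracle: walk the graph pieces independently
    assert layer.hidden == 48 // 2
    assert layer.attn.fc.in_channels == 2 * layer.hidden
    assert layer.final.conv.in_channels == 2 * layer.hidden
    assert layer.final.conv.out_channels == 48


def test_csplayer_rejects_odd_output_width():
    with pytest.raises(ConfigurationError):
        CSPLayer(16, 15)


# -- SPPF --------------------------------------------------------------------

def test_sppf_preserves_shape_and_constants(rng):
    blk = SPPF(16, 24, rng=rng).eval()
    out = blk(rand_fm(rng, 16, 13, 13))
    assert out.shape == (1, 24, 13, 13)


def test_chained_pools_equal_parallel_5_9_13(rng):
    x = Tensor(rng.normal(size=(1, 3, 11, 11)))
    p1 = x.maxpool2d(5, 1, 2)
    p2 = p1.maxpool2d(5, 1, 2)
    p3 = p2.maxpool2d(5, 1, 2)
    np.testing.assert_allclose(p1.data, x.maxpool2d(5, 1, 2).data, atol=1e-6)
    np.testing.assert_allclose(p2.data, x.maxpool2d(9, 1, 4).data, atol=1e-6)
    np.testing.assert_allclose(p3.data, x.maxpool2d(13, 1, 6).data, atol=1e-6)


# -- MHSA --------------------------------------------------------------------

def mhsa_oracle(x, wq, wk, wv, heads):
    """Two-nested-loop per-position attention (content-only, scaled)."""
    n, c, h, w = x.shape
    dh = c // heads
    npos = h * w
    flat = x.reshape(n, c, npos)
    out = np.zeros_like(flat)
    q = np.einsum("oc,ncp->nop", wq.reshape(c, c), flat)
    k = np.einsum("oc,ncp->nop", wk.reshape(c, c), flat)
    v = np.einsum("oc,ncp->nop", wv.reshape(c, c), flat)
    for b in range(n):
        for hd in range(heads):
            sl = slice(hd * dh, (hd + 1) * dh)
            for i in range(npos):
                logits = np.empty(npos)
                for j in range(npos):
                    logits[j] = q[b, sl, i] @ k[b, sl, j] / np.sqrt(dh)
                weights = np.exp(logits - logits.max())
                weights /= weights.sum()
                out[b, sl, i] = sum(weights[j] * v[b, sl, j]
                                    for j in range(npos))
    return out.reshape(n, c, h, w)


def test_mhsa_matches_bruteforce_oracle(rng):
    m = MHSA(8, heads=2, rng=rng)
    x = rand_fm(rng, 8, 4, 4)
    expected = mhsa_oracle(x.data, m.wq.weight.data, m.wk.weight.data,
                           m.wv.weight.data, heads=2)
    np.testing.assert_allclose(m(x).data, expected, atol=1e-5)


def test_mhsa_matches_oracle_at_larger_size(rng):
    m = MHSA(16, heads=4, rng=rng)
    x = rand_fm(rng, 16, 8, 8)
    expected = mhsa_oracle(x.data, m.wq.weight.data, m.wk.weight.data,
                           m.wv.weight.data, heads=4)
    np.testing.assert_allclose(m(x).data, expected, atol=1e-5)


def test_mhsa_rows_sum_to_one_and_default_heads(rng):
    m = MHSA(8, rng=rng)
    assert m.heads == 4
    attn = m.attention_weights(rand_fm(rng, 8, 3, 5)).data
    np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)


def test_mhsa_singleton_softmax(rng):
    m = MHSA(4, heads=2, rng=rng)
    x = rand_fm(rng, 4, 1, 1)
    attn = m.attention_weights(x).data
    np.testing.assert_allclose(attn, 1.0)
    expected = np.einsum("oc,nchw->nohw", m.wv.weight.data.reshape(4, 4),
                         x.data)
    np.testing.assert_allclose(m(x).data, expected, atol=1e-12)


def test_mhsa_rejects_indivisible_heads():
    with pytest.raises(ConfigurationError):
        MHSA(10, heads=4)


# -- BoT / BoT3 --------------------------------------------------------------

def test_bot_residual_identity_with_zeroed_branch(rng):
    blk = BoT(8, rng=rng).eval()
    zero_batchnorm(blk.expand)
    x = rand_fm(rng, 8, 4, 4)
    np.testing.assert_allclose(blk(x).data, x.data, atol=1e-12)


def test_bot_fewer_parameters_than_resnet_bottleneck(rng):
    c = 32
    bot = BoT(c, rng=rng)
    # closed-form ResNet bottleneck at equal channels: 1x1 + 3x3 + 1x1 + BNs
    resnet = (c * c + 9 * c * c + c * c) + 3 * 2 * c
    assert bot.num_parameters() < resnet


def test_bot3_preserves_shape_and_channels(rng):
    blk = BoT3(32, 32, rng=rng).eval()
    out = blk(rand_fm(rng, 32, 13, 13))
    assert out.shape == (1, 32, 13, 13)


def test_bot3_contains_exactly_one_mhsa_node(rng):
    blk = BoT3(16, 16, rng=rng)
    assert sum(isinstance(m, MHSA) for m in blk.modules()) == 1


def test_bot3_zeroed_inner_reduces_to_shortcut_path(rng):
    blk = BoT3(16, 16, rng=rng).eval()
    zero_batchnorm(blk.cv1)
    for b in blk.m:
        zero_batchnorm(b)
    x = rand_fm(rng, 16, 5, 5)
    # main branch emits zeros (cv1 then identity-killed BoT): result equals
    # cv3 applied to [0, cv2(x)]
    shortcut = blk.cv2(x)
    zeros = Tensor(np.zeros_like(shortcut.data))
    from uwdet.tensor import concatenate
    expected = blk.cv3(concatenate([zeros, shortcut], axis=1))
    np.testing.assert_allclose(blk(x).data, expected.data, atol=1e-10)


# -- property sweep ----------------------------------------------------------

@settings(max_examples=15, deadline=None, derandomize=True)
@given(c_out=st.sampled_from([8, 16, 24]), h=st.integers(3, 9),
       w=st.integers(3, 9), kind=st.sampled_from(
           ["csplayer", "c3", "sppf", "bot3", "cspnext"]))
def test_stride_one_blocks_preserve_spatial_and_declare_channels(c_out, h, w,
                                                                 kind):
    rng = np.random.default_rng(c_out * 1000 + h * 10 + w)
    c_in = 12
    if kind == "csplayer":
        blk = CSPLayer(c_in, c_out, rng=rng)
    elif kind == "c3":
        blk = C3(c_in, c_out, n=2, rng=rng)
    elif kind == "sppf":
        blk = SPPF(c_in, c_out, rng=rng)
    elif kind == "bot3":
        blk = BoT3(c_in, c_out, heads=2, rng=rng)
    else:
        blk = CSPNeXtBlock(c_in, c_out, add=False, rng=rng)
    out = blk.eval()(Tensor(rng.normal(size=(1, c_in, h, w))))
    assert out.shape == (1, c_out, h, w)
    assert blk.out_hw(h, w) == (h, w)
    assert np.isfinite(out.data).all()


def test_parameter_counts_match_closed_form_layer_sums(rng):
    """Whole-block counts equal sums of per-layer conv/BN closed forms."""
    def closed_form(module):
        total = 0
        for m in module.modules():
            if isinstance(m, nn.Conv2d):
                total += (m.out_channels * (m.in_channels // m.groups)
                          * m.kernel ** 2)
                if m.bias is not None:
                    total += m.out_channels
            elif isinstance(m, nn.BatchNorm2d):
                total += 2 * m.num_features
        return total

    for blk in (CSPLayer(16, 32, n=2, rng=rng), C3(16, 32, n=3, rng=rng),
                SPPF(16, 8, rng=rng), BoT3(16, 16, rng=rng),
                MHSA(8, rng=rng)):
        assert blk.num_parameters() == closed_form(blk)
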