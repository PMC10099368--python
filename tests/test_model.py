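"""Assembly audits: backbone/neck/head structure, pyramid shapes, and
parameter/FLOP accounting against independent closed-form sums."""

import numpy as np
import pytest

from uwdet import nn
from uwdet.blocks import BoT3, C3, ConvBnAct, CSPLayer, MHSA, SPPF
from uwdet.model import (DetectionModel, ModelConfig, build_backbone,
                         build_head, build_neck, count_flops,
                         count_parameters, make_divisible, model_summary)
from uwdet.tensor import Tensor


def nano_cfg(nc=5, size=96):
    return ModelConfig(num_classes=nc, input_size=size, scale="n")


# -- structural audits -------------------------------------------------------

def test_improved_backbone_has_stem_of_three_convs_and_four_stages():
    bb = build_backbone(nano_cfg(), variant="improved")
    assert len(bb.stem) == 3
    assert all(isinstance(m, ConvBnAct) for m in bb.stem)
    assert [m.conv.stride for m in bb.stem] == [2, 1, 1]
    assert len(bb.stages) == 4


def test_sppf_lives_in_stage_four_only():
    bb = build_backbone(nano_cfg(), variant="improved")
    for i, stage in enumerate(bb.stages):
        has_sppf = any(isinstance(m, SPPF) for m in stage)
        assert has_sppf == (i == 3)
        assert any(isinstance(m, CSPLayer) for m in stage)


def test_neck_contains_exactly_one_bot3_on_stride16_branch():
    cfg = nano_cfg()
    bb = build_backbone(cfg, variant="improved")
    neck = build_neck(cfg, bb, with_bot3=True)
    bot3s = [m for m in neck.modules() if isinstance(m, BoT3)]
    assert len(bot3s) == 1
    assert neck.bot3 is bot3s[0]
    # the BoT3 operates at the medium (stride-16) width
    assert neck.bot3.cv1.conv.in_channels == neck.out_channels[1]
    assert sum(isinstance(m, MHSA) for m in neck.modules()) == 1


def test_removing_bot3_recovers_classic_neck_node_for_node():
    cfg = nano_cfg()
    bb = build_backbone(cfg, variant="improved")
    with_, without = (build_neck(cfg, bb, with_bot3=f) for f in (True, False))
    names_with = [type(m).__name__ for _, m in with_.children()]
    names_without = [type(m).__name__ for _, m in without.children()]
    assert [n for n in names_with if n != "BoT3"] == names_without
    assert not any(isinstance(m, (BoT3, MHSA)) for m in without.modules())


def test_pyramid_spatial_sizes_at_416():
    cfg = ModelConfig(num_classes=5, input_size=416, scale="n")
    model = DetectionModel(cfg, variant="improved")
    x = Tensor(np.zeros((1, 3, 416, 416)))
    model.eval()
    p3, p4, p5 = model.backbone(x)
    assert (p3.shape[2], p4.shape[2], p5.shape[2]) == (52, 26, 13)


def test_input_size_must_be_divisible_by_32():
    from uwdet.blocks import ConfigurationError
    with pytest.raises(ConfigurationError):
        ModelConfig(num_classes=5, input_size=400)


# -- head --------------------------------------------------------------------

@pytest.mark.parametrize("nc,channels", [(5, 30), (80, 255)])
def test_head_channel_count(nc, channels):
    cfg = nano_cfg(nc=nc)
    model = DetectionModel(cfg, variant="improved")
    for conv in model.head.convs:
        assert conv.out_channels == channels


def test_head_maps_match_neck_spatial_sizes():
    model = DetectionModel(nano_cfg(size=96), variant="improved").eval()
    out = model(Tensor(np.zeros((2, 3, 96, 96))))
    assert [o.shape[:2] for o in out] == [(2, 3)] * 3
    assert [o.shape[2] for o in out] == [12, 6, 3]
    assert all(o.shape[4] == 10 for o in out)


# -- accounting --------------------------------------------------------------

def closed_form_count(model):
    total = 0
    for m in model.modules():
        if isinstance(m, nn.Conv2d):
            total += m.out_channels * (m.in_channels // m.groups) * m.kernel ** 2
            if m.bias is not None:
                total += m.out_channels
        elif isinstance(m, nn.BatchNorm2d):
            total += 2 * m.num_features
    return total


def test_single_conv_plus_bn_closed_form(rng):
    blk = ConvBnAct(3, 16, 3, rng=rng)
    assert blk.num_parameters() == 3 * 3 * 3 * 16 + 2 * 16  # 432 + 32


def test_single_conv_flops_closed_form(rng):
    conv = nn.Conv2d(1, 1, 3, stride=1, padding=1, rng=rng)
    assert conv.flops(8, 8) == 2 * 9 * 64


def test_model_counts_equal_closed_form_sums():
    for variant in ("baseline", "improved"):
        model = DetectionModel(nano_cfg(), variant=variant)
        assert count_parameters(model) == closed_form_count(model)


def test_flops_equal_independent_layerwise_sum():
    """Analytic total equals an independent walk that propagates shapes and
    sums conv costs (attention terms added separately)."""
    model = DetectionModel(nano_cfg(size=96), variant="improved")
    size = 96

    def conv_cost(conv, h, w):
        ho = (h + 2 * conv.padding - conv.kernel) // conv.stride + 1
        wo = (w + 2 * conv.padding - conv.kernel) // conv.stride + 1
        return 2 * conv.kernel ** 2 * (conv.in_channels // conv.groups) \
            * conv.out_channels * ho * wo

    # backbone: sequential shape propagation
    h = w = size
    total = 0
    for layer in model.backbone.stem + \
            [l for s in model.backbone.stages for l in s]:
        total += layer.flops(h, w)
        h, w = layer.out_hw(h, w)
    neck_h = size // 8
    total += model.neck.flops(neck_h, neck_h)
    total += model.head.flops(neck_h, neck_h)
    assert total == count_flops(model, size)
    # cross-check one concrete piece against the raw conv formula
    stem0 = model.backbone.stem[0]
    assert stem0.flops(size, size) == conv_cost(stem0.conv, size, size)


def test_baseline_x_matches_published_convention():
    """The 80-class x-scale baseline lands on the standard printed counts
    (86.7 M parameters, 205.7 GFLOPs at 640) within rounding."""
    cfg = ModelConfig(num_classes=80, input_size=640, scale="x",
                      anchor_reference=640)
    model = DetectionModel(cfg, variant="baseline")
    params_m = count_parameters(model) / 1e6
    gflops = count_flops(model, 640) / 1e9
    assert abs(params_m - 86.7) / 86.7 < 0.01
    assert abs(gflops - 205.7) / 205.7 < 0.02


def test_forward_is_finite_batched_and_deterministic(rng):
    model = DetectionModel(nano_cfg(size=64), variant="improved", seed=3)
    model.eval()
    x = Tensor(rng.random((2, 3, 64, 64)))
    out1 = model(x)
    out2 = model(x)
    for a, b in zip(out1, out2):
        assert np.isfinite(a.data).all()
        np.testing.assert_array_equal(a.data, b.data)
    zero = model(Tensor(np.zeros((1, 3, 64, 64))))
    assert all(np.isfinite(o.data).all() for o in zero)


def test_config_yaml_round_trip(tmp_path):
    cfg = ModelConfig(num_classes=7, input_size=416, scale="m", n_cspnext=2)
    path = tmp_path / "model.yaml"
    cfg.to_yaml(path)
    back = ModelConfig.from_yaml(path)
    assert back == cfg


def test_summary_prints_totals():
    model = DetectionModel(nano_cfg(size=96), variant="improved")
    text = model_summary(model, 96)
    assert "total" in text and "GFLOPs" in text


def test_make_divisible_rounds_up_to_multiple():
    assert make_divisible(65) == 72
    assert make_divisible(16) == 16
    assert make_divisible(3) == 8
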