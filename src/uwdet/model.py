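"""Detector assembly: backbone + FPN/PAN neck + anchor-based heads.

Two variants share the neck-and-head plumbing:

* ``baseline`` — classic YOLOv5 (C3 backbone with a 6x6 stem conv, SPPF,
  FPN+PAN neck, three anchor-based 1x1 prediction heads);
* ``improved`` — the underwater variant: an RTMDet-style backbone (a stem of
  three 3x3 convs followed by four stages of stride-2 conv + CSPLayer, with
  SPPF inside stage 4) and a single BoT3 bottleneck-transformer block on the
  stride-16 neck branch feeding the medium detection head.

Compound scaling follows the YOLOv5 convention: a ``scale`` letter maps to a
(depth_multiple, width_multiple) pair applied to base widths
(64, 128, 256, 512, 1024) and base C3 depths.  Parameter and FLOP accounting
is analytic — each block reports its own cost and the model sums them along
the wiring — with FLOPs defined as 2 x multiply-accumulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .blocks import (BoT3, C3, Concat, ConfigurationError, ConvBnAct,
                     CSPLayer, MHSA, SPPF, Upsample)
from .tensor import Tensor, concatenate

__all__ = [
    "ModelConfig", "DetectionModel", "Backbone", "Neck", "Detect",
    "build_backbone", "build_neck", "build_head", "count_parameters",
    "count_flops", "model_summary", "SCALES", "DEFAULT_ANCHORS",
]

SCALES = {
    "n": (0.33, 0.25),
    "s": (0.33, 0.50),
    "m": (0.67, 0.75),
    "l": (1.00, 1.00),
    "x": (1.33, 1.25),
}

BASE_WIDTHS = (64, 128, 256, 512, 1024)
BASE_BACKBONE_DEPTHS = (3, 6, 9, 3)
BASE_NECK_DEPTH = 3

# canonical anchor priors (pixels at a 640 reference size), 3 per scale
DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),       # stride 8
    ((30, 61), (62, 45), (59, 119)),      # stride 16
    ((116, 90), (156, 198), (373, 326)),  # stride 32
)

STRIDES = (8, 16, 32)


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(math.ceil(x / divisor) * divisor))


@dataclass
class ModelConfig:
    """Declarative description of an assembled detector."""

    num_classes: int = 5
    input_size: int = 416
    scale: str = "x"
    anchors: tuple = DEFAULT_ANCHORS
    anchor_reference: int = 640   # size at which the anchor priors are stated
    n_cspnext: int = 1
    mhsa_heads: int = 4
    bot3_site: str = "medium"     # pyramid level carrying the BoT3 block
    depthwise_cspnext: bool = False

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if self.input_size % 32:
            raise ConfigurationError("input_size must be divisible by 32")
        if self.num_classes < 1:
            raise ConfigurationError("need at least one class")
        anchors = tuple(tuple(tuple(a) for a in level) for level in self.anchors)
        if len(anchors) != 3 or any(len(level) != 3 for level in anchors):
            raise ConfigurationError("anchors must be 3 scales x 3 (w, h) pairs")
        self.anchors = anchors
        if self.bot3_site != "medium":
            raise ConfigurationError("the BoT3 block lives on the medium head")

    # -- derived plans ------------------------------------------------------
    @property
    def depth_multiple(self) -> float:
        return SCALES[self.scale][0]

    @property
    def width_multiple(self) -> float:
        return SCALES[self.scale][1]

    def widths(self) -> tuple[int, ...]:
        return tuple(make_divisible(w * self.width_multiple) for w in BASE_WIDTHS)

    def depth(self, n: int) -> int:
        return max(round(n * self.depth_multiple), 1)

    def scaled_anchors(self) -> np.ndarray:
        """Anchor priors in pixels at ``input_size``, shape (3, 3, 2)."""
        ratio = self.input_size / self.anchor_reference
        return np.array(self.anchors, dtype=float) * ratio

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "num_classes": self.num_classes,
            "input_size": self.input_size,
            "scale": self.scale,
            "anchors": [[list(a) for a in level] for level in self.anchors],
            "anchor_reference": self.anchor_reference,
            "n_cspnext": self.n_cspnext,
            "mhsa_heads": self.mhsa_heads,
            "bot3_site": self.bot3_site,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


class Backbone(nn.Module):
    """Feature extractor emitting the stride-8/16/32 pyramid (P3, P4, P5)."""

    def __init__(self, cfg: ModelConfig, variant: str, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        w = cfg.widths()
        self.variant = variant
        self.out_channels = (w[2], w[3], w[4])
        if variant == "improved":
            # stem: three 3x3 convs, strides (2, 1, 1), half width then full
            half = make_divisible(w[0] / 2, 4)
            self.stem = [
                ConvBnAct(3, half, 3, 2, rng=rng),
                ConvBnAct(half, half, 3, 1, rng=rng),
                ConvBnAct(half, w[0], 3, 1, rng=rng),
            ]
            def stage(cin, cout, with_sppf=False):
                layers = [ConvBnAct(cin, cout, 3, 2, rng=rng)]
                if with_sppf:
                    layers.append(SPPF(cout, cout, rng=rng))
                layers.append(CSPLayer(cout, cout, n=cfg.n_cspnext,
                                       depthwise=cfg.depthwise_cspnext, rng=rng))
                return layers
            self.stages = [
                stage(w[0], w[1]),
                stage(w[1], w[2]),
                stage(w[2], w[3]),
                stage(w[3], w[4], with_sppf=True),
            ]
        elif variant == "baseline":
            d = [cfg.depth(n) for n in BASE_BACKBONE_DEPTHS]
            self.stem = [ConvBnAct(3, w[0], 6, 2, padding=2, rng=rng)]
            self.stages = [
                [ConvBnAct(w[0], w[1], 3, 2, rng=rng), C3(w[1], w[1], d[0], rng=rng)],
                [ConvBnAct(w[1], w[2], 3, 2, rng=rng), C3(w[2], w[2], d[1], rng=rng)],
                [ConvBnAct(w[2], w[3], 3, 2, rng=rng), C3(w[3], w[3], d[2], rng=rng)],
                [ConvBnAct(w[3], w[4], 3, 2, rng=rng), C3(w[4], w[4], d[3], rng=rng),
                 SPPF(w[4], w[4], rng=rng)],
            ]
        else:
            raise ConfigurationError(f"unknown variant {variant!r}")

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        for layer in self.stem:
            x = layer(x)
        feats = []
        for stage in self.stages:
            for layer in stage:
                x = layer(x)
            feats.append(x)
        return feats[1], feats[2], feats[3]  # strides 8, 16, 32

    def flops(self, h: int, w: int) -> int:
        total = 0
        for layer in self.stem + [l for s in self.stages for l in s]:
            total += layer.flops(h, w)
            h, w = layer.out_hw(h, w)
        return total


class Neck(nn.Module):
    """FPN top-down + PAN bottom-up fusion, optionally with one BoT3 block on
    the stride-16 branch (the medium detection head)."""

    def __init__(self, cfg: ModelConfig, in_channels: tuple[int, int, int],
                 with_bot3: bool = True, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        c3n, c4n, c5n = in_channels
        d = cfg.depth(BASE_NECK_DEPTH)
        self.lat5 = ConvBnAct(c5n, c4n, 1, rng=rng)
        self.up = Upsample()
        self.fuse4 = C3(2 * c4n, c4n, d, shortcut=False, rng=rng)
        self.lat4 = ConvBnAct(c4n, c3n, 1, rng=rng)
        self.fuse3 = C3(2 * c3n, c3n, d, shortcut=False, rng=rng)
        self.down3 = ConvBnAct(c3n, c3n, 3, 2, rng=rng)
        self.pan4 = C3(2 * c3n, c4n, d, shortcut=False, rng=rng)
        self.bot3 = (BoT3(c4n, c4n, n=1, heads=cfg.mhsa_heads, rng=rng)
                     if with_bot3 else None)
        self.down4 = ConvBnAct(c4n, c4n, 3, 2, rng=rng)
        self.pan5 = C3(2 * c4n, c5n, d, shortcut=False, rng=rng)
        self.out_channels = (c3n, c4n, c5n)

    def forward(self, p3: Tensor, p4: Tensor, p5: Tensor):
        t5 = self.lat5(p5)
        f4 = self.fuse4(concatenate([self.up(t5), p4], axis=1))
        t4 = self.lat4(f4)
        out3 = self.fuse3(concatenate([self.up(t4), p3], axis=1))
        m4 = self.pan4(concatenate([self.down3(out3), t4], axis=1))
        out4 = self.bot3(m4) if self.bot3 is not None else m4
        out5 = self.pan5(concatenate([self.down4(out4), t5], axis=1))
        return out3, out4, out5

    def flops(self, h3: int, w3: int) -> int:
        h4, w4, h5, w5 = h3 // 2, w3 // 2, h3 // 4, w3 // 4
        total = self.lat5.flops(h5, w5)
        total += self.fuse4.flops(h4, w4) + self.lat4.flops(h4, w4)
        total += self.fuse3.flops(h3, w3) + self.down3.flops(h3, w3)
        total += self.pan4.flops(h4, w4)
        if self.bot3 is not None:
            total += self.bot3.flops(h4, w4)
        total += self.down4.flops(h4, w4) + self.pan5.flops(h5, w5)
        return total


class Detect(nn.Module):
    """Anchor-based prediction heads: one 1x1 conv per pyramid level emitting
    ``n_anchors * (5 + num_classes)`` channels per cell."""

    def __init__(self, cfg: ModelConfig, in_channels: tuple[int, int, int],
                 rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        anchors = cfg.scaled_anchors()
        if anchors.shape != (3, 3, 2):
            raise ConfigurationError("expected 3 anchors per detection scale")
        self.num_classes = cfg.num_classes
        self.n_anchors = anchors.shape[1]
        self.no = 5 + cfg.num_classes
        self.anchors = anchors            # pixels at cfg.input_size
        self.strides = np.array(STRIDES)
        self.convs = [nn.Conv2d(c, self.n_anchors * self.no, 1, bias=True,
                                rng=rng)
                      for c in in_channels]
        # objectness prior: start detectors pessimistic so early training is
        # not swamped by false positives
        for conv in self.convs:
            b = conv.bias.data.reshape(self.n_anchors, self.no)
            b[:, 4] -= 5.0
            conv.bias.data = b.reshape(-1)

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        """Raw per-scale maps reshaped to (N, n_anchors, H, W, 5 + nc)."""
        out = []
        for conv, x in zip(self.convs, feats):
            n, _, h, w = x.shape
            y = conv(x).reshape(n, self.n_anchors, self.no, h, w)
            out.append(y.transpose(0, 1, 3, 4, 2))
        return out

    def flops(self, h3: int, w3: int) -> int:
        sizes = ((h3, w3), (h3 // 2, w3 // 2), (h3 // 4, w3 // 4))
        return sum(conv.flops(h, w) for conv, (h, w) in zip(self.convs, sizes))


class DetectionModel(nn.Module):
    """Assembled detector (backbone -> neck -> heads)."""

    def __init__(self, cfg: ModelConfig, variant: str = "improved",
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.variant = variant
        self.backbone = build_backbone(cfg, variant=variant, rng=rng)
        self.neck = build_neck(cfg, self.backbone,
                               with_bot3=(variant == "improved"), rng=rng)
        self.head = build_head(cfg, self.neck, rng=rng)

    def forward(self, images: Tensor) -> list[Tensor]:
        p3, p4, p5 = self.backbone(images)
        feats = self.neck(p3, p4, p5)
        out = self.head(list(feats))
        for level, y in zip(STRIDES, out):
            if not np.isfinite(y.data).all():
                raise FloatingPointError(
                    f"non-finite activations at the stride-{level} head")
        return out

    def flops(self, input_size: int | None = None) -> int:
        size = input_size or self.cfg.input_size
        if size % 32:
            raise ConfigurationError("input_size must be divisible by 32")
        total = self.backbone.flops(size, size)
        total += self.neck.flops(size // 8, size // 8)
        total += self.head.flops(size // 8, size // 8)
        return total


def build_backbone(cfg: ModelConfig, variant: str = "improved",
                   rng=None) -> Backbone:
    return Backbone(cfg, variant=variant, rng=rng)


def build_neck(cfg: ModelConfig, backbone: Backbone, with_bot3: bool = True,
               rng=None) -> Neck:
    return Neck(cfg, backbone.out_channels, with_bot3=with_bot3, rng=rng)


def build_head(cfg: ModelConfig, neck: Neck, rng=None) -> Detect:
    return Detect(cfg, neck.out_channels, rng=rng)


def count_parameters(model: nn.Module) -> int:
    """Total learnable scalars (conv weights/biases + batch-norm affine)."""
    return model.num_parameters()


def count_flops(model: DetectionModel, input_size: int | None = None) -> int:
    """Analytic FLOPs (2 x multiply-accumulates) at the given input size."""
    return model.flops(input_size)


def model_summary(model: DetectionModel, input_size: int | None = None) -> str:
    size = input_size or model.cfg.input_size
    rows = [("backbone", model.backbone.num_parameters(),
             model.backbone.flops(size, size)),
            ("neck", model.neck.num_parameters(),
             model.neck.flops(size // 8, size // 8)),
            ("head", model.head.num_parameters(),
             model.head.flops(size // 8, size // 8))]
    lines = [f"{model.variant} detector, scale={model.cfg.scale}, "
             f"classes={model.cfg.num_classes}, input={size}",
             f"{'part':<10}{'params':>14}{'GFLOPs':>10}"]
    for name, p, f in rows:
        lines.append(f"{name:<10}{p:>14,}{f / 1e9:>10.1f}")
    lines.append(f"{'total':<10}{count_parameters(model):>14,}"
                 f"{count_flops(model, size) / 1e9:>10.1f}")
    return "\n".join(lines)
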