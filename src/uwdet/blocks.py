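"""Architectural building blocks for the underwater detector.

Feature maps are autograd :class:`~uwdet.tensor.Tensor` objects of shape
``(N, C, H, W)``.  Two block families live here:

* the classic YOLOv5 units (``ConvBnAct``, ``Bottleneck``, ``C3``, ``SPPF``)
  used by the baseline model and by the neck of the improved one;
* the units of the improved detector: ``CSPNeXtBlock`` (3x3 conv followed by a
  dense large 5x5 conv, optional residual), ``ChannelAttention`` (global
  average pool -> 1x1 conv -> hard-sigmoid gate), ``CSPLayer`` (the CSP
  wrapper with n CSPNeXt blocks and channel attention that replaces C3 in the
  backbone), and the bottleneck-transformer units ``MHSA`` / ``BoT`` /
  ``BoT3`` whose spatial mixing is content-only multi-head self-attention
  (no positional encodings).

Every block reports its own FLOPs (2 x multiply-accumulates) through
``flops(h, w)`` so that whole-model accounting is a pure graph walk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .tensor import Tensor, concatenate

__all__ = [
    "ConfigurationError", "BlockConfig", "ConvBnAct", "Bottleneck", "C3",
    "SPPF", "CSPNeXtBlock", "ChannelAttention", "CSPLayer", "MHSA", "BoT",
    "BoT3", "Concat", "Upsample",
]


class ConfigurationError(ValueError):
    """A block was configured with shape-illegal or inconsistent settings."""


@dataclass
class BlockConfig:
    """Declarative description of a single block.

    ``add_flag`` switches the CSPNeXt residual sum, ``n_blocks`` is the number
    of CSPNeXt blocks inside a CSPLayer (default 1), ``heads`` the MHSA head
    count (default 4).
    """

    in_channels: int
    out_channels: int
    kernel: int = 1
    stride: int = 1
    add_flag: bool = False
    n_blocks: int = 1
    heads: int = 4

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ConfigurationError("kernel must be a positive odd integer")
        if self.stride < 1 or self.n_blocks < 1 or self.heads < 1:
            raise ConfigurationError("stride, n_blocks and heads must be >= 1")
        if self.add_flag and self.in_channels != self.out_channels:
            raise ConfigurationError(
                "residual add requires in_channels == out_channels")


def _rng(rng):
    return rng if rng is not None else np.random.default_rng(0)


class ConvBnAct(nn.Module):
    """Conv -> BatchNorm -> SiLU, the CBS unit used throughout the network."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 1,
                 stride: int = 1, groups: int = 1, act: bool = True,
                 padding: int | None = None, rng=None):
        super().__init__()
        if padding is None and kernel % 2 == 0:
            raise ConfigurationError(
                "even kernel needs an explicit padding for same-size arithmetic")
        self.conv = nn.Conv2d(in_channels, out_channels, kernel, stride=stride,
                              padding=kernel // 2 if padding is None else padding,
                              groups=groups, bias=False, rng=_rng(rng))
        self.bn = nn.BatchNorm2d(out_channels)
        self.act = act

    @classmethod
    def from_config(cls, cfg: BlockConfig, rng=None) -> "ConvBnAct":
        return cls(cfg.in_channels, cfg.out_channels, cfg.kernel, cfg.stride,
                   rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.conv.in_channels:
            raise ConfigurationError(
                f"expected {self.conv.in_channels} channels, got {x.shape[1]}")
        out = self.bn(self.conv(x))
        return out.silu() if self.act else out

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return self.conv.out_hw(h, w)

    def flops(self, h: int, w: int) -> int:
        return self.conv.flops(h, w)


class Bottleneck(nn.Module):
    """Classic YOLOv5 bottleneck: 1x1 then 3x3, optional residual sum."""

    def __init__(self, in_channels: int, out_channels: int,
                 shortcut: bool = True, expansion: float = 1.0, rng=None):
        super().__init__()
        rng = _rng(rng)
        hidden = int(out_channels * expansion)
        self.cv1 = ConvBnAct(in_channels, hidden, 1, rng=rng)
        self.cv2 = ConvBnAct(hidden, out_channels, 3, rng=rng)
        self.add = shortcut and in_channels == out_channels

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def out_hw(self, h: int, w: int):
        return h, w

    def flops(self, h: int, w: int) -> int:
        return self.cv1.flops(h, w) + self.cv2.flops(h, w)


class C3(nn.Module):
    """YOLOv5 CSP bottleneck with three 1x1 convs around n inner bottlenecks."""

    def __init__(self, in_channels: int, out_channels: int, n: int = 1,
                 shortcut: bool = True, expansion: float = 0.5, rng=None):
        super().__init__()
        rng = _rng(rng)
        hidden = int(out_channels * expansion)
        if hidden < 1:
            raise ConfigurationError("expansion yields empty hidden width")
        self.cv1 = ConvBnAct(in_channels, hidden, 1, rng=rng)
        self.cv2 = ConvBnAct(in_channels, hidden, 1, rng=rng)
        self.m = [Bottleneck(hidden, hidden, shortcut, 1.0, rng=rng)
                  for _ in range(n)]
        self.cv3 = ConvBnAct(2 * hidden, out_channels, 1, rng=rng)
        self.hidden = hidden

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        for block in self.m:
            y = block(y)
        return self.cv3(concatenate([y, self.cv2(x)], axis=1))

    def out_hw(self, h: int, w: int):
        return h, w

    def flops(self, h: int, w: int) -> int:
        total = self.cv1.flops(h, w) + self.cv2.flops(h, w) + self.cv3.flops(h, w)
        return total + sum(b.flops(h, w) for b in self.m)


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained k=5 max pools.

    Chaining equal-kernel stride-1 pools reproduces the parallel 5/9/13
    pooling of classic SPP at a fraction of the cost.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 5,
                 rng=None):
        super().__init__()
        rng = _rng(rng)
        hidden = in_channels // 2
        self.cv1 = ConvBnAct(in_channels, hidden, 1, rng=rng)
        self.cv2 = ConvBnAct(hidden * 4, out_channels, 1, rng=rng)
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        p1 = y.maxpool2d(self.kernel, stride=1, padding=self.kernel // 2)
        p2 = p1.maxpool2d(self.kernel, stride=1, padding=self.kernel // 2)
        p3 = p2.maxpool2d(self.kernel, stride=1, padding=self.kernel // 2)
        return self.cv2(concatenate([y, p1, p2, p3], axis=1))

    def out_hw(self, h: int, w: int):
        return h, w

    def flops(self, h: int, w: int) -> int:
        return self.cv1.flops(h, w) + self.cv2.flops(h, w)


class CSPNeXtBlock(nn.Module):
    """3x3 conv followed by a large 5x5 conv, with optional residual sum.

    The 5x5 convolution is dense by default (``depthwise=False``); a
    depth-wise variant is available behind the flag for experimentation.
    """

    def __init__(self, in_channels: int, out_channels: int, add: bool = True,
                 kernel: int = 5, depthwise: bool = False, rng=None):
        super().__init__()
        rng = _rng(rng)
        if add and in_channels != out_channels:
            raise ConfigurationError(
                "residual CSPNeXt block needs in_channels == out_channels")
        self.conv1 = ConvBnAct(in_channels, out_channels, 3, rng=rng)
        self.conv2 = ConvBnAct(out_channels, out_channels, kernel,
                               groups=out_channels if depthwise else 1, rng=rng)
        self.add = add

    @classmethod
    def from_config(cls, cfg: BlockConfig, rng=None) -> "CSPNeXtBlock":
        return cls(cfg.in_channels, cfg.out_channels, add=cfg.add_flag, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(self.conv1(x))
        return x + y if self.add else y

    def out_hw(self, h: int, w: int):
        return h, w

    def flops(self, h: int, w: int) -> int:
        return self.conv1.flops(h, w) + self.conv2.flops(h, w)


class ChannelAttention(nn.Module):
    """Squeeze-style channel gate: global average pool -> 1x1 conv ->
    hard-sigmoid -> channelwise rescale.  Never amplifies activations since
    the gate lies in [0, 1]."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.fc = nn.Conv2d(channels, channels, 1, bias=True, rng=_rng(rng))

    def forward(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3), keepdims=True)
        gate = self.fc(pooled).hardsigmoid()
        return x * gate

    def gate(self, x: Tensor) -> Tensor:
        """The per-channel multiplier, exposed for inspection."""
        return self.fc(x.mean(axis=(2, 3), keepdims=True)).hardsigmoid()

    def out_hw(self, h: int, w: int):
        return h, w

    def flops(self, h: int, w: int) -> int:
        return self.fc.flops(1, 1)


class CSPLayer(nn.Module):
    """CSP wrapper with n residual CSPNeXt blocks and channel attention.

    Replaces C3 in the backbone: two parallel 1x1 convs split the input into a
    processed branch and a shortcut branch, the concatenation passes through
    channel attention, and a final 1x1 conv fuses to ``out_channels``.
    """

    def __init__(self, in_channels: int, out_channels: int, n: int = 1,
                 expansion: float = 0.5, depthwise: bool = False, rng=None):
        super().__init__()
        rng = _rng(rng)
        hidden = int(out_channels * expansion)
        if hidden * 2 != int(out_channels * expansion * 2) or hidden < 1:
            raise ConfigurationError("hidden split must be a positive integer")
        if out_channels % 2 and expansion == 0.5:
            raise ConfigurationError(
                "odd out_channels cannot be split into two half-width branches")
        self.main = ConvBnAct(in_channels, hidden, 1, rng=rng)
        self.short = ConvBnAct(in_channels, hidden, 1, rng=rng)
        self.blocks = [CSPNeXtBlock(hidden, hidden, add=True,
                                    depthwise=depthwise, rng=rng)
                       for _ in range(n)]
        self.attn = ChannelAttention(2 * hidden, rng=rng)
        self.final = ConvBnAct(2 * hidden, out_channels, 1, rng=rng)
        self.hidden = hidden

    @classmethod
    def from_config(cls, cfg: BlockConfig, rng=None) -> "CSPLayer":
        return cls(cfg.in_channels, cfg.out_channels, n=cfg.n_blocks, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.main(x)
        for block in self.blocks:
            y = block(y)
        merged = concatenate([y, self.short(x)], axis=1)
        return self.final(self.attn(merged))

    def out_hw(self, h: int, w: int):
        return h, w

    def flops(self, h: int, w: int) -> int:
        total = (self.main.flops(h, w) + self.short.flops(h, w)
                 + self.attn.flops(h, w) + self.final.flops(h, w))
        return total + sum(b.flops(h, w) for b in self.blocks)


class MHSA(nn.Module):
    """Content-only multi-head self-attention over flattened spatial positions.

    Queries, keys and values come from learned 1x1 projections; attention
    logits are scaled by ``1/sqrt(d/heads)`` and softmax-normalized over
    positions.  No positional encodings of any kind are used, so attention
    depends purely on content.
    """

    def __init__(self, channels: int, heads: int = 4, rng=None):
        super().__init__()
        rng = _rng(rng)
        if channels % heads:
            raise ConfigurationError(
                f"heads ({heads}) must divide the embedding dim ({channels})")
        self.channels = channels
        self.heads = heads
        self.wq = nn.Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.wk = nn.Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.wv = nn.Conv2d(channels, channels, 1, bias=False, rng=rng)

    def _attention(self, x: Tensor) -> tuple[Tensor, Tensor]:
        n, c, h, w = x.shape
        dh, npos = c // self.heads, h * w
        q = self.wq(x).reshape(n, self.heads, dh, npos)
        k = self.wk(x).reshape(n, self.heads, dh, npos)
        v = self.wv(x).reshape(n, self.heads, dh, npos)
        scores = q.transpose(0, 1, 3, 2) @ k            # (n, heads, N, N)
        attn = (scores * (1.0 / np.sqrt(dh))).softmax(axis=-1)
        out = attn @ v.transpose(0, 1, 3, 2)            # (n, heads, N, dh)
        return attn, out.transpose(0, 1, 3, 2).reshape(n, c, h, w)

    def forward(self, x: Tensor) -> Tensor:
        return self._attention(x)[1]

    def attention_weights(self, x: Tensor) -> Tensor:
        """The (n, heads, HW, HW) softmax matrix; each row sums to 1."""
        return self._attention(x)[0]

    def out_hw(self, h: int, w: int):
        return h, w

    def flops(self, h: int, w: int) -> int:
        npos = h * w
        proj = 3 * 2 * self.channels * self.channels * npos
        scores_mix = 2 * 2 * npos * npos * self.channels  # qk^T and attn.v
        return proj + scores_mix


class BoT(nn.Module):
    """Bottleneck transformer: extraction conv -> MHSA -> expansion conv with
    an elementwise residual sum.  The spatial 3x3 convolution of a ResNet
    bottleneck is replaced by self-attention, cutting parameters."""

    def __init__(self, channels: int, heads: int = 4, rng=None):
        super().__init__()
        rng = _rng(rng)
        self.extract = ConvBnAct(channels, channels, 1, rng=rng)
        self.mhsa = MHSA(channels, heads=heads, rng=rng)
        self.expand = ConvBnAct(channels, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.extract.conv.in_channels:
            raise ConfigurationError("skip connection needs matching channels")
        return x + self.expand(self.mhsa(self.extract(x)))

    def out_hw(self, h: int, w: int):
        return h, w

    def flops(self, h: int, w: int) -> int:
        return (self.extract.flops(h, w) + self.mhsa.flops(h, w)
                + self.expand.flops(h, w))


class BoT3(nn.Module):
    """C3 topology with the inner convolution stack replaced by a BoT block.

    Preserves both spatial size and (configured) channel count, so it can be
    dropped onto any neck branch without reshaping its neighbours.
    """

    def __init__(self, in_channels: int, out_channels: int, n: int = 1,
                 heads: int = 4, expansion: float = 0.5, rng=None):
        super().__init__()
        rng = _rng(rng)
        hidden = int(out_channels * expansion)
        if hidden < 1 or (out_channels % 2 and expansion == 0.5):
            raise ConfigurationError("hidden split must be a positive integer")
        self.cv1 = ConvBnAct(in_channels, hidden, 1, rng=rng)
        self.cv2 = ConvBnAct(in_channels, hidden, 1, rng=rng)
        self.m = [BoT(hidden, heads=heads, rng=rng) for _ in range(n)]
        self.cv3 = ConvBnAct(2 * hidden, out_channels, 1, rng=rng)
        self.hidden = hidden

    @classmethod
    def from_config(cls, cfg: BlockConfig, rng=None) -> "BoT3":
        return cls(cfg.in_channels, cfg.out_channels, n=cfg.n_blocks,
                   heads=cfg.heads, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        for block in self.m:
            y = block(y)
        return self.cv3(concatenate([y, self.cv2(x)], axis=1))

    def out_hw(self, h: int, w: int):
        return h, w

    def flops(self, h: int, w: int) -> int:
        total = self.cv1.flops(h, w) + self.cv2.flops(h, w) + self.cv3.flops(h, w)
        return total + sum(b.flops(h, w) for b in self.m)


class Concat(nn.Module):
    """Channel concatenation node for the assembly graph."""

    def forward(self, xs: list[Tensor]) -> Tensor:
        return concatenate(xs, axis=1)

    def flops(self, h: int, w: int) -> int:
        return 0


class Upsample(nn.Module):
    """Nearest-neighbour 2x upsampling node."""

    def forward(self, x: Tensor) -> Tensor:
        return x.upsample_nearest2()

    def out_hw(self, h: int, w: int):
        return 2 * h, 2 * w

    def flops(self, h: int, w: int) -> int:
        return 0
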