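"""Layer primitives and an SGD optimizer on top of the autograd core."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Identity", "SGD"]


class Module:
    """Base class with recursive parameter discovery and train/eval switching.

    Child modules and parameters are found by attribute inspection, so
    subclasses simply assign them in ``__init__``.  Lists of modules are
    supported via plain Python lists.
    """

    def __init__(self):
        self.training = True

    # -- containers ---------------------------------------------------------
    def children(self):
        def walk(name, value):
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(f"{name}.{i}", item)

        for name, value in vars(self).items():
            yield from walk(name, value)

    def modules(self):
        """Yield self and every descendant module (pre-order)."""
        yield self
        for _, child in self.children():
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
        for name, child in self.children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- state I/O ----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}

        def collect(mod: Module, prefix: str):
            for name, value in vars(mod).items():
                if isinstance(value, Tensor):
                    state[f"{prefix}{name}"] = value.data.copy()
                elif isinstance(value, np.ndarray):
                    state[f"{prefix}{name}"] = value.copy()
            for name, child in mod.children():
                collect(child, f"{prefix}{name}.")

        collect(self, "")
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        def assign(mod: Module, prefix: str):
            for name, value in vars(mod).items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor) and key in state:
                    value.data = np.asarray(state[key], dtype=np.float64).reshape(
                        value.data.shape)
                elif isinstance(value, np.ndarray) and key in state:
                    setattr(mod, name, np.asarray(state[key], dtype=np.float64))
            for name, child in mod.children():
                assign(child, f"{prefix}{name}.")

        assign(self, "")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """2-D convolution, He-initialized, bias optional (off before batch norm)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None, groups: int = 1,
                 bias: bool = False, rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.groups = groups
        fan_in = in_channels // groups * kernel * kernel
        scale = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_channels, in_channels // groups,
                                    kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"Conv2d configured for {self.in_channels} input channels, "
                f"got {x.shape[1]}")
        out = x.conv2d(self.weight, stride=self.stride, padding=self.padding,
                       groups=self.groups)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.padding - self.kernel) // self.stride + 1,
                (w + 2 * self.padding - self.kernel) // self.stride + 1)

    def flops(self, h: int, w: int) -> int:
        """2 x multiply-accumulates at the given *input* spatial size."""
        ho, wo = self.out_hw(h, w)
        macs = (self.kernel ** 2 * (self.in_channels // self.groups)
                * self.out_channels * ho * wo)
        return 2 * macs


class BatchNorm2d(Module):
    """Batch normalization with affine transform and running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(num_features), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.size / self.num_features
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.ravel())
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            xhat = (x - mean) / ((var + self.eps) ** 0.5)
        else:
            mean = self.running_mean.reshape(1, -1, 1, 1)
            std = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mean)) * Tensor(1.0 / std)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


def calibrate_batchnorm(model: Module, forward_fn) -> None:
    """Reset running statistics to the exact activation statistics of one
    calibration pass (momentum forced to 1), as done after fast training on
    small datasets where exponentially averaged statistics lag the weights."""
    saved = []
    for m in model.modules():
        if isinstance(m, BatchNorm2d):
            saved.append((m, m.momentum))
            m.momentum = 1.0
    model.train()
    forward_fn()
    for m, mom in saved:
        m.momentum = mom


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.937,
                 weight_decay: float = 0.0005):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
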