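"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient and
the closure needed to propagate gradients to its parents.  The op set is the
one a convolutional detector needs — elementwise arithmetic, matmul, (strided,
padded) 2-D convolution, max pooling, nearest-neighbour upsampling, reductions,
reshaping/indexing, the activations used by the blocks, and a numerically
stable binary cross-entropy with logits.  Gradients flow through a single
topological sort per ``backward`` call.

All data is kept in float64 for numerical headroom; the models exercised here
are small enough that the extra width is free.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() needs a single-element tensor")
        return float(self.data.reshape(()))

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autograd engine ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be deep: stacked conv blocks)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            pending = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if pending:
                stack.append(node)
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad)
        else:
            self.grad = self.grad + grad

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = backward
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        counts = mask.sum(axis=axis, keepdims=True)
        shown = out_data if keepdims or axis is None else np.squeeze(out_data, axis=axis)
        if axis is None and not keepdims:
            shown = out_data.reshape(())
        out = Tensor(shown, parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g).reshape(out_data.shape)
            # split gradient evenly across tied maxima
            self._accumulate(mask * (g / counts))

        out._backward = backward
        return out

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        out = Tensor(out_data, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    def sqrt(self):
        return self**0.5

    def atan(self):
        out = Tensor(np.arctan(self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / (1.0 + self.data**2))

        out._backward = backward
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = backward
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 + self.data * (1.0 - s)))

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        inside = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * inside)

        out._backward = backward
        return out

    def hardsigmoid(self):
        """Piecewise-linear sigmoid gate clip(x/6 + 0.5, 0, 1)."""
        return (self * (1.0 / 6.0) + 0.5).clip(0.0, 1.0)

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def maximum(self, other):
        other = as_tensor(other)
        out = Tensor(np.maximum(self.data, other.data), parents=(self, other))
        take_self = self.data >= other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * take_self, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * ~take_self, other.data.shape))

        out._backward = backward
        return out

    def minimum(self, other):
        other = as_tensor(other)
        out = Tensor(np.minimum(self.data, other.data), parents=(self, other))
        take_self = self.data <= other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * take_self, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * ~take_self, other.data.shape))

        out._backward = backward
        return out

    # -- spatial ops (N, C, H, W) -------------------------------------------
    def conv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0,
               groups: int = 1):
        x, w = self.data, weight.data
        n, cin, h, wid = x.shape
        cout, cin_g, kh, kw = w.shape
        if cin != cin_g * groups:
            raise ValueError(
                f"conv2d channel mismatch: input has {cin}, weight expects "
                f"{cin_g * groups} (groups={groups})"
            )
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        ho = (h + 2 * padding - kh) // stride + 1
        wo = (wid + 2 * padding - kw) // stride + 1
        sN, sC, sH, sW = xp.strides
        windows = np.lib.stride_tricks.as_strided(
            xp,
            shape=(n, cin, ho, wo, kh, kw),
            strides=(sN, sC, sH * stride, sW * stride, sH, sW),
            writeable=False,
        )
        if groups == 1:
            out_data = np.einsum("nchwij,ocij->nohw", windows, w, optimize=True)
        else:
            cpg_in, cpg_out = cin // groups, cout // groups
            parts = []
            for gi in range(groups):
                parts.append(np.einsum(
                    "nchwij,ocij->nohw",
                    windows[:, gi * cpg_in:(gi + 1) * cpg_in],
                    w[gi * cpg_out:(gi + 1) * cpg_out],
                    optimize=True,
                ))
            out_data = np.concatenate(parts, axis=1)
        out = Tensor(out_data, parents=(self, weight))

        def backward(g):
            if groups != 1:
                cpg_in, cpg_out = cin // groups, cout // groups
                if weight.requires_grad:
                    gw = np.empty_like(w)
                    for gi in range(groups):
                        gw[gi * cpg_out:(gi + 1) * cpg_out] = np.einsum(
                            "nohw,nchwij->ocij",
                            g[:, gi * cpg_out:(gi + 1) * cpg_out],
                            windows[:, gi * cpg_in:(gi + 1) * cpg_in],
                            optimize=True,
                        )
                    weight._accumulate(gw)
                if self.requires_grad:
                    gxp = np.zeros_like(xp)
                    for gi in range(groups):
                        gs = g[:, gi * cpg_out:(gi + 1) * cpg_out]
                        ws = w[gi * cpg_out:(gi + 1) * cpg_out]
                        for i in range(kh):
                            for j in range(kw):
                                contrib = np.einsum("nohw,oc->nchw", gs, ws[:, :, i, j])
                                gxp[:, gi * cpg_in:(gi + 1) * cpg_in,
                                    i:i + ho * stride:stride,
                                    j:j + wo * stride:stride] += contrib
                    self._accumulate(
                        gxp[:, :, padding:padding + h, padding:padding + wid])
                return
            if weight.requires_grad:
                gw = np.einsum("nohw,nchwij->ocij", g, windows, optimize=True)
                weight._accumulate(gw)
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        contrib = np.einsum("nohw,oc->nchw", g, w[:, :, i, j],
                                            optimize=True)
                        gxp[:, :, i:i + ho * stride:stride,
                            j:j + wo * stride:stride] += contrib
                self._accumulate(gxp[:, :, padding:padding + h, padding:padding + wid])

        out._backward = backward
        return out

    def maxpool2d(self, kernel: int, stride: int = 1, padding: int = 0):
        x = self.data
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
        ho = (h + 2 * padding - kernel) // stride + 1
        wo = (w + 2 * padding - kernel) // stride + 1
        sN, sC, sH, sW = xp.strides
        windows = np.lib.stride_tricks.as_strided(
            xp,
            shape=(n, c, ho, wo, kernel, kernel),
            strides=(sN, sC, sH * stride, sW * stride, sH, sW),
            writeable=False,
        )
        out_data = windows.max(axis=(4, 5))
        out = Tensor(out_data, parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            mask = windows == out_data[..., None, None]
            counts = mask.sum(axis=(4, 5), keepdims=True)
            gwin = mask * (g[..., None, None] / counts)
            gxp = np.zeros_like(xp)
            for i in range(kernel):
                for j in range(kernel):
                    gxp[:, :, i:i + ho * stride:stride,
                        j:j + wo * stride:stride] += gwin[..., i, j]
            self._accumulate(gxp[:, :, padding:padding + h, padding:padding + w])

        out._backward = backward
        return out

    def upsample_nearest2(self):
        """Nearest-neighbour 2x upsampling on (N, C, H, W)."""
        out = Tensor(self.data.repeat(2, axis=2).repeat(2, axis=3), parents=(self,))
        n, c, h, w = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(
                    g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        out._backward = backward
        return out

    # -- losses -------------------------------------------------------------
    def bce_with_logits(self, target: np.ndarray):
        """Elementwise binary cross-entropy on logits (stable log1p form)."""
        x = self.data
        t = np.asarray(target, dtype=np.float64)
        loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
        out = Tensor(loss, parents=(self,))

        def backward(g):
            if self.requires_grad:
                s = 1.0 / (1.0 + np.exp(-x))
                self._accumulate(g * (s - t))

        out._backward = backward
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = backward
    return out
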