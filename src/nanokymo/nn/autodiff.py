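"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the kymograph network needs: broadcasting
elementwise arithmetic, (batched) matrix products, reductions, shape
manipulation, sliding-window patch extraction for convolutions, and the
stable nonlinearities (leaky ReLU, sigmoid, softplus).  Everything is
float64; gradient correctness is established by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "cat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    n_extra = grad.ndim - len(shape)
    if n_extra > 0:
        grad = grad.sum(axis=tuple(range(n_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor defers to us

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- elementwise arithmetic ---------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def sqrt(self):
        return self**0.5

    def exp(self):
        e = np.exp(self.data)  # captured locally: no self-referential cycle
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    # -- nonlinearities ------------------------------------------------
    def leaky_relu(self, slope: float = 0.1):
        mask = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def softplus(self):
        # log(1 + e^x), computed stably; gradient is sigmoid(x)
        out = Tensor(np.logaddexp(0.0, self.data), parents=(self,))
        out._backward = lambda g: self._accum(
            g / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        )
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - t**2))
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties share the gradient equally."""
        m = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == m).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = Tensor(out_data, parents=(self,))

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g * mask)

        out._backward = bwd
        return out

    # -- shape manipulation -------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out

    # -- linear algebra ------------------------------------------------
    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            a, b = self.data, other.data
            self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), self.shape))
            other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, other.shape))

        out._backward = bwd
        return out

    # -- convolution support -------------------------------------------
    def pad2d(self, ph: int, pw: int):
        """Zero-pad the last two axes symmetrically."""
        widths = [(0, 0)] * (self.ndim - 2) + [(ph, ph), (pw, pw)]
        out = Tensor(np.pad(self.data, widths), parents=(self,))

        def bwd(g):
            sl = [slice(None)] * (self.ndim - 2)
            sl += [slice(ph, g.shape[-2] - ph), slice(pw, g.shape[-1] - pw)]
            self._accum(g[tuple(sl)])

        out._backward = bwd
        return out

    def unfold(self, kh: int, kw: int):
        """Extract all kh x kw patches from a (B, C, H, W) tensor.

        Returns (B, H-kh+1, W-kw+1, C*kh*kw); the backward pass
        scatter-adds overlapping patch gradients back.
        """
        b, c, h, w = self.shape
        win = np.lib.stride_tricks.sliding_window_view(self.data, (kh, kw), axis=(2, 3))
        # win: (B, C, Ho, Wo, kh, kw) -> (B, Ho, Wo, C*kh*kw)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho, wo, c * kh * kw)
        out = Tensor(cols, parents=(self,))

        def bwd(g):
            g6 = g.reshape(b, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            full = np.zeros((b, c, h, w))
            for u in range(kh):
                for v in range(kw):
                    full[:, :, u : u + ho, v : v + wo] += g6[:, :, :, :, u, v]
            self._accum(full)

        out._backward = bwd
        return out


def cat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along an axis, with gradient routing by slicing."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out._backward = bwd
    return out
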