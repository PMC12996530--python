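"""Neural-network building blocks used by the hierarchical vision transformer."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, cat

__all__ = [
    "Module",
    "Dense",
    "Conv2d",
    "MaxPool2d",
    "LayerNorm",
    "MultiHeadAttention",
    "TransformerBlock",
    "PatchEncoder",
    "softmax",
]


class Module:
    """Base class with recursive parameter collection (torch-style)."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.astype(np.float64)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, d_in, d_out, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    """Same-padded stride-1 2-D convolution on (B, C, H, W) tensors."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("odd kernel sizes only")
        self.kernel = kernel
        fan_in = c_in * kernel * kernel
        self.w = Tensor(
            _glorot(rng, fan_in, c_out, (fan_in, c_out)), requires_grad=True
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.c_out = c_out

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel
        p = k // 2
        cols = x.pad2d(p, p).unfold(k, k)       # (B, H, W, C*k*k)
        out = cols @ self.w + self.b            # (B, H, W, Cout)
        return out.transpose((0, 3, 1, 2))


class MaxPool2d(Module):
    """Non-overlapping 2x2 max pooling."""

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        y = x.reshape(b, c, h // 2, 2, w // 2, 2)
        y = y.transpose((0, 1, 2, 4, 3, 5)).reshape(b, c, h // 2, w // 2, 4)
        return y.max(axis=-1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps).sqrt() * self.gamma + self.beta


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.data.max(axis=axis, keepdims=True)  # constant shift, no grad
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadAttention(Module):
    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator):
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        self.wq = Dense(embed_dim, embed_dim, rng)
        self.wk = Dense(embed_dim, embed_dim, rng)
        self.wv = Dense(embed_dim, embed_dim, rng)
        self.wo = Dense(embed_dim, embed_dim, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, n, e = x.shape
        return x.reshape(b, n, self.n_heads, self.head_dim).transpose((0, 2, 1, 3))

    def __call__(self, x: Tensor) -> Tensor:
        b, n, e = x.shape
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(self.head_dim))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(b, n, e)
        return self.wo(out)


class TransformerBlock(Module):
    """Pre-norm transformer block: MHA and an MLP, each with a residual."""

    def __init__(self, embed_dim: int, n_heads: int, mlp_dim: int,
                 rng: np.random.Generator, leaky_slope: float = 0.1):
        self.norm1 = LayerNorm(embed_dim)
        self.attn = MultiHeadAttention(embed_dim, n_heads, rng)
        self.norm2 = LayerNorm(embed_dim)
        self.fc1 = Dense(embed_dim, mlp_dim, rng)
        self.fc2 = Dense(mlp_dim, embed_dim, rng)
        self.slope = leaky_slope

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).leaky_relu(self.slope))


class PatchEncoder(Module):
    """Project flattened patches to the embedding and add a learned
    positional embedding, one position per patch."""

    def __init__(self, n_patches: int, patch_dim: int, embed_dim: int,
                 rng: np.random.Generator):
        self.proj = Dense(patch_dim, embed_dim, rng)
        self.pos = Tensor(rng.normal(0.0, 0.02, size=(n_patches, embed_dim)),
                          requires_grad=True)

    def __call__(self, patches: Tensor) -> Tensor:
        return self.proj(patches) + self.pos


class Adam:
    """ADAM optimizer (Kingma & Ba) over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
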