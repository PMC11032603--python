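"""Neural-network building blocks on top of the autograd tensor.

Initialization follows the common fan-in uniform convention for linear and
convolutional weights, standard-normal embeddings, and identity affine
parameters for the normalization layers. All randomness flows through the
``numpy.random.Generator`` handed to each layer, so a model built from a
given seed is bit-reproducible.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d, embedding, softmax


class Module:
    """Minimal module base: parameter discovery, train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for attr, value in vars(self).items():
            name = f"{prefix}{attr}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def _submodules(self) -> Iterator["Module"]:
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self) -> "Module":
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update(self._buffers())
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = self._buffer_refs()
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = value.astype(params[name].data.dtype).copy()
            elif name in buffers:
                owner, attr = buffers[name]
                setattr(owner, attr, value.copy())
            else:
                raise KeyError(f"unexpected parameter {name}")

    # running statistics and other non-trainable arrays
    def _buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for (name, (owner, attr)) in self._buffer_refs(prefix).items():
            out[name] = getattr(owner, attr).copy()
        return out

    def _buffer_refs(self, prefix: str = "") -> dict[str, tuple["Module", str]]:
        out: dict[str, tuple[Module, str]] = {}
        for attr, value in vars(self).items():
            name = f"{prefix}{attr}"
            if isinstance(value, Module):
                out.update(value._buffer_refs(f"{name}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item._buffer_refs(f"{name}.{i}."))
            elif attr in getattr(self, "_buffer_names", ()):
                out[name] = (self, attr)
        return out


def _uniform(rng: np.random.Generator, shape, bound: float, dtype) -> Tensor:
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(dtype), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        bound = 1.0 / math.sqrt(d_in)
        self.weight = _uniform(rng, (d_in, d_out), bound, dtype)
        self.bias = _uniform(rng, (d_out,), bound, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.weight = Tensor(rng.standard_normal((n_tokens, dim)).astype(dtype), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding(self.weight, idx)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout fraction must be in [0,1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(x.dtype))


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=np.float32, eps: float = 1e-5):
        super().__init__()
        self.weight = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).pow(-0.5) * self.weight + self.bias


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention with a fused QKV projection.

    No key-padding mask is applied: the padding token carries its own
    learned embedding and participates in attention like any base.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        bound = 1.0 / math.sqrt(d_model)
        self.in_proj_weight = _uniform(rng, (d_model, 3 * d_model), bound, dtype)
        self.in_proj_bias = _uniform(rng, (3 * d_model,), bound, dtype)
        self.out_proj = Linear(d_model, d_model, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        b, l, d = x.shape
        qkv = x @ self.in_proj_weight + self.in_proj_bias  # (B, L, 3D)
        q, k, v = qkv[:, :, :d], qkv[:, :, d:2 * d], qkv[:, :, 2 * d:]
        def heads(t: Tensor) -> Tensor:
            return t.reshape(b, l, self.n_heads, self.d_head).transpose(0, 2, 1, 3)
        q, k, v = heads(q), heads(k), heads(v)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, l, d)
        return self.out_proj(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: Attn -> add&norm -> FF(ReLU) -> add&norm."""

    def __init__(self, d_model: int, n_heads: int, ff_dim: int, p_dropout: float,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng, dtype)
        self.ff1 = Linear(d_model, ff_dim, rng, dtype)
        self.ff2 = Linear(ff_dim, d_model, rng, dtype)
        self.norm1 = LayerNorm(d_model, dtype)
        self.norm2 = LayerNorm(d_model, dtype)
        self.drop = Dropout(p_dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x)))
        x = self.norm2(x + self.drop(self.ff2(self.drop(self.ff1(x).relu()))))
        return x


class Conv2d(Module):
    """Stride-1 "same" convolution, channels-last activations (N, H, W, C)."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd to preserve spatial shape")
        bound = 1.0 / math.sqrt(c_in * kernel_size * kernel_size)
        self.weight = _uniform(rng, (kernel_size, kernel_size, c_in, c_out), bound, dtype)
        self.bias = _uniform(rng, (c_out,), bound, dtype)
        self.padding = kernel_size // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization, channels-last (N, H, W, C).

    Batch statistics at train time (population variance), exponentially
    averaged running statistics at inference; momentum 0.1, eps 1e-5.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.weight = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[-1]
        if self.training:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 1, 2), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(c))
            xhat = centered * (var + self.eps).pow(-0.5)
        else:
            mu = Tensor(self.running_mean)
            sd = Tensor(1.0 / np.sqrt(self.running_var + self.eps))
            xhat = (x - mu) * sd
        return xhat * self.weight + self.bias
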