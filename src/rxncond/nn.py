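"""Neural-network layers and the AdamW optimizer on the autodiff core.

Transformer blocks use the pre-normalization arrangement (layer norm
before each sub-block, residual after), which trains stably without a
warmup-sensitive schedule at the small widths this package targets.
Attention layers return their softmax weight arrays so downstream
interpretability code can consume them directly.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32
NEG_INF = -1e9


class Module:
    """Base class with recursive parameter discovery by attribute path."""

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((name, value))
            elif isinstance(value, Module):
                out.extend((f"{name}.{k}", p) for k, p in value.named_parameters())
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(
                            (f"{name}.{i}.{k}", p) for k, p in item.named_parameters()
                        )
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        if strict and missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            if k in state:
                if p.data.shape != state[k].shape:
                    raise ValueError(
                        f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}"
                    )
                p.data = state[k].astype(p.data.dtype).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, scale: float = 0.02):
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(d_in, d_out)).astype(DTYPE), requires_grad=True
        )
        self.bias = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, scale: float = 0.02):
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(n, d)).astype(DTYPE), requires_grad=True
        )

    def __call__(self, ids: np.ndarray) -> Tensor:
        return ad.embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = ad.tmean(x, axis=-1, keepdims=True)
        centered = x - mu
        var = ad.tmean(ad.mul(centered, centered), axis=-1, keepdims=True)
        inv = ad.power(var + self.eps, -0.5)
        return ad.mul(centered, inv) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float):
        self.p = p

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        if not training or self.p <= 0.0:
            return x
        keep = (rng.random(x.shape) >= self.p).astype(x.data.dtype) / (1.0 - self.p)
        return ad.mul(x, keep)


class MultiHeadAttention(Module):
    """Scaled dot-product attention; returns (output, weights ndarray).

    Weights have shape (batch, heads, queries, keys); each row over
    admissible keys sums to 1.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("n_heads must divide d_model")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        return ad.transpose(
            ad.reshape(x, (b, t, self.n_heads, self.d_head)), (0, 2, 1, 3)
        )

    def __call__(
        self,
        query: Tensor,
        key: Tensor,
        value: Tensor,
        key_mask: Optional[np.ndarray] = None,
        causal: bool = False,
    ) -> tuple[Tensor, np.ndarray]:
        q, k, v = self._split(self.q_proj(query)), self._split(self.k_proj(key)), self._split(
            self.v_proj(value)
        )
        scores = ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))) * (
            1.0 / math.sqrt(self.d_head)
        )
        bias = np.zeros((1, 1, q.shape[2], k.shape[2]), dtype=DTYPE)
        if key_mask is not None:
            bias = bias + (1.0 - key_mask[:, None, None, :].astype(DTYPE)) * NEG_INF
        if causal:
            tri = np.triu(np.ones((q.shape[2], k.shape[2]), dtype=DTYPE), k=1)
            bias = bias + tri[None, None] * NEG_INF
        attn = ad.softmax(scores + bias, axis=-1)
        out = ad.matmul(attn, v)
        b, h, t, dh = out.shape
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (b, t, h * dh))
        return self.out_proj(out), attn.data


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_ff, rng)
        self.fc2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(ad.relu(self.fc1(x)))


class EncoderLayer(Module):
    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float, rng):
        self.norm1 = LayerNorm(d_model)
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.norm2 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.drop = Dropout(dropout)

    def __call__(self, x, key_mask, training, rng):
        h = self.norm1(x)
        attn_out, weights = self.attn(h, h, h, key_mask=key_mask)
        x = x + self.drop(attn_out, training, rng)
        x = x + self.drop(self.ff(self.norm2(x)), training, rng)
        return x, weights


class DecoderLayer(Module):
    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float, rng):
        self.norm1 = LayerNorm(d_model)
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.norm2 = LayerNorm(d_model)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.norm3 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.drop = Dropout(dropout)

    def __call__(self, x, memory, memory_mask, training, rng):
        h = self.norm1(x)
        sa, _ = self.self_attn(h, h, h, causal=True)
        x = x + self.drop(sa, training, rng)
        h = self.norm2(x)
        ca, cross_weights = self.cross_attn(h, memory, memory, key_mask=memory_mask)
        x = x + self.drop(ca, training, rng)
        x = x + self.drop(self.ff(self.norm3(x)), training, rng)
        return x, cross_weights


class AdamW:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / bc1
            v_hat = self.v[i] / bc2
            p.data = p.data - self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
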