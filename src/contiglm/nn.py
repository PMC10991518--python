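"""Transformer building blocks and an AdamW optimizer on the autograd engine.

Layers follow the post-layer-norm encoder convention (residual then
LayerNorm) with GELU feed-forward blocks and learned relative key-query
position embeddings: the attention score between positions i and j gains
two bias terms, q_i . r(i-j) and k_j . r(i-j), where r is a per-layer table
over clipped signed offsets.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import (Tensor, gelu, relative_attention_scores, softmax)


class Module:
    def parameters(self) -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield name, val
            elif isinstance(val, Module):
                for sub, p in val.parameters():
                    yield f"{name}.{sub}", p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters():
                            yield f"{name}.{i}.{sub}", p

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        scale = 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.uniform(-scale, scale, (d_in, d_out)).astype(dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float64):
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class RelativeSelfAttention(Module):
    """Multi-head self-attention with relative key-query position bias."""

    def __init__(self, hidden: int, n_heads: int, max_rel_distance: int,
                 rng: np.random.Generator, dtype=np.float64):
        if hidden % n_heads:
            raise ValueError("hidden size must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = hidden // n_heads
        self.max_rel_distance = max_rel_distance
        self.q_proj = Linear(hidden, hidden, rng, dtype)
        self.k_proj = Linear(hidden, hidden, rng, dtype)
        self.v_proj = Linear(hidden, hidden, rng, dtype)
        self.o_proj = Linear(hidden, hidden, rng, dtype)
        n_buckets = 2 * max_rel_distance - 1
        self.rel_emb = Tensor(
            (rng.standard_normal((n_buckets, self.head_dim)) * 0.02).astype(dtype),
            requires_grad=True)

    def _distance_index(self, L: int) -> np.ndarray:
        offs = np.arange(L)[:, None] - np.arange(L)[None, :]
        clipped = np.clip(offs, -(self.max_rel_distance - 1),
                          self.max_rel_distance - 1)
        return clipped + self.max_rel_distance - 1

    def __call__(self, x: Tensor, key_mask: np.ndarray,
                 return_attn: bool = False):
        """x: (B, L, hidden); key_mask: (B, L) bool, True = real token."""
        B, L, hidden = x.shape
        H, dh = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q_proj(x)), split(self.k_proj(x)), split(self.v_proj(x))
        scores = q @ k.transpose(0, 1, 3, 2)
        idx = self._distance_index(L)
        scores = scores + relative_attention_scores(q, self.rel_emb, idx, "q")
        scores = scores + relative_attention_scores(k, self.rel_emb, idx, "k")
        scores = scores * (1.0 / np.sqrt(dh))
        bias = np.where(key_mask[:, None, None, :], 0.0, -1e9)
        attn = softmax(scores + bias, axis=-1)
        ctx = attn @ v                                     # (B, H, L, dh)
        out = self.o_proj(ctx.transpose(0, 2, 1, 3).reshape(B, L, hidden))
        return (out, attn.data) if return_attn else (out, None)


class EncoderLayer(Module):
    def __init__(self, hidden: int, n_heads: int, ffn_dim: int,
                 max_rel_distance: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.attn = RelativeSelfAttention(hidden, n_heads, max_rel_distance, rng, dtype)
        self.ln1 = LayerNorm(hidden, dtype=dtype)
        self.ff1 = Linear(hidden, ffn_dim, rng, dtype)
        self.ff2 = Linear(ffn_dim, hidden, rng, dtype)
        self.ln2 = LayerNorm(hidden, dtype=dtype)

    def __call__(self, x: Tensor, key_mask: np.ndarray, return_attn: bool = False):
        a, attn = self.attn(x, key_mask, return_attn)
        x = self.ln1(x + a)
        x = self.ln2(x + self.ff2(gelu(self.ff1(x))))
        return x, attn


class AdamW:
    """Adam with decoupled weight decay (no decay on biases/LayerNorm gains)."""

    def __init__(self, params: list[tuple[str, Tensor]], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for _, p in params]
        self.v = [np.zeros_like(p.data) for _, p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, (name, p) in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and p.data.ndim > 1:
                p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.grad = None
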