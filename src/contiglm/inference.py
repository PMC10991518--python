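"""Contextualized embeddings, masked-context embeddings, attention maps and
pooled contig embeddings from a trained network.

The contextualized embedding of a gene is the hidden state at its position
(default: last encoder layer; layer 0 is the projected input).  Masked-
context embeddings are the hidden states at positions whose token was
replaced by the mask value, so they carry only information propagated from
the genomic context.  Attention maps are per-layer/head row-stochastic
matrices over real (unpadded) positions, optionally symmetrized as
S = (A + A^T)/2, which preserves total attention mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .corpus import SubContig, unmasked_batch
from .model import GLMModule


@dataclass
class ContextualOutput:
    """Per-layer hidden states and attention matrices for one contig."""

    hidden_states: np.ndarray   # (n_layers+1, L, hidden); [0] = projected input
    attentions: np.ndarray      # (n_layers, n_heads, L, L), row-stochastic


@dataclass
class SymmetrizedAttention:
    """Per-layer/head symmetric attention matrices for one contig."""

    matrices: np.ndarray        # (n_layers, n_heads, L, L)
    symmetrized: bool

    @property
    def n_heads_total(self) -> int:
        return self.matrices.shape[0] * self.matrices.shape[1]

    def adjacent_pair_features(self) -> np.ndarray:
        """(L-1, n_layers*n_heads) attention value at each (i, i+1) entry."""
        nl, nh, L, _ = self.matrices.shape
        idx = np.arange(L - 1)
        feats = self.matrices[:, :, idx, idx + 1]     # (nl, nh, L-1)
        return feats.reshape(nl * nh, L - 1).T


def run_contig(module: GLMModule, contig: SubContig,
               mask_positions: tuple[int, ...] = ()) -> ContextualOutput:
    """Single-contig forward pass collecting all layers and attentions."""
    batch = unmasked_batch([contig])
    for i in mask_positions:
        batch.tokens[0, i] = module.config.mask_value
    with ag.no_grad():
        _, hiddens, attns = module.encode(batch.tokens, batch.attention_mask,
                                          collect_hidden=True,
                                          collect_attn=True)
    L = len(contig)
    hs = np.stack([h[0, :L] for h in hiddens])
    at = np.stack([a[0][:, :L, :L] for a in attns])
    return ContextualOutput(hs, at)


def contextual_embeddings(module: GLMModule, contig: SubContig,
                          layer: int = -1) -> np.ndarray:
    """(L, hidden) per-gene contextualized embeddings from ``layer``
    (default last; 0 gives the projected inputs, pre-encoder)."""
    out = run_contig(module, contig)
    n = out.hidden_states.shape[0]
    if not -n <= layer < n:
        raise IndexError(f"layer {layer} out of range for {n} hidden stacks")
    return out.hidden_states[layer]


def masked_context_embeddings(module: GLMModule, contig: SubContig,
                              positions: list[int], layer: int = -1
                              ) -> np.ndarray:
    """Hidden states at masked positions: context-only representations with
    no propagation from the query gene's own embedding."""
    L = len(contig)
    for p in positions:
        if not 0 <= p < L:
            raise IndexError(f"position {p} out of range")
    if len(set(positions)) == L:
        warnings.warn("all positions masked: embeddings are context-free")
    out = run_contig(module, contig, mask_positions=tuple(positions))
    return out.hidden_states[layer][np.array(positions, dtype=int)]


def attention_maps(module: GLMModule, contig: SubContig,
                   symmetrize: bool = True) -> SymmetrizedAttention:
    """Attention matrices from an unmasked pass over one contig; padded
    rows/columns are already dropped."""
    out = run_contig(module, contig)
    mats = out.attentions
    if symmetrize:
        mats = 0.5 * (mats + np.swapaxes(mats, -1, -2))
    return SymmetrizedAttention(mats, symmetrize)


def contig_embedding(module: GLMModule, contig: SubContig,
                     mode: str = "contextualized") -> np.ndarray:
    """Mean-pooled contig embedding: over the last hidden layer
    (``contextualized``) or over the raw input embeddings (``context_free``)."""
    if len(contig) == 0:
        raise ValueError("empty contig")
    if mode == "context_free":
        return np.stack([g.embedding for g in contig.genes]).mean(axis=0)
    if mode == "contextualized":
        return contextual_embeddings(module, contig, layer=-1).mean(axis=0)
    raise ValueError(f"unknown mode {mode!r}")
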