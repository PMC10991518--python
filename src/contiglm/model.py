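"""The genomic language model: a transformer encoder over gene tokens with a
multi-prediction likelihood head.

Each input token is a gene's (normalized, clipped) protein embedding with an
orientation flag appended (E+1 features).  A learned affine map takes tokens
into the hidden size; a stack of post-LN encoder layers with relative
key-query position embeddings contextualizes them; one affine head projects
each position's final hidden state into ``n_pred`` candidate label vectors
plus ``n_pred`` likelihood logits.  Because more than one gene can
legitimately occupy a genomic niche, the training loss scores only the
candidate closest (L2) to the label and teaches the likelihood head to
point at that candidate:

    total = MSE(closest prediction, label) + alpha * CE(likelihood logits, closest index)
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .corpus import MASK_VALUE, MaskedBatch
from .nn import AdamW, EncoderLayer, Linear, Module  # noqa: F401  (AdamW re-export)


@dataclass(frozen=True)
class GLMConfig:
    """Architecture hyper-parameters.

    ``full_scale()`` gives the full-size configuration (19 layers, hidden
    1280, 10 heads, 4 predictions, 1281-feature inputs, 100-feature labels);
    ``desk_scale()`` the small CPU configuration used throughout the tests.
    """

    n_layers: int = 4
    hidden: int = 128
    n_heads: int = 4
    n_pred: int = 4
    input_dim: int | None = None     # E + 1, filled in from data
    label_dim: int | None = None     # k_pc + 1, filled in from data
    ffn_mult: int = 4
    max_rel_distance: int = 30
    mask_value: float = MASK_VALUE
    alpha: float = 1e-4
    dropout: float = 0.0

    def __post_init__(self):
        if self.hidden % self.n_heads:
            raise ValueError("hidden must be divisible by n_heads")
        if self.n_pred < 1:
            raise ValueError("n_pred must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    @property
    def total_heads(self) -> int:
        return self.n_layers * self.n_heads

    @property
    def head_width(self) -> int:
        if self.label_dim is None:
            raise ValueError("label_dim not set")
        return self.n_pred * self.label_dim + self.n_pred

    @classmethod
    def full_scale(cls) -> "GLMConfig":
        return cls(n_layers=19, hidden=1280, n_heads=10, n_pred=4,
                   input_dim=1281, label_dim=100, max_rel_distance=30,
                   alpha=1e-4)

    @classmethod
    def desk_scale(cls, input_dim: int | None = None,
                   label_dim: int | None = None) -> "GLMConfig":
        return cls(n_layers=4, hidden=128, n_heads=4, n_pred=4,
                   input_dim=input_dim, label_dim=label_dim,
                   max_rel_distance=30, alpha=1e-4)

    def resolved(self, input_dim: int, label_dim: int) -> "GLMConfig":
        return replace(self, input_dim=self.input_dim or input_dim,
                       label_dim=self.label_dim or label_dim)


@dataclass
class PredictionSet:
    """Model output at masked positions: ``n_pred`` candidate label vectors
    and a likelihood simplex per position."""

    positions: list[tuple[int, int]]           # (batch, position)
    predictions: np.ndarray                    # (P, n_pred, label_dim)
    likelihood_logits: np.ndarray              # (P, n_pred)

    @property
    def likelihoods(self) -> np.ndarray:
        z = self.likelihood_logits - self.likelihood_logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    @property
    def top_prediction(self) -> np.ndarray:
        """Highest-likelihood candidate per position, (P, label_dim)."""
        idx = self.likelihood_logits.argmax(axis=-1)
        return self.predictions[np.arange(len(idx)), idx]

    @property
    def top_likelihood(self) -> np.ndarray:
        return self.likelihoods.max(axis=-1)


@dataclass
class LossBreakdown:
    mse_term: float
    ce_term: float
    total: float
    alpha: float
    closest_indices: np.ndarray

    def __post_init__(self):
        if np.isfinite(self.total):
            assert abs(self.total -
                       (self.mse_term + self.alpha * self.ce_term)) < 1e-9


class GLMModule(Module):
    """The network itself (parameters + forward pass on the autograd engine)."""

    def __init__(self, config: GLMConfig, seed: int, dtype=np.float64):
        if config.input_dim is None or config.label_dim is None:
            raise ValueError("config.input_dim and label_dim must be set")
        self.config = config
        rng = np.random.default_rng(seed)
        self.input_proj = Linear(config.input_dim, config.hidden, rng, dtype)
        self.layers = [EncoderLayer(config.hidden, config.n_heads,
                                    config.ffn_mult * config.hidden,
                                    config.max_rel_distance, rng, dtype)
                       for _ in range(config.n_layers)]
        self.head = Linear(config.hidden, config.head_width, rng, dtype)

    def encode(self, tokens: np.ndarray, key_mask: np.ndarray,
               collect_hidden: bool = False, collect_attn: bool = False):
        """Returns (final_hidden Tensor (B,L,hidden), hiddens, attns).

        ``hiddens[0]`` is the projected input (pre-encoder); ``hiddens[k]``
        the output of layer k.  ``attns[k]`` is (B, n_heads, L, L).
        """
        h = self.input_proj(Tensor(tokens))
        hiddens = [h.data] if collect_hidden else None
        attns = [] if collect_attn else None
        for layer in self.layers:
            h, attn = layer(h, key_mask, return_attn=collect_attn)
            if collect_hidden:
                hiddens.append(h.data)
            if collect_attn:
                attns.append(attn)
        return h, hiddens, attns

    def head_at(self, h: Tensor, positions: Sequence[tuple[int, int]]) -> Tensor:
        b = np.array([p[0] for p in positions])
        i = np.array([p[1] for p in positions])
        return self.head(h[(b, i)])

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.parameters():
            p.data = state[name].copy()


def init_model(config: GLMConfig, seed: int, dtype=np.float64) -> GLMModule:
    return GLMModule(config, seed, dtype)


def split_head_output(out: np.ndarray, n_pred: int, label_dim: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    preds = out[:, :n_pred * label_dim].reshape(-1, n_pred, label_dim)
    logits = out[:, n_pred * label_dim:]
    return preds, logits


def forward(module: GLMModule, batch: MaskedBatch, need_hidden: bool = False,
            need_attn: bool = False):
    """Run the model on a batch; returns a PredictionSet for the masked
    positions (empty if none) and, on request, the raw hidden/attention
    stacks.  Padding keys receive zero attention mass."""
    cfg = module.config
    if batch.tokens.shape[-1] != cfg.input_dim:
        raise ValueError(f"token width {batch.tokens.shape[-1]} != "
                         f"config.input_dim {cfg.input_dim}")
    with ag.no_grad():
        h, hiddens, attns = module.encode(batch.tokens, batch.attention_mask,
                                          collect_hidden=need_hidden,
                                          collect_attn=need_attn)
        if batch.masked_positions:
            out = module.head_at(h, batch.masked_positions).data
            preds, logits = split_head_output(out, cfg.n_pred, cfg.label_dim)
        else:
            preds = np.zeros((0, cfg.n_pred, cfg.label_dim))
            logits = np.zeros((0, cfg.n_pred))
    pset = PredictionSet(list(batch.masked_positions), preds, logits)
    extras = {}
    if need_hidden:
        extras["hidden_states"] = hiddens
    if need_attn:
        extras["attentions"] = attns
    return (pset, extras) if (need_hidden or need_attn) else pset


def closest_prediction_indices(predictions: np.ndarray,
                               labels: np.ndarray) -> np.ndarray:
    """Argmin over candidates of L2 distance to the label (ties -> lowest)."""
    d2 = ((predictions - labels[:, None, :]) ** 2).sum(axis=-1)
    return d2.argmin(axis=1)


def compute_loss(preds: PredictionSet, labels: np.ndarray,
                 alpha: float) -> LossBreakdown:
    """The training objective, computed from a PredictionSet.

    MSE is the mean over masked positions and label dimensions of the squared
    error of the closest candidate; CE is the mean cross-entropy of the
    likelihood logits against the closest-candidate index.
    """
    P, n_pred, label_dim = preds.predictions.shape
    if n_pred == 0:
        raise ValueError("n_pred must be >= 1")
    if not np.all(np.isfinite(preds.predictions)):
        raise FloatingPointError("non-finite predictions")
    labels = np.asarray(labels, dtype=np.float64)
    if labels.shape != (P, label_dim):
        raise ValueError("one label per masked position required")
    closest = closest_prediction_indices(preds.predictions, labels)
    chosen = preds.predictions[np.arange(P), closest]
    mse = float(((chosen - labels) ** 2).mean())
    logits = preds.likelihood_logits
    lse = np.log(np.exp(logits - logits.max(axis=1, keepdims=True))
                 .sum(axis=1)) + logits.max(axis=1)
    ce = float((lse - logits[np.arange(P), closest]).mean())
    return LossBreakdown(mse, ce, mse + alpha * ce, alpha, closest)


def loss_tensor(head_out: Tensor, labels: np.ndarray, n_pred: int,
                alpha: float) -> tuple[Tensor, LossBreakdown]:
    """Differentiable loss from raw head output at masked positions."""
    P = head_out.shape[0]
    label_dim = labels.shape[1]
    preds = head_out[:, :n_pred * label_dim].reshape(P, n_pred, label_dim)
    logits = head_out[:, n_pred * label_dim:]
    closest = closest_prediction_indices(preds.data, labels)
    rows = np.arange(P)
    chosen = preds[(rows, closest)]
    diff = chosen - Tensor(labels)
    mse = (diff * diff).mean()
    logp = ag.log_softmax(logits, axis=-1)
    ce = -(logp[(rows, closest)].mean())
    total = mse + alpha * ce
    bd = LossBreakdown(mse.item(), ce.item(), total.item(), alpha, closest)
    return total, bd
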