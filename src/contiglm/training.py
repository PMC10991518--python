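"""Training loop, evaluation metrics, and the Model/Results surface.

:class:`ContigLanguageModel` is built from a corpus (it splits off a
validation set, fits the embedding normalizer and the PCA-whitening label
projector on the training split only, and resolves the architecture
config); ``.fit()`` runs masked-language-model training and returns a
:class:`GLMResults` carrying the trained network, the loss history, the
validation metrics, and every inference/downstream entry point.

Metrics
-------
pseudo-accuracy
    A masked gene is correct when the selected prediction is strictly
    closer (L2, in full label space including orientation) to that gene's
    label than to any other gene label in the same sub-contig; ties count
    as incorrect.
absolute accuracy
    Same criterion against the label universe of a whole genome, each gene
    masked one at a time.  It can never exceed pseudo-accuracy on the same
    predictions because the universe contains each sub-contig's labels.
confidence
    Fraction of masked positions whose top likelihood exceeds a threshold
    (0.75 in the headline analysis), and the pseudo-accuracy restricted to
    them.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import (EmbeddingNormalizer, LabelProjector, MaskedBatch,
                     SubContig, contig_labels, fit_label_projector,
                     fit_normalizer, mask_batch, normalize_corpus)
from .model import (GLMConfig, GLMModule, PredictionSet, forward,
                    loss_tensor)
from .nn import AdamW

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    """Desk-scale training defaults (the full-scale run used batch 3000,
    5000 warm-up steps to a peak learning rate of 1e-4 with AdamW)."""

    batch_size: int = 32
    total_steps: int = 500
    warmup_steps: int = 50
    peak_lr: float = 1e-3
    weight_decay: float = 0.01
    mask_rate: float = 0.15
    grad_clip: float = 1.0
    eval_every: int = 100
    eval_contigs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.warmup_steps > self.total_steps:
            raise ValueError("warmup_steps must be <= total_steps")
        if self.peak_lr <= 0:
            raise ValueError("peak_lr must be > 0")

    def lr_at(self, step: int) -> float:
        """Linear warmup to peak_lr at ``warmup_steps``, constant after."""
        if step < self.warmup_steps:
            return self.peak_lr * (step + 1) / self.warmup_steps
        return self.peak_lr


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _select_predictions(preds: PredictionSet, labels: np.ndarray | None,
                        selection: str) -> np.ndarray:
    if selection == "top_likelihood":
        return preds.top_prediction
    if selection == "oracle_best":
        # diagnostic upper bound: candidate closest to the true label
        d2 = ((preds.predictions - labels[:, None, :]) ** 2).sum(-1)
        idx = d2.argmin(axis=1)
        return preds.predictions[np.arange(len(idx)), idx]
    raise ValueError(f"unknown selection {selection!r}")


def _correct_flags(preds: PredictionSet, batch: MaskedBatch,
                   proj: LabelProjector, selection: str) -> np.ndarray:
    """Per-masked-position correctness under the in-subcontig criterion."""
    labels_by_contig = [contig_labels(proj, c) for c in batch.contigs]
    true_labels = np.stack([labels_by_contig[b][i]
                            for b, i in preds.positions])
    chosen = _select_predictions(preds, true_labels, selection)
    flags = np.zeros(len(preds.positions), dtype=bool)
    for k, (b, i) in enumerate(preds.positions):
        lab = labels_by_contig[b]
        d = np.linalg.norm(lab - chosen[k], axis=1)
        others = np.delete(d, i)
        if np.any(np.all(np.isclose(lab, lab[i]), axis=1) &
                  (np.arange(len(lab)) != i)):
            warnings.warn(f"duplicate labels in contig {batch.contigs[b].contig_id}; "
                          "ties count as incorrect")
        flags[k] = d[i] < others.min()
    return flags


def pseudo_accuracy(preds: PredictionSet, batch: MaskedBatch,
                    proj: LabelProjector,
                    selection: str = "top_likelihood") -> float:
    if not preds.positions:
        raise ValueError("no masked positions")
    return float(_correct_flags(preds, batch, proj, selection).mean())


def confidence_report(preds: PredictionSet, batch: MaskedBatch,
                      proj: LabelProjector, tau: float = 0.75
                      ) -> tuple[float, float]:
    """(fraction of positions with top likelihood > tau, pseudo-accuracy
    restricted to those positions; nan when none qualify)."""
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must be in [0, 1)")
    flags = _correct_flags(preds, batch, proj, "top_likelihood")
    high = preds.top_likelihood > tau
    frac = float(high.mean())
    acc = float(flags[high].mean()) if high.any() else float("nan")
    return frac, acc


def absolute_accuracy(module: GLMModule, genome: Sequence[SubContig],
                      proj: LabelProjector, chunk: int = 64,
                      selection: str = "top_likelihood") -> float:
    """Mask every gene of the genome one at a time and score against the
    genome-wide label universe."""
    universe = np.concatenate([contig_labels(proj, c) for c in genome])
    if universe.size == 0:
        raise ValueError("empty label universe")
    offsets = np.cumsum([0] + [len(c) for c in genome])
    jobs = [(ci, i) for ci, c in enumerate(genome) for i in range(len(c))]
    n_correct = 0
    for s in range(0, len(jobs), chunk):
        part = jobs[s:s + chunk]
        contigs = [genome[ci] for ci, _ in part]
        L_max = max(len(c) for c in contigs)
        E1 = len(contigs[0].genes[0].token)
        tokens = np.zeros((len(part), L_max, E1))
        attn = np.zeros((len(part), L_max), dtype=bool)
        positions = []
        for b, ((ci, i), c) in enumerate(zip(part, contigs)):
            attn[b, :len(c)] = True
            for j, g in enumerate(c.genes):
                tokens[b, j] = g.token
            tokens[b, i] = module.config.mask_value
            positions.append((b, i))
        batch = MaskedBatch(tokens, attn, positions, np.zeros((0, 1)),
                            module.config.mask_value, contigs)
        preds = forward(module, batch)
        true_labels = np.stack([universe[offsets[ci] + i] for ci, i in part])
        chosen = _select_predictions(preds, true_labels, selection)
        for k, (ci, i) in enumerate(part):
            d = np.linalg.norm(universe - chosen[k], axis=1)
            gi = offsets[ci] + i
            n_correct += d[gi] < np.delete(d, gi).min()
    return n_correct / len(jobs)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(module: GLMModule, train_contigs: Sequence[SubContig],
          val_contigs: Sequence[SubContig], proj: LabelProjector,
          cfg: TrainConfig, verbose: bool = False
          ) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Masked-LM training; returns (best state dict by validation
    pseudo-accuracy, per-step history)."""
    if not train_contigs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(list(module.parameters()), lr=cfg.peak_lr,
                weight_decay=cfg.weight_decay)
    history: list[dict] = []
    best_acc, best_state = -1.0, module.state_dict()
    n_pred, alpha = module.config.n_pred, module.config.alpha
    for step in range(cfg.total_steps):
        idx = rng.choice(len(train_contigs), size=min(cfg.batch_size,
                                                      len(train_contigs)),
                         replace=False)
        batch = mask_batch([train_contigs[i] for i in idx], cfg.mask_rate,
                           proj, seed=int(rng.integers(2 ** 31)))
        h, _, _ = module.encode(batch.tokens, batch.attention_mask)
        out = module.head_at(h, batch.masked_positions)
        total, bd = loss_tensor(out, batch.labels, n_pred, alpha)
        if not np.isfinite(total.item()):
            raise RuntimeError(f"non-finite loss at step {step}: {bd}")
        opt.zero_grad()
        total.backward()
        if cfg.grad_clip:
            gnorm = np.sqrt(sum(float((p.grad ** 2).sum())
                                for _, p in opt.params if p.grad is not None))
            if gnorm > cfg.grad_clip:
                scale = cfg.grad_clip / gnorm
                for _, p in opt.params:
                    if p.grad is not None:
                        p.grad *= scale
        opt.lr = cfg.lr_at(step)
        opt.step()
        rec = {"step": step, "lr": opt.lr, "mse": bd.mse_term,
               "ce": bd.ce_term, "total": bd.total}
        if val_contigs and ((step + 1) % cfg.eval_every == 0
                            or step + 1 == cfg.total_steps):
            vsub = list(val_contigs)[:cfg.eval_contigs]
            vbatch = mask_batch(vsub, cfg.mask_rate, proj, seed=cfg.seed + 1)
            vpreds = forward(module, vbatch)
            vacc = pseudo_accuracy(vpreds, vbatch, proj)
            rec["val_pseudo_accuracy"] = vacc
            if vacc >= best_acc:
                best_acc, best_state = vacc, module.state_dict()
            if verbose:
                logger.info("step %d loss %.4f val pseudo-acc %.3f",
                            step, bd.total, vacc)
        history.append(rec)
    if not val_contigs:
        best_state = module.state_dict()
    return best_state, history


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class ContigLanguageModel:
    """Masked gene-level language model over sub-contigs.

    Construction splits the corpus into train/validation contigs, fits the
    per-feature normalizer and the PCA-whitening label projector on the
    training split only, and resolves the architecture configuration from
    the data (input width E+1, label width k_pc+1).
    """

    def __init__(self, contigs: Sequence[SubContig],
                 config: GLMConfig | None = None, k_pc: int = 16,
                 clip_bound: float = 10.0, val_fraction: float = 0.15,
                 split_seed: int = 0):
        if not contigs:
            raise ValueError("empty corpus")
        rng = np.random.default_rng(split_seed)
        order = rng.permutation(len(contigs))
        n_val = max(1, int(round(val_fraction * len(contigs)))) \
            if val_fraction > 0 else 0
        val_idx = set(order[:n_val].tolist())
        raw_train = [contigs[i] for i in range(len(contigs)) if i not in val_idx]
        raw_val = [contigs[i] for i in sorted(val_idx)]
        self.normalizer = fit_normalizer(
            (g for c in raw_train for g in c.genes), clip_bound)
        self.train_contigs = normalize_corpus(self.normalizer, raw_train)
        self.val_contigs = normalize_corpus(self.normalizer, raw_val)
        self.projector = fit_label_projector(
            (g for c in self.train_contigs for g in c.genes), k_pc)
        E1 = len(contigs[0].genes[0].token)
        self.config = (config or GLMConfig.desk_scale()).resolved(
            E1, self.projector.label_dim)

    @classmethod
    def from_corpus_dir(cls, path: str | Path, **kw) -> "ContigLanguageModel":
        from .corpus import read_corpus
        return cls(read_corpus(path), **kw)

    def fit(self, train_config: TrainConfig | None = None,
            init_seed: int = 0, verbose: bool = False) -> "GLMResults":
        cfg = train_config or TrainConfig()
        module = GLMModule(self.config, seed=init_seed)
        best_state, history = train(module, self.train_contigs,
                                    self.val_contigs, self.projector, cfg,
                                    verbose)
        module.load_state_dict(best_state)
        return GLMResults(self, module, history, cfg)

    def results_from_module(self, module: GLMModule) -> "GLMResults":
        """Wrap an existing (e.g. untrained) network in a Results object."""
        return GLMResults(self, module, [], None)

    def normalize(self, contigs: Sequence[SubContig]) -> list[SubContig]:
        return normalize_corpus(self.normalizer, contigs)


class GLMResults:
    """Fitted-model results: trained parameters, history, metrics, and the
    inference entry points (contextual embeddings, attention maps, pooled
    contig embeddings)."""

    def __init__(self, model: ContigLanguageModel, module: GLMModule,
                 history: list[dict], train_config: TrainConfig | None):
        self.model = model
        self.module = module
        self.history = history
        self.train_config = train_config

    # -- evaluation -------------------------------------------------------
    def predict(self, batch: MaskedBatch) -> PredictionSet:
        return forward(self.module, batch)

    def evaluate(self, contigs: Sequence[SubContig] | None = None,
                 mask_rate: float = 0.15, tau: float = 0.75,
                 seed: int = 0, normalized: bool = True) -> dict:
        contigs = list(contigs) if contigs is not None else self.model.val_contigs
        if not normalized:
            contigs = self.model.normalize(contigs)
        batch = mask_batch(contigs, mask_rate, self.model.projector, seed)
        preds = self.predict(batch)
        acc = pseudo_accuracy(preds, batch, self.model.projector)
        frac, hacc = confidence_report(preds, batch, self.model.projector, tau)
        return {"pseudo_accuracy": acc,
                "oracle_best_accuracy": pseudo_accuracy(
                    preds, batch, self.model.projector, "oracle_best"),
                "high_conf_fraction": frac, "high_conf_accuracy": hacc,
                "tau": tau, "n_masked": batch.n_masked}

    def absolute_accuracy(self, genome: Sequence[SubContig],
                          normalized: bool = True) -> float:
        genome = list(genome) if normalized else self.model.normalize(genome)
        return absolute_accuracy(self.module, genome, self.model.projector)

    # -- inference (delegates) -------------------------------------------
    def contextual_embeddings(self, contig, layer: int = -1,
                              normalized: bool = True):
        from .inference import contextual_embeddings
        contig = contig if normalized else self.model.normalize([contig])[0]
        return contextual_embeddings(self.module, contig, layer)

    def masked_context_embeddings(self, contig, positions, layer: int = -1,
                                  normalized: bool = True):
        from .inference import masked_context_embeddings
        contig = contig if normalized else self.model.normalize([contig])[0]
        return masked_context_embeddings(self.module, contig, positions, layer)

    def attention_maps(self, contig, symmetrize: bool = True,
                       normalized: bool = True):
        from .inference import attention_maps
        contig = contig if normalized else self.model.normalize([contig])[0]
        return attention_maps(self.module, contig, symmetrize)

    def contig_embedding(self, contig, mode: str = "contextualized",
                         normalized: bool = True):
        from .inference import contig_embedding
        contig = contig if normalized else self.model.normalize([contig])[0]
        return contig_embedding(self.module, contig, mode)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        cfg = self.module.config
        n_params = sum(p.data.size for _, p in self.module.parameters())
        lines = [
            "Contig language model results",
            "=" * 60,
            f"layers: {cfg.n_layers}   hidden: {cfg.hidden}   "
            f"heads/layer: {cfg.n_heads}   total heads: {cfg.total_heads}",
            f"predictions/position: {cfg.n_pred}   label dim: {cfg.label_dim}"
            f"   input dim: {cfg.input_dim}",
            f"parameters: {n_params:,}   alpha: {cfg.alpha}",
            f"label PCA explained variance: "
            f"{self.model.projector.explained_variance_ratio.sum():.3f}",
        ]
        if self.history:
            last = self.history[-1]
            lines.append(f"steps trained: {len(self.history)}   "
                         f"final loss: {last['total']:.5f} "
                         f"(mse {last['mse']:.5f}, ce {last['ce']:.4f})")
            vaccs = [h["val_pseudo_accuracy"] for h in self.history
                     if "val_pseudo_accuracy" in h]
            if vaccs:
                lines.append(f"best validation pseudo-accuracy: {max(vaccs):.4f}")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        proj, norm = self.model.projector, self.model.normalizer
        arrays = {f"param.{k}": v for k, v in self.module.state_dict().items()}
        arrays.update({
            "norm.means": norm.feature_means, "norm.stds": norm.feature_stds,
            "proj.mean": proj.pca_mean, "proj.components": proj.components,
            "proj.scales": proj.whitening_scales,
            "proj.evr": proj.explained_variance_ratio,
        })
        np.savez(path / "checkpoint.npz", **arrays)
        meta = {"version": CHECKPOINT_VERSION,
                "config": asdict(self.module.config),
                "clip_bound": norm.clip_bound,
                "history": self.history}
        (path / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "GLMResults":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        arrays = np.load(path / "checkpoint.npz")
        config = GLMConfig(**meta["config"])
        module = GLMModule(config, seed=0)
        module.load_state_dict({k[len("param."):]: arrays[k]
                                for k in arrays.files if k.startswith("param.")})
        model = ContigLanguageModel.__new__(ContigLanguageModel)
        model.normalizer = EmbeddingNormalizer(arrays["norm.means"],
                                               arrays["norm.stds"],
                                               meta["clip_bound"])
        model.projector = LabelProjector(arrays["proj.mean"],
                                         arrays["proj.components"],
                                         arrays["proj.scales"],
                                         arrays["proj.evr"])
        model.config = config
        model.train_contigs, model.val_contigs = [], []
        return cls(model, module, meta["history"], None)
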