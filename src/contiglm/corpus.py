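"""Gene-table corpus: containers, normalization, label construction, masking, IO.

A corpus is a list of sub-contigs, each an ordered run of genes.  Every gene
carries a fixed-length context-free protein embedding and an orientation
flag (+0.5 forward, -0.5 reverse); the model's input token is the embedding
concatenated with the orientation.  Training labels are the PCA-whitened
leading principal components of the normalized embedding, again concatenated
with orientation.

On disk a corpus is a directory holding ``index.jsonl`` (one contig per
line: ids, orientations, optional family/operon/class annotations) and
``embeddings.npz`` (one array per gene id).  A flat TSV reader is provided
for small fixtures.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

FORWARD = 0.5
REVERSE = -0.5
MASK_VALUE = -1.0


class CorpusFormatError(ValueError):
    """Malformed on-disk corpus (bad index line, missing embedding, ...)."""


@dataclass
class GeneRecord:
    """One gene: context-free embedding plus orientation and optional labels."""

    gene_id: str
    embedding: np.ndarray
    orientation: float
    family_id: str | None = None
    annotation: str | None = None
    class_label: str | None = None

    def __post_init__(self):
        self.embedding = np.asarray(self.embedding, dtype=np.float64)
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be +0.5 or -0.5, got {self.orientation}")
        if not np.all(np.isfinite(self.embedding)):
            raise ValueError(f"non-finite embedding for gene {self.gene_id}")

    @property
    def token(self) -> np.ndarray:
        """Model input token: embedding with orientation appended."""
        return np.concatenate([self.embedding, [self.orientation]])


@dataclass
class SubContig:
    """An ordered window of genes cut from a contig (the model's input unit)."""

    contig_id: str
    genes: list[GeneRecord]
    operon_pairs: np.ndarray | None = None   # bool, length L-1
    contig_class: str | None = None

    def __post_init__(self):
        if len(self.genes) < 2:
            raise ValueError(f"contig {self.contig_id} has fewer than 2 genes")
        if self.operon_pairs is not None:
            self.operon_pairs = np.asarray(self.operon_pairs, dtype=bool)
            if self.operon_pairs.shape != (len(self.genes) - 1,):
                raise ValueError(
                    f"contig {self.contig_id}: operon_pairs must have length L-1")

    def __len__(self) -> int:
        return len(self.genes)


class EmbeddingProvider(Protocol):
    """Pluggable source of context-free protein embeddings keyed by gene id."""

    def __call__(self, gene_id: str) -> np.ndarray: ...


class LookupEmbeddingProvider:
    """Embedding provider backed by an in-memory mapping."""

    def __init__(self, table: dict[str, np.ndarray]):
        self._table = table

    def __call__(self, gene_id: str) -> np.ndarray:
        return self._table[gene_id]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingNormalizer:
    """Per-feature z-scoring followed by clipping to [-clip_bound, clip_bound].

    Standard deviations are population s.d. (ddof=0); zero-variance features
    get their s.d. replaced by 1 so the normalized value is exactly 0.
    Because clipping follows the z-score, applying the transform twice is
    not a no-op; idempotence is deliberately not claimed.
    """

    feature_means: np.ndarray
    feature_stds: np.ndarray
    clip_bound: float

    def apply_array(self, emb: np.ndarray) -> np.ndarray:
        emb = np.asarray(emb, dtype=np.float64)
        if emb.shape[-1] != self.feature_means.shape[0]:
            raise ValueError(
                f"embedding width {emb.shape[-1]} != normalizer width "
                f"{self.feature_means.shape[0]}")
        z = (emb - self.feature_means) / self.feature_stds
        return np.clip(z, -self.clip_bound, self.clip_bound)


def fit_normalizer(genes: Iterable[GeneRecord], clip_bound: float = 10.0
                   ) -> EmbeddingNormalizer:
    embs = np.stack([g.embedding for g in genes])
    if embs.shape[0] < 2:
        raise ValueError("need at least 2 genes to fit a normalizer")
    means = embs.mean(axis=0)
    stds = embs.std(axis=0)            # population s.d.
    stds = np.where(stds == 0.0, 1.0, stds)
    return EmbeddingNormalizer(means, stds, float(clip_bound))


def apply_normalizer(norm: EmbeddingNormalizer, gene: GeneRecord) -> GeneRecord:
    return GeneRecord(gene.gene_id, norm.apply_array(gene.embedding),
                      gene.orientation, gene.family_id, gene.annotation,
                      gene.class_label)


def normalize_corpus(norm: EmbeddingNormalizer,
                     contigs: Sequence[SubContig]) -> list[SubContig]:
    return [SubContig(c.contig_id, [apply_normalizer(norm, g) for g in c.genes],
                      c.operon_pairs, c.contig_class) for c in contigs]


# ---------------------------------------------------------------------------
# Labels: PCA whitening + orientation
# ---------------------------------------------------------------------------

@dataclass
class LabelProjector:
    """PCA-whitening map from a normalized embedding to the training-label
    space.  The label is the k_pc whitened component scores concatenated with
    the orientation flag (label_dim = k_pc + 1; 99 + 1 at full scale).

    Component signs follow the convention that each component's
    largest-magnitude loading is positive, so refits are reproducible.
    """

    pca_mean: np.ndarray
    components: np.ndarray        # (k_pc, E), orthonormal rows
    whitening_scales: np.ndarray  # per-component score s.d. on the fit corpus
    explained_variance_ratio: np.ndarray

    @property
    def k_pc(self) -> int:
        return self.components.shape[0]

    @property
    def label_dim(self) -> int:
        return self.k_pc + 1

    def project(self, emb: np.ndarray) -> np.ndarray:
        emb = np.asarray(emb, dtype=np.float64)
        return (emb - self.pca_mean) @ self.components.T / self.whitening_scales


def fit_label_projector(genes: Iterable[GeneRecord], k_pc: int) -> LabelProjector:
    embs = np.stack([g.embedding for g in genes])
    n, E = embs.shape
    if k_pc >= E or k_pc >= n:
        raise ValueError(f"k_pc={k_pc} must be < embedding dim {E} and corpus size {n}")
    pca = PCA(n_components=k_pc, svd_solver="full")
    pca.fit(embs)
    comps = pca.components_.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(comps[np.arange(k_pc), np.abs(comps).argmax(axis=1)])
    comps *= flip[:, None]
    scales = np.sqrt(pca.explained_variance_)   # ddof=1 score s.d.
    return LabelProjector(pca.mean_.copy(), comps, scales,
                          pca.explained_variance_ratio_.copy())


def make_label(proj: LabelProjector, gene: GeneRecord) -> np.ndarray:
    return np.concatenate([proj.project(gene.embedding), [gene.orientation]])


# ---------------------------------------------------------------------------
# Masking & batch assembly
# ---------------------------------------------------------------------------

@dataclass
class MaskedBatch:
    """Padded token batch with masked positions and their training labels."""

    tokens: np.ndarray            # (B, L_max, E+1)
    attention_mask: np.ndarray    # (B, L_max) bool, True = real gene
    masked_positions: list[tuple[int, int]]
    labels: np.ndarray            # (n_masked, label_dim)
    mask_value: float = MASK_VALUE
    contigs: list[SubContig] = field(default_factory=list)

    @property
    def n_masked(self) -> int:
        return len(self.masked_positions)


def mask_batch(contigs: Sequence[SubContig], rate: float, proj: LabelProjector,
               seed: int) -> MaskedBatch:
    """Independently mask each gene with probability ``rate`` (at least one
    per contig; the whole contig's draw is redrawn if it selects none), set
    masked tokens to the mask value everywhere, and record labels from the
    unmasked records."""
    if not 0.0 < rate < 1.0:
        raise ValueError(f"mask rate must be in (0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    E1 = len(contigs[0].genes[0].token)
    L_max = max(len(c) for c in contigs)
    B = len(contigs)
    tokens = np.zeros((B, L_max, E1))
    attention_mask = np.zeros((B, L_max), dtype=bool)
    masked_positions: list[tuple[int, int]] = []
    labels: list[np.ndarray] = []
    for b, contig in enumerate(contigs):
        L = len(contig)
        attention_mask[b, :L] = True
        for i, g in enumerate(contig.genes):
            tokens[b, i] = g.token
        sel = rng.random(L) < rate
        while not sel.any():
            sel = rng.random(L) < rate
        for i in np.flatnonzero(sel):
            tokens[b, i] = MASK_VALUE
            masked_positions.append((b, int(i)))
            labels.append(make_label(proj, contig.genes[i]))
    return MaskedBatch(tokens, attention_mask, masked_positions,
                       np.stack(labels), MASK_VALUE, list(contigs))


def unmasked_batch(contigs: Sequence[SubContig]) -> MaskedBatch:
    """Padded batch with no masking (inference input)."""
    E1 = len(contigs[0].genes[0].token)
    L_max = max(len(c) for c in contigs)
    tokens = np.zeros((len(contigs), L_max, E1))
    attention_mask = np.zeros((len(contigs), L_max), dtype=bool)
    for b, contig in enumerate(contigs):
        attention_mask[b, :len(contig)] = True
        for i, g in enumerate(contig.genes):
            tokens[b, i] = g.token
    return MaskedBatch(tokens, attention_mask, [], np.zeros((0, 1)),
                       MASK_VALUE, list(contigs))


def contig_labels(proj: LabelProjector, contig: SubContig) -> np.ndarray:
    return np.stack([make_label(proj, g) for g in contig.genes])


# ---------------------------------------------------------------------------
# On-disk format
# ---------------------------------------------------------------------------

def write_corpus(contigs: Sequence[SubContig], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    with open(path / "index.jsonl", "w") as fh:
        for c in contigs:
            rec = {
                "contig_id": c.contig_id,
                "gene_ids": [g.gene_id for g in c.genes],
                "orientations": [g.orientation for g in c.genes],
                "family_ids": [g.family_id for g in c.genes],
                "annotations": [g.annotation for g in c.genes],
                "class_labels": [g.class_label for g in c.genes],
                "operon_pairs": (None if c.operon_pairs is None
                                 else [bool(x) for x in c.operon_pairs]),
                "contig_class": c.contig_class,
            }
            fh.write(json.dumps(rec) + "\n")
            for g in c.genes:
                arrays[g.gene_id] = g.embedding
    np.savez(path / "embeddings.npz", **arrays)


def read_corpus(path: str | Path) -> list[SubContig]:
    path = Path(path)
    index = path / "index.jsonl"
    blob = path / "embeddings.npz"
    if not index.exists():
        raise FileNotFoundError(index)
    if not blob.exists():
        raise CorpusFormatError(f"missing embedding container {blob}")
    try:
        arrays = np.load(blob)
    except Exception as exc:   # truncated/corrupt container
        raise CorpusFormatError(f"unreadable embedding container {blob}: {exc}")
    contigs: list[SubContig] = []
    with open(index) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(
                    f"{index}: malformed JSON on line {lineno}: {exc}")
            genes = []
            for i, gid in enumerate(rec["gene_ids"]):
                if gid not in arrays:
                    raise CorpusFormatError(
                        f"{index} line {lineno}: embedding for gene {gid} "
                        f"missing from {blob}")
                genes.append(GeneRecord(
                    gid, arrays[gid], rec["orientations"][i],
                    rec.get("family_ids", [None] * len(rec["gene_ids"]))[i],
                    rec.get("annotations", [None] * len(rec["gene_ids"]))[i],
                    rec.get("class_labels", [None] * len(rec["gene_ids"]))[i]))
            op = rec.get("operon_pairs")
            contigs.append(SubContig(rec["contig_id"], genes,
                                     None if op is None else np.asarray(op, bool),
                                     rec.get("contig_class")))
    if not contigs:
        warnings.warn(f"empty corpus at {path}")
        logger.warning("empty corpus at %s", path)
    return contigs


def read_corpus_tsv(path: str | Path) -> list[SubContig]:
    """Flat TSV fixture reader: columns contig_id, gene_id, orientation,
    family_id (or '-'), then the embedding features."""
    by_contig: dict[str, list[GeneRecord]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise CorpusFormatError(f"{path} line {lineno}: expected at "
                                        f"least 5 columns, got {len(parts)}")
            cid, gid, ori, fam = parts[:4]
            emb = np.array([float(x) for x in parts[4:]])
            by_contig.setdefault(cid, []).append(
                GeneRecord(gid, emb, float(ori), None if fam == "-" else fam))
    return [SubContig(cid, genes) for cid, genes in by_contig.items()]


def read_operon_pairs_tsv(path: str | Path,
                          contigs: Sequence[SubContig]) -> list[SubContig]:
    """Attach operon labels from a two-column TSV of operonic adjacent gene-id
    pairs (RegulonDB-style export); unlisted adjacencies are non-operonic."""
    operonic: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            a, b = line.split()[:2]
            operonic.add((a, b))
    out = []
    for c in contigs:
        flags = np.array([(c.genes[i].gene_id, c.genes[i + 1].gene_id) in operonic
                          for i in range(len(c) - 1)], dtype=bool)
        out.append(SubContig(c.contig_id, c.genes, flags, c.contig_class))
    return out
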