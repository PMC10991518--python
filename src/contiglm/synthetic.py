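"""Synthetic gene-table corpora with planted structure.

The generator emulates, at desk scale, the statistical structure the model
and its downstream analyses assume in real metagenomic data:

* gene families = points in embedding space (a catalog of centers) with
  isotropic within-family noise — stand-ins for protein-language-model
  embeddings of family representatives;
* operons = templates of >= 2 families instantiated as contiguous,
  co-oriented blocks (ground truth for the attention analyses);
* genomic context = first-order successor rules between background
  families; rules with two or more high-mass successors plant genuinely
  ambiguous contexts, which is what a multi-prediction head is for;
* interacting pairs = two reserved families planted only as a strict
  forward adjacency (ground truth for paralog matching);
* contig classes = distinct family-usage weights (taxonomy stand-in).

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import FORWARD, REVERSE, GeneRecord, SubContig


@dataclass(frozen=True)
class FamilyCatalog:
    """Embedding centers for gene families plus the within-family noise s.d."""

    centers: np.ndarray                  # (n_families, emb_dim)
    noise_scale: float
    group_of: dict[int, int] | None = None

    def __post_init__(self):
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.centers.ndim != 2 or self.centers.shape[1] < 2:
            raise ValueError("centers must be (n_families, emb_dim>=2)")

    @property
    def n_families(self) -> int:
        return self.centers.shape[0]

    @property
    def emb_dim(self) -> int:
        return self.centers.shape[1]

    def family_name(self, idx: int) -> str:
        return f"F{idx:04d}"


@dataclass(frozen=True)
class OperonTemplate:
    """Ordered families instantiated as one co-oriented block."""

    families: tuple[int, ...]
    insert_prob: float = 0.2

    def __post_init__(self):
        if len(self.families) < 2:
            raise ValueError("an operon template needs >= 2 families")
        if not 0.0 <= self.insert_prob <= 1.0:
            raise ValueError("insert_prob must be in [0, 1]")


@dataclass(frozen=True)
class ContextRule:
    """First-order context: distribution of the family following the trigger."""

    trigger_family: int
    successors: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self):
        if len(self.successors) != len(self.probs):
            raise ValueError("successors and probs must align")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("successor distribution must sum to 1")


@dataclass
class SyntheticCorpus:
    contigs: list[SubContig]
    operon_truth: list[np.ndarray]           # bool per adjacent pair
    contig_class: list[str | None]
    pair_truth: list[tuple[int, int]]
    seed: int
    catalog: FamilyCatalog = None

    def __post_init__(self):
        for c, t in zip(self.contigs, self.operon_truth):
            assert len(t) == len(c) - 1


def build_family_catalog(n_families: int, emb_dim: int, noise_scale: float,
                         seed: int, group_of: dict[int, int] | None = None
                         ) -> FamilyCatalog:
    """Centers drawn i.i.d. from the sphere of radius sqrt(emb_dim) (a fixed
    spherical distribution), so typical inter-center distance stays O(sqrt(E))
    regardless of the family count."""
    if n_families < 2 or emb_dim < 2:
        raise ValueError("need n_families >= 2 and emb_dim >= 2")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_families, emb_dim))
    centers = raw / np.linalg.norm(raw, axis=1, keepdims=True) * np.sqrt(emb_dim)
    return FamilyCatalog(centers, float(noise_scale), group_of)


def sample_interacting_pairs(catalog: FamilyCatalog, n_pairs: int,
                             seed: int) -> list[tuple[int, int]]:
    """Reserve ``2 * n_pairs`` disjoint families as interacting pairs; pass
    the result to :func:`sample_corpus`, which plants each pair exclusively
    as the strict forward adjacency (X immediately followed by Y)."""
    if 2 * n_pairs > catalog.n_families:
        raise ValueError("not enough families for the requested pairs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(catalog.n_families, size=2 * n_pairs, replace=False)
    return [(int(chosen[2 * i]), int(chosen[2 * i + 1])) for i in range(n_pairs)]


def sample_corpus(catalog: FamilyCatalog,
                  templates: list[OperonTemplate],
                  rules: list[ContextRule],
                  n_contigs: int,
                  len_range: tuple[int, int],
                  class_spec: dict[str, dict[int, float]] | None = None,
                  seed: int = 0,
                  pairs: list[tuple[int, int]] | None = None,
                  pair_insert_prob: float = 0.15,
                  background_families: list[int] | None = None,
                  ) -> SyntheticCorpus:
    """Sample a corpus of sub-contigs with planted structure.

    Contigs are built left to right.  At each open position an operon block
    may start (per-template Bernoulli(insert_prob), if it fits), a planted
    pair may be inserted, or a background gene is drawn — from the previous
    background gene's context rule when one exists, otherwise from the
    class's family-usage weights (uniform over the background pool by
    default).  Blocks are contiguous, share one orientation, and set the
    operon truth on their internal adjacencies; they never straddle contig
    boundaries.  Background orientations are Bernoulli(1/2).
    """
    lo, hi = len_range
    if lo < 2 or hi < lo:
        raise ValueError(f"invalid len_range {len_range}")
    for t in templates:
        if len(t.families) > hi:
            raise ValueError("template longer than max contig length")
    pairs = list(pairs or [])
    rng = np.random.default_rng(seed)
    rule_map = {r.trigger_family: r for r in rules}

    reserved = {f for t in templates for f in t.families}
    reserved |= {f for p in pairs for f in p}
    for p in pairs:
        for r in rules:
            if p[0] in r.successors or p[1] in r.successors:
                raise ValueError("pair families may not appear in context rules")
    pair_fams = {f for p in pairs for f in p}
    if background_families is None:
        background_families = [f for f in range(catalog.n_families)
                               if f not in reserved]
    elif pair_fams & set(background_families):
        raise ValueError("pair families may not be background families")
    if not background_families:
        raise ValueError("no background families left")

    class_names = sorted(class_spec) if class_spec else None

    contigs: list[SubContig] = []
    operon_truth: list[np.ndarray] = []
    classes: list[str | None] = []
    for ci in range(n_contigs):
        L = int(rng.integers(lo, hi + 1))
        cls = None
        weights = None
        if class_names:
            cls = class_names[int(rng.integers(len(class_names)))]
            spec = class_spec[cls]
            fams = sorted(spec)
            w = np.array([spec[f] for f in fams], dtype=float)
            weights = (fams, w / w.sum())
        fam_seq: list[int] = []
        ori_seq: list[float] = []
        op_flags = np.zeros(max(L - 1, 0), dtype=bool)
        prev_bg: int | None = None
        i = 0
        while i < L:
            placed = False
            for t in templates:
                if i + len(t.families) <= L and rng.random() < t.insert_prob:
                    ori = FORWARD if rng.random() < 0.5 else REVERSE
                    for j, f in enumerate(t.families):
                        fam_seq.append(f)
                        ori_seq.append(ori)
                        if j > 0:
                            op_flags[i + j - 1] = True
                    i += len(t.families)
                    prev_bg = None
                    placed = True
                    break
            if placed:
                continue
            if pairs and i + 2 <= L and rng.random() < pair_insert_prob:
                x, y = pairs[int(rng.integers(len(pairs)))]
                fam_seq.extend([x, y])
                ori_seq.extend([FORWARD, FORWARD])
                i += 2
                prev_bg = None
                continue
            if prev_bg is not None and prev_bg in rule_map:
                r = rule_map[prev_bg]
                f = int(np.asarray(r.successors)[
                    rng.choice(len(r.successors), p=np.asarray(r.probs))])
            elif weights is not None:
                fams, w = weights
                f = int(np.asarray(fams)[rng.choice(len(fams), p=w)])
            else:
                f = int(background_families[int(rng.integers(len(background_families)))])
            fam_seq.append(f)
            ori_seq.append(FORWARD if rng.random() < 0.5 else REVERSE)
            prev_bg = f
            i += 1
        genes = []
        for pos, (f, o) in enumerate(zip(fam_seq, ori_seq)):
            emb = catalog.centers[f]
            if catalog.noise_scale > 0:
                emb = emb + catalog.noise_scale * rng.standard_normal(catalog.emb_dim)
            genes.append(GeneRecord(f"c{ci:05d}_g{pos:02d}", emb, o,
                                    family_id=catalog.family_name(f)))
        contigs.append(SubContig(f"c{ci:05d}", genes, op_flags.copy(), cls))
        operon_truth.append(op_flags)
        classes.append(cls)
    return SyntheticCorpus(contigs, operon_truth, classes, pairs, seed, catalog)


def context_variance_corpus(catalog: FamilyCatalog, probe_family: int,
                            contexts: list[tuple[int, int]],
                            n_occurrences: int, seed: int) -> list[SubContig]:
    """Length-5 contigs placing the probe family mid-contig inside one of
    ``len(contexts)`` distinct flanking contexts (cycled), for the
    context-variance analyses.  Contexts are (left, right) family pairs; the
    outer positions repeat the flank so each context is unambiguous."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_occurrences):
        left, right = contexts[k % len(contexts)]
        fams = [left, left, probe_family, right, right]
        genes = []
        for pos, f in enumerate(fams):
            emb = catalog.centers[f]
            if catalog.noise_scale > 0:
                emb = emb + catalog.noise_scale * rng.standard_normal(catalog.emb_dim)
            genes.append(GeneRecord(f"v{probe_family}_{k:04d}_g{pos}", emb,
                                    FORWARD, family_id=catalog.family_name(f)))
        out.append(SubContig(f"v{probe_family}_{k:04d}", genes))
    return out
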