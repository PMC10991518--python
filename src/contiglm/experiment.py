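"""The desk-scale reference experiment: one fixed synthetic study design
exercising the model and every downstream analysis end to end on CPU.

The corpus plants, in 2,000 sub-contigs of 15-20 genes over a 30-family
catalog (32-dim embeddings, within-family noise s.d. 0.05):

* a deterministic successor chain over the ten background families
  (family i is always followed by i+1), with one ambiguous branch
  (family 9 is followed by family 0 or 5 with equal mass) to exercise the
  multi-prediction head;
* three operon templates — (10,11,12), (13,14,15,16), (17,18) — inserted
  as contiguous co-oriented blocks (operon ground truth);
* three interacting family pairs (20,21), (22,23), (24,25) planted only as
  strict forward adjacencies (paralog-matching ground truth).

The model is the 4-layer/128-hidden/4-head desk configuration with 4
predictions per masked position and 17-dim labels (16 whitened principal
components + orientation), trained for 400 AdamW steps at batch 32.
All randomness derives from one master seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import synthetic as syn
from .model import GLMConfig, GLMModule
from .synthetic import ContextRule, OperonTemplate, SyntheticCorpus
from .training import ContigLanguageModel, GLMResults, TrainConfig

N_FAMILIES = 30
EMB_DIM = 32
NOISE_SCALE = 0.05
N_CONTIGS = 2000
LEN_RANGE = (15, 20)
K_PC = 16
CHAIN_FAMILIES = list(range(10))
TEMPLATES = [OperonTemplate((10, 11, 12), 0.15),
             OperonTemplate((13, 14, 15, 16), 0.10),
             OperonTemplate((17, 18), 0.10)]
PAIRS = [(20, 21), (22, 23), (24, 25)]


def chain_rules() -> list[ContextRule]:
    rules = [ContextRule(i, (i + 1,), (1.0,)) for i in range(9)]
    rules.append(ContextRule(9, (0, 5), (0.5, 0.5)))
    return rules


def build_catalog(seed: int) -> syn.FamilyCatalog:
    return syn.build_family_catalog(N_FAMILIES, EMB_DIM, NOISE_SCALE, seed)


def structured_corpus(seed: int, n_contigs: int = N_CONTIGS) -> SyntheticCorpus:
    ss = np.random.SeedSequence(seed).spawn(2)
    cat = build_catalog(int(ss[0].generate_state(1)[0] % 2**31))
    return syn.sample_corpus(cat, TEMPLATES, chain_rules(), n_contigs,
                             LEN_RANGE, seed=int(ss[1].generate_state(1)[0] % 2**31),
                             pairs=PAIRS, background_families=CHAIN_FAMILIES)


def desk_train_config(seed: int, total_steps: int = 400) -> TrainConfig:
    return TrainConfig(batch_size=32, total_steps=total_steps,
                       warmup_steps=min(50, total_steps), peak_lr=1e-3,
                       eval_every=100, eval_contigs=150, seed=seed)


@dataclass
class DeskRun:
    corpus: SyntheticCorpus
    model: ContigLanguageModel
    results: GLMResults

    @property
    def untrained_results(self) -> GLMResults:
        module = GLMModule(self.model.config, seed=987)
        return self.model.results_from_module(module)


def run_desk_experiment(seed: int, total_steps: int = 400,
                        n_contigs: int = N_CONTIGS,
                        verbose: bool = False) -> DeskRun:
    """Generate the corpus, fit normalizer/projector, train the model."""
    corpus = structured_corpus(seed, n_contigs)
    config = dataclasses.replace(GLMConfig.desk_scale(), alpha=0.1)
    model = ContigLanguageModel(corpus.contigs, config, k_pc=K_PC,
                                val_fraction=0.1, split_seed=seed)
    results = model.fit(desk_train_config(seed, total_steps),
                        init_seed=seed, verbose=verbose)
    return DeskRun(corpus, model, results)


def operon_analysis(run: DeskRun, n_contigs: int = 120, perm: int = 300,
                    seed: int = 0, untrained: bool = False) -> dict:
    """Attention-based operon recovery on held-out contigs: the strongest
    head's Pearson correlation against a permutation null, and the
    all-heads logistic classifier's 5-fold average precision."""
    from . import downstream as ds
    res = run.untrained_results if untrained else run.results
    contigs = run.model.val_contigs[:n_contigs]
    attns = [res.attention_maps(c) for c in contigs]
    rho = ds.head_operon_correlation(attns, contigs)
    fm = ds.build_pair_features(attns, contigs)
    best = int(rho.rho.abs().idxmax())
    rng = np.random.default_rng(seed)
    x, y = fm.X[:, best], fm.y.astype(float)
    null = np.array([abs(np.corrcoef(x, rng.permutation(y))[0, 1])
                     for _ in range(perm)])
    clf = ds.train_operon_classifier(fm, k=5, seed=seed)
    return {"max_abs_rho": float(rho.rho.abs().max()),
            "best_layer": int(rho.loc[best, "layer"]),
            "best_head": int(rho.loc[best, "head"]),
            "perm_null_p99": float(np.quantile(null, 0.99)),
            "mean_ap": clf.mean_ap, "sd_ap": clf.sd_ap,
            "prevalence": clf.prevalence, "n_pairs": len(fm.y)}


def paralog_analysis(run: DeskRun, n_iter: int = 1000, seed: int = 0) -> dict:
    """Recover the planted interacting partners through masked-flank
    queries; compare against the standard-normal chance simulation."""
    from . import downstream as ds
    from .corpus import FORWARD, GeneRecord
    cat = run.corpus.catalog
    norm, proj = run.model.normalizer, run.model.projector
    cand = np.stack([
        np.concatenate([proj.project(norm.apply_array(cat.centers[f])),
                        [FORWARD]]) for f in range(cat.n_families)])
    matches, partners = 0, []
    for x, y in run.corpus.pair_truth:
        q = GeneRecord("query", norm.apply_array(cat.centers[x]), FORWARD)
        r = ds.paralog_match(run.results.module, q, cand, partner_idx=y)
        matches += r.correct_exact
        partners.append(y)
    null = ds.paralog_chance_simulation(cand, partners, n_iter=n_iter,
                                        seed=seed)
    return {"exact_matches": int(matches), "n_queries": len(partners),
            "chance_mean": float(null.mean()),
            "chance_p95": float(np.quantile(null, 0.95))}


def variance_analysis(run: DeskRun, n_occurrences: int = 120,
                      seed: int = 0) -> dict:
    """Context-variance of one probe family planted into 1, 2 or 4 distinct
    flanking contexts, plus the noise-free single-context degenerate case."""
    from . import downstream as ds
    from . import synthetic as syn
    cat = run.corpus.catalog
    fam = cat.family_name(12)
    out = {}
    for n_ctx, ctxs in [(1, [(0, 1)]), (2, [(0, 1), (2, 3)]),
                        (4, [(0, 1), (2, 3), (4, 5), (6, 7)])]:
        contigs = syn.context_variance_corpus(cat, 12, ctxs, n_occurrences,
                                              seed=seed + n_ctx)
        contigs = run.model.normalize(contigs)
        occ = ds.collect_occurrence_embeddings(run.results.module, contigs)
        rep = ds.context_variance({fam: occ[fam]}, n_samples=10,
                                  sample_size=100, seed=seed)
        out[n_ctx] = rep.variance[fam]
    cat0 = syn.FamilyCatalog(cat.centers, 0.0)
    contigs0 = run.model.normalize(
        syn.context_variance_corpus(cat0, 12, [(0, 1)], 110, seed=seed))
    occ0 = ds.collect_occurrence_embeddings(run.results.module, contigs0)
    rep0 = ds.context_variance({fam: occ0[fam]}, n_samples=10,
                               sample_size=100, seed=seed)
    out["noise_free_single_context"] = rep0.variance[fam]
    return out


def masked_probe_analysis(run: DeskRun, n_contigs: int = 160, layer: int = 2,
                          min_count: int = 4, seed: int = 0) -> dict:
    """Linear probe of the masked gene's family from the masked-position
    hidden state (context-only information).  Classes with fewer than
    ``min_count`` occurrences are dropped; the 70/30 split is stratified
    per class so every test class is seen in training."""
    from .downstream import linear_probe
    contigs = run.model.val_contigs[:n_contigs]
    feats, labs = [], []
    for c in contigs:
        i = len(c) // 2
        feats.append(run.results.masked_context_embeddings(c, [i], layer)[0])
        labs.append(c.genes[i].family_id)
    feats, labs = np.stack(feats), np.array(labs)
    vals, counts = np.unique(labs, return_counts=True)
    keep = np.isin(labs, vals[counts >= min_count])
    feats, labs = feats[keep], labs[keep]
    rng = np.random.default_rng(seed)
    tr_idx, te_idx = [], []
    for v in np.unique(labs):
        idx = rng.permutation(np.flatnonzero(labs == v))
        cut = max(1, int(round(0.7 * len(idx))))
        tr_idx.extend(idx[:cut])
        te_idx.extend(idx[cut:])
    tr_idx, te_idx = np.array(tr_idx), np.array(te_idx)
    res = linear_probe((feats[tr_idx], labs[tr_idx]),
                       (feats[te_idx], labs[te_idx]))
    return {"accuracy": res.accuracy,
            "chance": 1.0 / len(np.unique(labs)),
            "n_test": len(te_idx)}


def null_pseudo_accuracy(seed: int, n_contigs: int = 2000,
                         length: int = 20, mask_rate: float = 0.25) -> dict:
    """Pseudo-accuracy of an untrained network on an exchangeable corpus;
    the expectation is 1/L."""
    from .corpus import mask_batch
    from .model import forward
    from .training import _correct_flags
    corpus = exchangeable_corpus(seed, n_contigs, length)
    config = dataclasses.replace(GLMConfig.desk_scale(), alpha=0.1)
    model = ContigLanguageModel(corpus.contigs, config, k_pc=K_PC,
                                val_fraction=0.0)
    module = GLMModule(model.config, seed=seed)
    hits = total = 0
    for chunk in range(0, n_contigs, 500):
        batch = mask_batch(model.train_contigs[chunk:chunk + 500], mask_rate,
                           model.projector, seed=seed + chunk)
        flags = _correct_flags(forward(module, batch), batch,
                               model.projector, "top_likelihood")
        hits += int(flags.sum())
        total += len(flags)
    return {"accuracy": hits / total, "n_masked": total,
            "expected": 1.0 / length}


def exchangeable_corpus(seed: int, n_contigs: int = 1000,
                        length: int = 20) -> SyntheticCorpus:
    """No planted structure: families drawn i.i.d. uniformly, so every gene
    label is exchangeable within its contig (the null for pseudo-accuracy)."""
    ss = np.random.SeedSequence(seed).spawn(2)
    cat = build_catalog(int(ss[0].generate_state(1)[0] % 2**31))
    return syn.sample_corpus(cat, [], [], n_contigs, (length, length),
                             seed=int(ss[1].generate_state(1)[0] % 2**31))
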