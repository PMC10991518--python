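# contiglm

Masked language modelling of **gene-level tokens** on microbial contigs:
a transformer encoder that reads an ordered window of 15–30 genes — each
gene a fixed protein embedding plus an orientation flag — and learns to
reconstruct masked genes from their genomic context.  On top of the
trained encoder the package implements the full downstream toolkit used
to interrogate such models: attention-based operon prediction,
contextualized gene and contig embeddings, Gaussian KL-divergence
comparisons of embedding distributions, per-gene context-variance (a
proxy for horizontal-transfer propensity), linear probes of gene
function, paralog matching, and contig-level taxonomy classification.

It is aimed at computational (meta)genomics researchers who want a
self-contained, CPU-scale, fully tested implementation of this modelling
stack — including a synthetic-corpus generator with planted ground truth
(operon blocks, context rules, interacting gene pairs, contig classes)
for validating every analysis end to end.

## The model

A gene token is `[embedding (E features), orientation (±0.5)]`.  Labels
are the PCA-whitened top-`k_pc` principal-component scores of the
normalized embedding plus orientation.  With 15% of genes masked to the
constant −1 token, the encoder (relative key-query position embeddings,
post-LN layers) produces, per masked position, `n_pred = 4` candidate
label vectors and a likelihood simplex, trained with

    total = MSE(closest candidate, label) + α · CE(likelihoods, closest index)

so that multi-modal genomic niches can be represented instead of
averaged away.  A prediction is judged by *pseudo-accuracy*: correct if
it lands strictly closer to the masked gene's label than to any other
gene label in the sub-contig (expected value 1/L under exchangeable
labels).  See `docs/methods.md` for the complete account.

## Worked example

```python
from contiglm.experiment import run_desk_experiment, operon_analysis

run = run_desk_experiment(seed=1)       # ~4 min on one CPU core
print(run.results.summary())
print(run.results.evaluate(seed=5))
print(operon_analysis(run, seed=0))
```

```
Contig language model results
============================================================
layers: 4   hidden: 128   heads/layer: 4   total heads: 16
predictions/position: 4   label dim: 17   input dim: 33
parameters: 814,280   alpha: 0.1
label PCA explained variance: 0.942
steps trained: 400   final loss: 0.12016 (mse 0.09835, ce 0.2180)
best validation pseudo-accuracy: 0.6929

{'pseudo_accuracy': 0.6427, 'oracle_best_accuracy': 0.7078,
 'high_conf_fraction': 0.7496, 'high_conf_accuracy': 0.7461,
 'tau': 0.75, 'n_masked': 599}

{'max_abs_rho': 0.6506, 'best_layer': 3, 'best_head': 2,
 'perm_null_p99': 0.0529, 'mean_ap': 0.9627, 'sd_ap': 0.0111,
 'prevalence': 0.3426, 'n_pairs': 2011}
```

The desk-scale model recovers the planted context far above the 1/17.5 ≈
0.057 exchangeability baseline; its high-confidence predictions
(likelihood > 0.75) are *more* accurate than average, i.e. the likelihood
head is calibrated; one attention head correlates strongly with the
planted operon blocks (ρ = 0.65 against a permutation-null 99th
percentile of 0.053); and a logistic regression over all head features
predicts operonic adjacency at average precision 0.96 versus a 0.34
prevalence.

The same workflow is available from the shell:

```bash
contiglm simulate --config sim.yaml --out corpus/
contiglm train --corpus corpus/ --out ckpt/ --steps 400
contiglm eval --checkpoint ckpt/ --corpus corpus/ --out metrics.json
contiglm operon --checkpoint ckpt/ --corpus corpus/ --out-prefix operon
```

(plus `embed`, `attend`, `kl`, `variance`, `probe`, `paralog`,
`taxonomy`).

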