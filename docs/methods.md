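# Methods

## The model

`contiglm` trains a masked language model over *gene-level* tokens.  The
input unit is a sub-contig: an ordered window of 15–30 genes cut from an
assembled (meta)genomic contig.  Each gene is represented by a fixed,
context-free protein embedding of width E (in production pipelines a
protein-language-model embedding of the gene's translated sequence; here
anything supplied through the embedding-provider interface) concatenated
with an orientation flag, +0.5 for forward and −0.5 for reverse, giving an
(E+1)-feature token.

Embeddings are z-scored per feature and clipped to ±10 before use
(population standard deviation; features with zero variance are mapped to
exactly 0).  Training labels are deliberately lower-dimensional than the
inputs: the label of a gene is the PCA-whitened score vector of its
normalized embedding on the leading `k_pc` principal components,
concatenated with its orientation (`label_dim = k_pc + 1`; at full scale
99 components + orientation = 100 features).  Whitening is fitted on the
training split only; component signs are fixed by making each component's
largest-magnitude loading positive, so refits are bit-reproducible.

During training 15% of tokens are masked independently per gene (with a
floor of at least one masked gene per contig — the whole contig's draw is
redrawn if it selects none; the induced bias on the marginal rate is
measured in the tests and is negligible at L ≥ 15).  A masked token is the
constant −1 vector across *all* E+1 slots, embedding and orientation alike.

The encoder is a post-layer-norm transformer with GELU feed-forward blocks
and learned relative key-query position embeddings: the attention logit
between positions i and j gains q_i·r(i−j) + k_j·r(i−j), where r is a
per-layer table over signed offsets clipped at ±(`max_rel_distance`−1).
A learned affine map adapts the (E+1)-wide tokens to the hidden size.

Because more than one gene can legitimately occupy a genomic niche, the
head makes `n_pred` = 4 candidate predictions per position plus 4
likelihood logits, all from a single affine map of the final hidden state.
The loss scores only the candidate closest (L2) to the label and trains
the likelihood head toward the index of that candidate:

    total = MSE(closest candidate, label) + α · CE(likelihood logits, closest index)

MSE is averaged over masked positions and label dimensions; CE over
positions; argmin ties break to the lowest index.  Likelihoods are the
softmax of the logits — the cross-entropy in the objective presupposes a
categorical distribution.

## Evaluation metrics

*Pseudo-accuracy*: a masked gene counts as correct when the selected
prediction is strictly closer to that gene's label than to every other
gene label in the same sub-contig (ties are incorrect — conservative and
deterministic).  The prediction selected is the highest-likelihood
candidate, which keeps the metric consistent with the confidence analysis;
the best-of-4 oracle variant is reported as a secondary diagnostic only.
Distances use the full label space including the orientation coordinate,
since the label is defined with orientation concatenated.
*Absolute accuracy* applies the same criterion against the label universe
of a whole genome with each gene masked one at a time; it can never exceed
pseudo-accuracy on the same predictions because the universe contains each
sub-contig's labels.  *Confidence report*: the fraction of masked
positions whose top likelihood exceeds τ (0.75 by convention) and the
pseudo-accuracy restricted to them.

Under exchangeable labels (an i.i.d. corpus and a predictor independent of
the masked gene's own label) the expected pseudo-accuracy is 1/L; this is
the null against which recovery is judged.

## Hyper-parameters

| parameter | full scale | desk scale | notes |
|---|---|---|---|
| layers / hidden / heads | 19 / 1280 / 10 | 4 / 128 / 4 | 190 vs 16 total heads |
| predictions per position | 4 | 4 | |
| label dim (k_pc + 1) | 100 | 17 | |
| α (CE weight) | 1e-4 | 0.1 | see below |
| optimizer | AdamW, 5000-step warmup to 1e-4, batch 3000 | AdamW, 50-step warmup to 1e-3, batch 32, 400 steps | linear warmup, constant after |
| mask rate | 0.15 | 0.15 | Bernoulli per gene, ≥1 per contig |

α at full scale (1e-4) assumes ~1.3M optimizer steps; over a 400-step desk
run the likelihood head would receive essentially no gradient and the
confidence analysis would be vacuous (no prediction could ever clear
τ = 0.75).  The desk configuration therefore sets α = 0.1, chosen once
from this gradient-scale argument and kept fixed.  Desk training clips the
global gradient norm at 1.0; the learning rate is constant after warmup
(the post-warmup schedule is a free choice here).  Training runs in
float64 — at desk sizes the cost is acceptable and CPU determinism is
worth more than speed.

## The synthetic corpus

The generator emulates the statistical structure the analyses assume,
with analytic ground truth:

- **families** — points on the sphere of radius √E with isotropic Gaussian
  within-family noise (s.d. `noise_scale`); isotropy keeps expectations
  (e.g. the context-variance of a family) available in closed form;
- **operons** — templates of ≥2 families instantiated as contiguous,
  co-oriented blocks; blocks never straddle contig boundaries, so the
  adjacency-level operon truth is unambiguous; background orientations are
  Bernoulli(1/2), mirroring the polycistronic-transcription signal the
  attention analysis looks for;
- **context** — first-order successor rules between background families;
  rules with two equal-mass successors plant genuinely ambiguous contexts,
  the situation the 4-way prediction head exists for;
- **interacting pairs** — reserved family pairs planted only as strict
  forward adjacencies (ground truth for paralog matching);
- **contig classes** — distinct family-usage weights (taxonomy stand-in).

It does **not** simulate nucleotide sequence, intergenic spacing, codon
structure, homology gradients or realistic phylogeny.  Passing recovery
tests on this corpus therefore demonstrates that the implementation can
learn and report planted structure of the assumed form — not that the
desk-scale model would reach the full-scale numbers on real metagenomes.

### The reference experiment (`contiglm.experiment`)

2,000 contigs of 15–20 genes over a 30-family catalog (E = 32, noise 0.05):
a deterministic successor chain over families 0–9 with one ambiguous
branch (9 → {0, 5}), operon templates (10,11,12), (13,14,15,16), (17,18)
at insertion probabilities 0.15/0.10/0.10 (operonic prevalence ≈ 0.33
of adjacent pairs), and pairs (20,21), (22,23), (24,25).  10% of contigs
are held out whole (the full-scale protocol's 70%-identity homology
exclusion needs a sequence-similarity oracle and is available as a
pluggable filter, not a default).  Problem sizes for the downstream
analyses (120 held-out contigs for the operon statistics, 120 occurrences
per context level for the variance statistic, 1000 chance iterations for
paralog matching) were chosen once as the smallest sizes at which the
corresponding null distributions are stable.

## Downstream statistics

- **Operon analysis** — the feature for an adjacent pair (i, i+1) is the
  single symmetrized attention entry at (i, i+1), one per head
  (symmetrization S = (A+Aᵀ)/2 preserves total mass).  Per-head Pearson ρ
  is computed on pairs pooled across contigs (one global ρ per head) with
  Bonferroni adjustment across heads; the all-heads classifier is an
  L2-regularized logistic regression (C = 1.0, recorded) under stratified
  5-fold CV reporting average precision.
- **Gaussian KL** — closed form ½[tr(Σ₁⁻¹Σ₀) − k + (μ₁−μ₀)ᵀΣ₁⁻¹(μ₁−μ₀) +
  ln(det Σ₁/det Σ₀)].  Preprocessing: per-sample Mahalanobis outlier
  removal at the chi-squared(0.975, k) quantile, then PCA fitted on the
  pooled sample so both distributions live in one space.  Singular
  covariances get a ridge ε = 1e-6·tr(Σ)/k, recorded and warned about.
  The KL ratio D(B‖A)/D(C‖A) reads < 1 as "B sits closer to the reference
  A than C does".
- **Context variance** — per family: the mean over 10 independent samples
  of 100 occurrences of the mean pairwise Euclidean distance between the
  occurrence embeddings; occurrences at the first or last contig position
  are excluded; families with fewer occurrences than the sample size are
  skipped and logged.  The baseline mode attributes the contig-averaged
  context-free embedding to every occurrence.
- **Linear probe** — one affine layer + softmax, mini-batch gradient
  descent, early stopping on a held-out split (patience 10), replicate
  seeds for error bars; per-class F1 comparisons use a two-sided t-test
  with Benjamini–Hochberg correction across classes.
- **Paralog matching** — a three-token contig (mask, query, mask) in
  forward orientation; each flank's highest-likelihood prediction is
  matched to the nearest candidate label; correct when either flank
  recovers the true partner (or its sequence cluster).  The chance
  baseline replaces both predictions with standard-normal vectors over
  1000 iterations — the simulation *is* the null, no closed form is
  assumed.
- **Taxonomy** — logistic regression on mean-pooled contig embeddings
  (contextualized = last hidden layer; context-free = raw inputs),
  stratified 5-fold CV, micro-averaged precision-recall.
- **Silhouette** — the standard Euclidean silhouette score.

## Numerical conventions and degenerate inputs

Argmin ties break to the lowest index everywhere.  Nearest-label ties in
the accuracy metrics count as incorrect (duplicate labels additionally
warn).  Padding positions receive −1e9 attention logits (zero mass to
machine precision), are never masked or labelled, and are dropped before
pooling or attention export.  Attention rows over real keys are
row-stochastic within 1e-5.  The hidden-state stack indexes the projected
input as layer 0 and the final encoder output (no extra layer-norm) as
layer −1.  Zero-variance features normalize to 0; empty corpora warn and
return empty lists; constant attention columns yield a missing (NaN) ρ.

At desk scale the absolute-accuracy metric is intrinsically low even for a
well-trained model: with 30 families across ~450 universe genes, every
family contributes many near-identical labels, and the unique-nearest
criterion can only be satisfied for roughly one occurrence per family
(observed ≈ 0.06 ≈ 1/mean multiplicity, versus 0.64 pseudo-accuracy).
On a real genome, where genes are essentially unique, the two metrics are
comparable; here absolute accuracy is reported for the set-inclusion
invariant (absolute ≤ pseudo), not as a performance figure.

## Known limitations

The untrained-encoder control of the operon classifier does not sit at
prevalence under the reference conditions: planted blocks use reserved
families, so family identity alone is nearly sufficient to predict operon
membership, and even random-init attention values expose token identity
to a trained logistic regression.  The corresponding test documents this
margin rather than hiding it; the analogous full-scale observation is
that a one-hot ablation still learns substantial operon signal from
orientation and co-occurrence alone.  The same caveat applies to any
"untrained network ≈ chance" control on this corpus: hidden states and
attention values of a random-init encoder are nearly injective functions
of their inputs, so a classifier trained on top of them can decode
whatever the inputs determine (e.g. a masked-context probe on an
untrained encoder reaches well above chance because the deterministic
successor rules make the masked family a function of its context).
Untrained controls here measure input-determinism, not learning.  Desk-scale numbers are recovery
demonstrations, not estimates of full-scale performance.
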