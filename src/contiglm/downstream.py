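"""Downstream statistics on attentions and contextualized embeddings.

Covers the operon analyses (per-head Pearson correlation against operon
labels and an all-heads logistic-regression operon classifier), the
Gaussian KL-divergence machinery with Mahalanobis outlier removal and PCA,
the per-gene context-variance statistic, linear probes of gene function,
paralog matching with its standard-normal chance simulation, contig-level
taxonomy classification, and a silhouette utility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (average_precision_score, confusion_matrix,
                             f1_score, precision_recall_curve,
                             silhouette_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import label_binarize

from .corpus import GeneRecord, MaskedBatch, SubContig
from .inference import SymmetrizedAttention, run_contig
from .model import GLMModule, forward

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Operon analysis
# ---------------------------------------------------------------------------

@dataclass
class PairFeatureMatrix:
    """Adjacent-gene-pair features: one symmetrized attention value per head
    at the (i, i+1) entry, with the operonic label."""

    X: np.ndarray                 # (n_pairs, n_layers*n_heads)
    y: np.ndarray                 # bool
    pairs: list[tuple[str, int]]  # (contig_id, i)


def build_pair_features(attns: list[SymmetrizedAttention],
                        contigs: list[SubContig]) -> PairFeatureMatrix:
    rows, labels, meta = [], [], []
    for att, c in zip(attns, contigs):
        if c.operon_pairs is None:
            raise ValueError(f"contig {c.contig_id} has no operon labels")
        feats = att.adjacent_pair_features()          # (L-1, heads)
        rows.append(feats)
        labels.append(np.asarray(c.operon_pairs, dtype=bool))
        meta.extend((c.contig_id, i) for i in range(len(c) - 1))
    return PairFeatureMatrix(np.concatenate(rows), np.concatenate(labels), meta)


def head_operon_correlation(attns: list[SymmetrizedAttention],
                            contigs: list[SubContig]) -> pd.DataFrame:
    """Per-(layer, head) Pearson correlation between the (i, i+1)
    symmetrized attention values pooled over contigs and the boolean operon
    labels, with Bonferroni-adjusted p-values across heads."""
    fm = build_pair_features(attns, contigs)
    if fm.y.sum() == 0 or fm.y.sum() == len(fm.y):
        raise ValueError("operon labels have zero variance")
    if len(fm.y) < 2:
        raise ValueError("need at least 2 labeled pairs")
    nl, nh = attns[0].matrices.shape[:2]
    recs = []
    n_tests = nl * nh
    for h in range(n_tests):
        x = fm.X[:, h]
        if np.ptp(x) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.pearsonr(x, fm.y.astype(float))
        recs.append({"layer": h // nh, "head": h % nh, "rho": rho, "p": p,
                     "p_bonferroni": min(p * n_tests, 1.0) if np.isfinite(p)
                     else np.nan})
    return pd.DataFrame(recs)


@dataclass
class OperonClassifierResult:
    fold_ap: np.ndarray
    mean_ap: float
    sd_ap: float
    prevalence: float
    pr_curves: list[tuple[np.ndarray, np.ndarray]]
    classifier: LogisticRegression


def train_operon_classifier(fm: PairFeatureMatrix, k: int = 5, C: float = 1.0,
                            seed: int = 0) -> OperonClassifierResult:
    """All-heads logistic regression with stratified k-fold CV; reports the
    per-fold average precision and precision-recall curves.  L2 regularization
    at C=1.0 (recorded here) unless overridden."""
    y = fm.y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("operon classifier needs both classes")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aps, curves = [], []
    for tr, te in skf.split(fm.X, y):
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(fm.X[tr], y[tr])
        scores = clf.decision_function(fm.X[te])
        aps.append(average_precision_score(y[te], scores))
        prec, rec, _ = precision_recall_curve(y[te], scores)
        curves.append((prec, rec))
    final = LogisticRegression(C=C, max_iter=2000).fit(fm.X, y)
    aps = np.array(aps)
    return OperonClassifierResult(aps, float(aps.mean()), float(aps.std()),
                                  float(y.mean()), curves, final)


# ---------------------------------------------------------------------------
# Gaussian KL divergence
# ---------------------------------------------------------------------------

@dataclass
class GaussianSummary:
    mean: np.ndarray
    covariance: np.ndarray
    n: int
    regularization: float = 0.0

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


def summarize_gaussian(X: np.ndarray) -> GaussianSummary:
    X = np.asarray(X, dtype=np.float64)
    return GaussianSummary(X.mean(axis=0), np.cov(X, rowvar=False), X.shape[0])


def remove_outliers_mahalanobis(X: np.ndarray, chi2_q: float = 0.975
                                ) -> np.ndarray:
    """Drop points whose squared Mahalanobis distance from the sample mean
    exceeds the chi-squared quantile ``chi2_q`` at the data dimension."""
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    k = X.shape[1]
    cov = cov + 1e-12 * np.eye(k)
    d2 = np.einsum("ij,jk,ik->i", X - mu, np.linalg.inv(cov), X - mu)
    return X[d2 <= stats.chi2.ppf(chi2_q, df=k)]


def kl_preprocess(X0: np.ndarray, X1: np.ndarray, n_pc: int,
                  chi2_q: float = 0.975
                  ) -> tuple[GaussianSummary, GaussianSummary]:
    """The embedding-distribution pipeline: Mahalanobis outlier removal per
    sample, then PCA to ``n_pc`` components fitted on the pooled sample so
    both distributions live in one space."""
    from sklearn.decomposition import PCA
    X0 = remove_outliers_mahalanobis(X0, chi2_q)
    X1 = remove_outliers_mahalanobis(X1, chi2_q)
    pca = PCA(n_components=n_pc, svd_solver="full")
    pca.fit(np.concatenate([X0, X1]))
    return summarize_gaussian(pca.transform(X0)), \
        summarize_gaussian(pca.transform(X1))


def gaussian_kl(P: GaussianSummary, Q: GaussianSummary) -> float:
    """Closed-form KL divergence between Gaussians,

        D_KL(P||Q) = 1/2 [ tr(S1^-1 S0) - k + (m1-m0)^T S1^-1 (m1-m0)
                           + ln(det S1 / det S0) ]

    with (m0, S0) = P and (m1, S1) = Q.  Singular Q covariances are
    ridge-regularized (eps = 1e-6 * trace/k, recorded on the summary) with a
    warning."""
    if P.dim != Q.dim:
        raise ValueError("dimension mismatch")
    k = P.dim
    S0, S1 = P.covariance, Q.covariance
    sign1, logdet1 = np.linalg.slogdet(S1)
    if sign1 <= 0 or not np.isfinite(np.linalg.cond(S1)) \
            or np.linalg.cond(S1) > 1e12:
        eps = 1e-6 * np.trace(S1) / k
        logger.warning("ridge-regularizing singular covariance (eps=%.3g)", eps)
        S1 = S1 + eps * np.eye(k)
        Q.regularization = eps
        sign1, logdet1 = np.linalg.slogdet(S1)
    sign0, logdet0 = np.linalg.slogdet(S0)
    if sign0 <= 0:
        eps = 1e-6 * max(np.trace(S0), 1e-12) / k
        S0 = S0 + eps * np.eye(k)
        P.regularization = eps
        sign0, logdet0 = np.linalg.slogdet(S0)
    S1inv = np.linalg.inv(S1)
    dmu = Q.mean - P.mean
    val = 0.5 * (np.trace(S1inv @ S0) - k + dmu @ S1inv @ dmu
                 + logdet1 - logdet0)
    return float(max(val, 0.0))


def kl_ratio(A: GaussianSummary, B: GaussianSummary,
             C: GaussianSummary) -> float:
    """D_KL(B||A) / D_KL(C||A): below 1 means distribution B sits closer to
    the reference A than C does (functional discrimination)."""
    denom = gaussian_kl(C, A)
    if denom == 0.0:
        raise ZeroDivisionError("D_KL(C||A) is zero; ratio undefined")
    return gaussian_kl(B, A) / denom


# ---------------------------------------------------------------------------
# Context variance
# ---------------------------------------------------------------------------

@dataclass
class VarianceReport:
    """Per-gene context variance: mean (over ``n_samples`` random samples of
    ``sample_size`` occurrences) of the mean pairwise Euclidean distance
    between the occurrence embeddings."""

    variance: dict[str, float]
    skipped: list[str]
    n_samples: int
    sample_size: int

    @property
    def values(self) -> np.ndarray:
        return np.array([self.variance[k] for k in sorted(self.variance)])

    @property
    def kurtosis(self) -> float:
        return float(stats.kurtosis(self.values))      # Fisher (excess)

    @property
    def skew(self) -> float:
        return float(stats.skew(self.values))


def context_variance(occurrences: dict[str, np.ndarray], n_samples: int = 10,
                     sample_size: int = 100, seed: int = 0) -> VarianceReport:
    if sample_size < 2:
        raise ValueError("sample_size must be >= 2")
    rng = np.random.default_rng(seed)
    out, skipped = {}, []
    for key in sorted(occurrences):
        X = np.asarray(occurrences[key])
        if X.shape[0] < sample_size:
            skipped.append(key)
            logger.info("skipping %s: %d < %d occurrences", key, X.shape[0],
                        sample_size)
            continue
        vals = []
        for _ in range(n_samples):
            idx = rng.choice(X.shape[0], size=sample_size, replace=False)
            d = X[idx]
            from scipy.spatial.distance import pdist
            vals.append(pdist(d).mean())
        out[key] = float(np.mean(vals))
    return VarianceReport(out, skipped, n_samples, sample_size)


def collect_occurrence_embeddings(module: GLMModule,
                                  contigs: list[SubContig], layer: int = -1,
                                  mode: str = "contextualized",
                                  exclude_edges: bool = True
                                  ) -> dict[str, np.ndarray]:
    """Group per-occurrence embeddings by family: contextualized hidden
    states, or the contig-averaged context-free baseline (the same mean
    input embedding attributed to every occurrence in the contig).
    Occurrences at the first or last contig position are excluded."""
    acc: dict[str, list[np.ndarray]] = {}
    for c in contigs:
        if mode == "contextualized":
            embs = run_contig(module, c).hidden_states[layer]
        elif mode == "contig_averaged_context_free":
            pooled = np.stack([g.embedding for g in c.genes]).mean(axis=0)
            embs = np.tile(pooled, (len(c), 1))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        lo, hi = (1, len(c) - 1) if exclude_edges else (0, len(c))
        for i in range(lo, hi):
            fam = c.genes[i].family_id or c.genes[i].gene_id
            acc.setdefault(fam, []).append(embs[i])
    return {k: np.stack(v) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# Linear probes
# ---------------------------------------------------------------------------

@dataclass
class ProbeConfig:
    patience: int = 10
    batch_size: int = 256
    lr: float = 0.05
    max_epochs: int = 500
    val_fraction: float = 0.1
    seed: int = 0


@dataclass
class ProbeResult:
    accuracy: float
    per_class_f1: dict[str, float]
    mean_average_precision: float
    classes: list[str]


def linear_probe(train: tuple[np.ndarray, np.ndarray],
                 test: tuple[np.ndarray, np.ndarray],
                 cfg: ProbeConfig | None = None) -> ProbeResult:
    """Single affine layer + softmax trained by mini-batch gradient descent
    with early stopping (``patience`` epochs without validation-loss
    improvement)."""
    cfg = cfg or ProbeConfig()
    Xtr, ytr = np.asarray(train[0], float), np.asarray(train[1])
    Xte, yte = np.asarray(test[0], float), np.asarray(test[1])
    classes = sorted(set(map(str, ytr)))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    missing = set(map(str, yte)) - set(classes)
    if missing:
        raise ValueError(f"test classes absent from training: {missing}")
    cls_idx = {c: i for i, c in enumerate(classes)}
    ytr_i = np.array([cls_idx[str(v)] for v in ytr])
    yte_i = np.array([cls_idx[str(v)] for v in yte])
    rng = np.random.default_rng(cfg.seed)
    n = len(Xtr)
    order = rng.permutation(n)
    n_val = max(1, int(cfg.val_fraction * n))
    vi, ti = order[:n_val], order[n_val:]
    mu, sd = Xtr[ti].mean(0), Xtr[ti].std(0) + 1e-8
    Xt, Xv = (Xtr[ti] - mu) / sd, (Xtr[vi] - mu) / sd
    yt, yv = ytr_i[ti], ytr_i[vi]
    C, d = len(classes), Xtr.shape[1]
    W = np.zeros((d, C))
    b = np.zeros(C)

    def _loss(X, y, W, b):
        z = X @ W + b
        z -= z.max(1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(1, keepdims=True))
        return -logp[np.arange(len(y)), y].mean()

    best = (np.inf, W.copy(), b.copy())
    stale = 0
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(Xt))
        for s in range(0, len(Xt), cfg.batch_size):
            idx = perm[s:s + cfg.batch_size]
            X, y = Xt[idx], yt[idx]
            z = X @ W + b
            z -= z.max(1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(1, keepdims=True)
            p[np.arange(len(y)), y] -= 1.0
            p /= len(y)
            W -= cfg.lr * (X.T @ p)
            b -= cfg.lr * p.sum(0)
        vl = _loss(Xv, yv, W, b)
        if vl < best[0] - 1e-6:
            best = (vl, W.copy(), b.copy())
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    _, W, b = best
    Xs = (Xte - mu) / sd
    z = Xs @ W + b
    pred = z.argmax(1)
    acc = float((pred == yte_i).mean())
    f1 = f1_score(yte_i, pred, average=None, labels=np.arange(C),
                  zero_division=0)
    z -= z.max(1, keepdims=True)
    proba = np.exp(z)
    proba /= proba.sum(1, keepdims=True)
    Y = label_binarize(yte_i, classes=np.arange(C))
    if C == 2:
        Y = np.column_stack([1 - Y, Y])
    present = Y.sum(0) > 0
    mAP = float(np.mean([average_precision_score(Y[:, c], proba[:, c])
                         for c in range(C) if present[c]]))
    return ProbeResult(acc, dict(zip(classes, f1.tolist())), mAP, classes)


def compare_probe_f1(runs_a: list[ProbeResult], runs_b: list[ProbeResult]
                     ) -> pd.DataFrame:
    """Per-class two-sided t-test of F1 across replicate probe runs with
    Benjamini-Hochberg correction across classes."""
    classes = runs_a[0].classes
    recs = []
    for c in classes:
        a = np.array([r.per_class_f1[c] for r in runs_a])
        b = np.array([r.per_class_f1[c] for r in runs_b])
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and a[0] == b[0]:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b)
            if not np.isfinite(p):
                p = 1.0
        recs.append({"class": c, "f1_a": a.mean(), "f1_b": b.mean(),
                     "t": t, "p": p})
    df = pd.DataFrame(recs)
    m = len(df)
    order = np.argsort(df["p"].values)
    adj = np.empty(m)
    prev = 1.0
    for rank, i in enumerate(reversed(order), start=0):
        k = m - rank
        prev = min(prev, df["p"].values[i] * m / k)
        adj[i] = prev
    df["p_bh"] = adj
    return df


# ---------------------------------------------------------------------------
# Paralog matching
# ---------------------------------------------------------------------------

@dataclass
class ParalogQueryResult:
    query_id: str
    predictions: np.ndarray        # (2, n_pred, label_dim), one row per flank
    likelihoods: np.ndarray        # (2, n_pred)
    nearest: tuple[int, int]       # nearest candidate per flank's top prediction
    correct_exact: bool
    correct_cluster: bool


def _nearest_candidate(vec: np.ndarray, candidates: np.ndarray) -> int:
    return int(np.linalg.norm(candidates - vec, axis=1).argmin())


def paralog_match(module: GLMModule, query: GeneRecord,
                  candidate_labels: np.ndarray, partner_idx: int,
                  clusters: dict[int, int] | None = None
                  ) -> ParalogQueryResult:
    """Mask both flanks of a three-token contig (mask, query, mask), predict
    them, and match each flank's highest-likelihood prediction to the
    nearest candidate label; correct when either flank recovers the true
    partner (or its sequence cluster)."""
    candidate_labels = np.asarray(candidate_labels, dtype=np.float64)
    if candidate_labels.size == 0:
        raise ValueError("empty candidate list")
    cfg = module.config
    E1 = cfg.input_dim
    tokens = np.full((1, 3, E1), cfg.mask_value)
    tokens[0, 1] = query.token
    attn = np.ones((1, 3), dtype=bool)
    batch = MaskedBatch(tokens, attn, [(0, 0), (0, 2)], np.zeros((0, 1)),
                        cfg.mask_value, [])
    pset = forward(module, batch)
    top = pset.top_prediction                      # (2, label_dim)
    nearest = (_nearest_candidate(top[0], candidate_labels),
               _nearest_candidate(top[1], candidate_labels))
    exact = partner_idx in nearest
    if clusters is not None:
        cl = clusters.get(partner_idx)
        cluster_ok = any(clusters.get(nb) == cl for nb in nearest)
    else:
        cluster_ok = exact
    return ParalogQueryResult(query.gene_id, pset.predictions,
                              pset.likelihoods, nearest, bool(exact),
                              bool(cluster_ok))


def paralog_chance_simulation(candidate_labels: np.ndarray,
                              partner_indices: list[int], n_iter: int = 1000,
                              seed: int = 0) -> np.ndarray:
    """The chance baseline: replace the two flank predictions of every query
    with standard-normal vectors, repeat the nearest-candidate matching, and
    return the exact-match count per iteration."""
    candidate_labels = np.asarray(candidate_labels, dtype=np.float64)
    rng = np.random.default_rng(seed)
    k = candidate_labels.shape[1]
    counts = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        for partner in partner_indices:
            preds = rng.standard_normal((2, k))
            nearest = (_nearest_candidate(preds[0], candidate_labels),
                       _nearest_candidate(preds[1], candidate_labels))
            counts[it] += partner in nearest
    return counts


# ---------------------------------------------------------------------------
# Taxonomy classification & silhouette
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyResult:
    fold_ap: np.ndarray
    mean_ap: float
    sd_ap: float
    confusion: np.ndarray
    classes: list[str]
    pr_curves: list[tuple[np.ndarray, np.ndarray]]


def taxonomy_classifier(embeddings: np.ndarray, classes: list[str],
                        k: int = 5, C: float = 1.0, seed: int = 0
                        ) -> TaxonomyResult:
    """Logistic regression on contig embeddings with stratified k-fold CV;
    micro-averaged average precision over one-vs-rest scores."""
    y = np.asarray(classes)
    uniq, counts = np.unique(y, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 contig classes")
    small = uniq[counts < k].tolist()
    if small:
        raise ValueError(f"classes smaller than k={k}: {small}")
    yi = np.searchsorted(uniq, y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aps, curves = [], []
    conf = np.zeros((len(uniq), len(uniq)), dtype=int)
    for tr, te in skf.split(embeddings, yi):
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(embeddings[tr], yi[tr])
        proba = clf.predict_proba(embeddings[te])
        Y = label_binarize(yi[te], classes=np.arange(len(uniq)))
        if len(uniq) == 2:
            Y = np.column_stack([1 - Y, Y])
        aps.append(average_precision_score(Y.ravel(), proba.ravel()))
        prec, rec, _ = precision_recall_curve(Y.ravel(), proba.ravel())
        curves.append((prec, rec))
        conf += confusion_matrix(yi[te], clf.predict(embeddings[te]),
                                 labels=np.arange(len(uniq)))
    aps = np.array(aps)
    return TaxonomyResult(aps, float(aps.mean()), float(aps.std()), conf,
                          uniq.tolist(), curves)


def silhouette(embeddings: np.ndarray, grouping: list[str]) -> float:
    """Standard silhouette score with the Euclidean metric."""
    groups = np.asarray(grouping)
    if len(np.unique(groups)) < 2:
        raise ValueError("silhouette needs >= 2 groups")
    if len(groups) < 3:
        raise ValueError("silhouette needs >= 3 points")
    return float(silhouette_score(np.asarray(embeddings), groups,
                                  metric="euclidean"))
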