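"""Closed forms, Monte-Carlo oracles, and null behaviour of the downstream
statistics (no trained model required here)."""

import numpy as np
import pytest
from scipy import stats

from contiglm.downstream import (GaussianSummary, PairFeatureMatrix,
                                 context_variance, gaussian_kl, kl_preprocess,
                                 kl_ratio, linear_probe,
                                 paralog_chance_simulation,
                                 remove_outliers_mahalanobis, silhouette,
                                 taxonomy_classifier,
                                 train_operon_classifier)


def gsum(mean, cov, n=100):
    return GaussianSummary(np.atleast_1d(np.asarray(mean, float)),
                           np.atleast_2d(np.asarray(cov, float)), n)


class TestGaussianKL:
    def test_identical_distributions_give_zero(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((5, 5))
        cov = A @ A.T + np.eye(5)
        P = gsum(rng.standard_normal(5), cov)
        assert gaussian_kl(P, P) == pytest.approx(0.0, abs=1e-8)

    def test_unit_variance_mean_shift_closed_form(self):
        # KL(N(0,1) || N(1,1)) = 1/2 (mu difference)^2 = 0.5
        P, Q = gsum(0.0, 1.0), gsum(1.0, 1.0)
        assert gaussian_kl(P, Q) == pytest.approx(0.5, abs=1e-12)

    def test_1d_general_closed_form(self):
        # KL(N(m0,s0^2)||N(m1,s1^2)) = ln(s1/s0) + (s0^2+(m0-m1)^2)/(2 s1^2) - 1/2
        m0, s0, m1, s1 = 0.3, 1.2, -0.5, 0.8
        expect = np.log(s1 / s0) + (s0**2 + (m0 - m1)**2) / (2 * s1**2) - 0.5
        assert gaussian_kl(gsum(m0, s0**2), gsum(m1, s1**2)) == \
            pytest.approx(expect, abs=1e-12)

    def test_matches_monte_carlo_oracle_5d(self):
        """Closed form vs a 1e6-sample Monte-Carlo estimate of
        E_P[log p(x) - log q(x)] on random 5-d Gaussians."""
        rng = np.random.default_rng(42)
        k = 5
        A = rng.standard_normal((k, k))
        B = rng.standard_normal((k, k))
        P = gsum(rng.standard_normal(k), A @ A.T + np.eye(k))
        Q = gsum(rng.standard_normal(k), B @ B.T + np.eye(k))
        n = 1_000_000
        X = rng.multivariate_normal(P.mean, P.covariance, size=n)
        lp = stats.multivariate_normal(P.mean, P.covariance).logpdf(X)
        lq = stats.multivariate_normal(Q.mean, Q.covariance).logpdf(X)
        diffs = lp - lq
        mc, se = diffs.mean(), diffs.std(ddof=1) / np.sqrt(n)
        assert abs(gaussian_kl(P, Q) - mc) < 3 * se

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = int(rng.integers(1, 6))
            A = rng.standard_normal((k, k))
            B = rng.standard_normal((k, k))
            P = gsum(rng.standard_normal(k), A @ A.T + 0.5 * np.eye(k))
            Q = gsum(rng.standard_normal(k), B @ B.T + 0.5 * np.eye(k))
            assert gaussian_kl(P, Q) >= 0.0

    def test_singular_covariance_is_regularized(self):
        P = gsum([0.0, 0.0], np.eye(2))
        Q = gsum([0.0, 0.0], [[1.0, 0.0], [0.0, 0.0]])   # rank 1
        val = gaussian_kl(P, Q)
        assert np.isfinite(val)
        assert Q.regularization > 0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            gaussian_kl(gsum(0.0, 1.0), gsum([0.0, 0.0], np.eye(2)))


class TestKLRatio:
    def test_identical_b_and_c_give_one(self):
        A = gsum([0.0, 0.0], np.eye(2))
        B = gsum([1.0, 0.0], np.eye(2))
        C = gsum([1.0, 0.0], np.eye(2))
        assert kl_ratio(A, B, C) == pytest.approx(1.0)

    def test_b_equals_reference_gives_zero(self):
        A = gsum(0.0, 1.0)
        B = gsum(0.0, 1.0)
        C = gsum(2.0, 1.0)
        assert kl_ratio(A, B, C) == pytest.approx(0.0, abs=1e-10)

    def test_zero_denominator_raises(self):
        A = gsum(0.0, 1.0)
        with pytest.raises(ZeroDivisionError):
            kl_ratio(A, gsum(1.0, 1.0), gsum(0.0, 1.0))


class TestMahalanobisFilter:
    def test_removes_about_expected_fraction(self):
        rng = np.random.default_rng(1)
        X = rng.multivariate_normal(np.zeros(4), np.eye(4), size=8000)
        kept = remove_outliers_mahalanobis(X, 0.975)
        removed = 1 - len(kept) / len(X)
        assert abs(removed - 0.025) < 0.01

    def test_flags_gross_outlier(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.standard_normal((500, 3)), [[50, 50, 50]]])
        kept = remove_outliers_mahalanobis(X)
        assert len(kept) < len(X)
        assert not (kept == 50).all(axis=1).any()

    def test_kl_preprocess_pipeline_shapes(self):
        rng = np.random.default_rng(3)
        X0 = rng.standard_normal((400, 10))
        X1 = rng.standard_normal((400, 10)) + 0.5
        P, Q = kl_preprocess(X0, X1, n_pc=3)
        assert P.dim == Q.dim == 3
        assert gaussian_kl(P, Q) >= 0


class TestContextVariance:
    def test_identical_occurrences_zero_variance(self):
        occ = {"fam": np.tile(np.arange(4.0), (150, 1))}
        rep = context_variance(occ, n_samples=5, sample_size=100, seed=0)
        assert rep.variance["fam"] == 0.0

    def test_two_point_masses_approach_half_distance(self):
        """Balanced occurrences at two points distance d apart: the mean
        pairwise distance tends to d * (cross-pair fraction) = d/2
        (exhaustive expectation: n/2*n/2 cross pairs of n(n-1)/2 total)."""
        d = 4.0
        a = np.zeros((300, 2))
        b = np.tile([d, 0.0], (300, 1))
        occ = {"fam": np.vstack([a, b])}
        n = 100
        exact = d * (n // 2) * (n // 2) / (n * (n - 1) / 2)
        rep = context_variance(occ, n_samples=20, sample_size=n, seed=1)
        assert rep.variance["fam"] == pytest.approx(exact, rel=0.05)

    def test_small_families_skipped_and_logged(self):
        occ = {"big": np.random.default_rng(0).standard_normal((120, 3)),
               "small": np.zeros((10, 3))}
        rep = context_variance(occ, n_samples=3, sample_size=100, seed=0)
        assert rep.skipped == ["small"]
        assert set(rep.variance) == {"big"}

    def test_sample_size_validation(self):
        with pytest.raises(ValueError):
            context_variance({"f": np.zeros((10, 2))}, sample_size=1)

    def test_distribution_shape_stats_finite(self):
        rng = np.random.default_rng(4)
        occ = {f"f{i}": rng.standard_normal((110, 3)) * (1 + i)
               for i in range(6)}
        rep = context_variance(occ, n_samples=4, sample_size=100, seed=0)
        assert np.isfinite(rep.kurtosis) and np.isfinite(rep.skew)


class TestOperonStats:
    def _fm(self, X, y):
        return PairFeatureMatrix(X, y, [("c", i) for i in range(len(y))])

    def _synthetic_attention(self, labels_per_contig):
        """One layer, three heads over L=5 contigs: head 0's (i, i+1)
        entries equal the operon labels, head 1 is uniform (constant),
        head 2 is seeded noise."""
        from contiglm.corpus import FORWARD, GeneRecord, SubContig
        from contiglm.inference import SymmetrizedAttention
        rng = np.random.default_rng(0)
        attns, contigs = [], []
        for ci, labs in enumerate(labels_per_contig):
            L = len(labs) + 1
            mats = np.zeros((1, 3, L, L))
            idx = np.arange(L - 1)
            mats[0, 0, idx, idx + 1] = labs
            mats[0, 1] = 1.0 / L
            mats[0, 2] = rng.random((L, L))
            mats = 0.5 * (mats + np.swapaxes(mats, -1, -2))
            mats[0, 0, idx, idx + 1] = labs   # keep exact after symmetrize
            attns.append(SymmetrizedAttention(mats, True))
            genes = [GeneRecord(f"c{ci}g{i}", np.ones(2) * i, FORWARD)
                     for i in range(L)]
            contigs.append(SubContig(f"c{ci}", genes, np.array(labs, bool)))
        return attns, contigs

    def test_label_equal_attention_head_gives_rho_one(self):
        from contiglm.downstream import head_operon_correlation
        attns, contigs = self._synthetic_attention(
            [[0, 1, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]])
        df = head_operon_correlation(attns, contigs)
        perfect = df[(df["layer"] == 0) & (df["head"] == 0)].iloc[0]
        assert perfect.rho == pytest.approx(1.0)
        assert perfect.p_bonferroni <= 3 * perfect.p
        constant = df[(df["layer"] == 0) & (df["head"] == 1)].iloc[0]
        assert np.isnan(constant.rho)     # undefined, reported missing

    def test_permuted_labels_match_null_distribution(self):
        rng = np.random.default_rng(5)
        n = 400
        X = rng.random((n, 8))
        y = rng.random(n) < 0.3
        fm = self._fm(X, y)
        rhos = [stats.pearsonr(X[:, h], rng.permutation(y).astype(float))[0]
                for h in range(8) for _ in range(30)]
        # 95th percentile of |rho| under the null ~ 1.96/sqrt(n)
        assert np.quantile(np.abs(rhos), 0.95) < 3.5 / np.sqrt(n)

    def test_separable_features_reach_ap_one(self):
        rng = np.random.default_rng(6)
        y = np.r_[np.ones(50, bool), np.zeros(150, bool)]
        X = y[:, None] * 2.0 + rng.random((200, 3)) * 0.1
        res = train_operon_classifier(self._fm(X, y), k=5)
        assert res.mean_ap == pytest.approx(1.0)
        assert res.prevalence == pytest.approx(0.25)

    def test_uninformative_features_near_prevalence(self):
        rng = np.random.default_rng(7)
        y = rng.random(600) < 0.3
        X = rng.random((600, 10))
        res = train_operon_classifier(self._fm(X, y), k=5)
        assert abs(res.mean_ap - y.mean()) < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_operon_classifier(self._fm(np.random.rand(20, 2),
                                             np.zeros(20, bool)))


class TestLinearProbe:
    def test_separable_blobs_perfect(self):
        rng = np.random.default_rng(8)
        X0 = rng.standard_normal((100, 4))
        X1 = rng.standard_normal((100, 4)) + 8.0
        X = np.vstack([X0, X1])
        y = np.array(["a"] * 100 + ["b"] * 100)
        idx = rng.permutation(200)
        res = linear_probe((X[idx[:150]], y[idx[:150]]),
                           (X[idx[150:]], y[idx[150:]]))
        assert res.accuracy == 1.0
        assert res.mean_average_precision == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((600, 6))
        y = rng.choice(list("abcd"), size=600)
        res = linear_probe((X[:450], y[:450]), (X[450:], y[450:]))
        assert abs(res.accuracy - 0.25) < 0.12

    def test_missing_train_class_rejected(self):
        X = np.random.rand(20, 3)
        with pytest.raises(ValueError):
            linear_probe((X, ["a"] * 20), (X, ["a"] * 10 + ["b"] * 10))

    def test_f1_comparison_bh_adjusts(self):
        from contiglm.downstream import ProbeResult, compare_probe_f1
        mk = lambda f1a, f1b: (
            [ProbeResult(0.5, {"x": f1a + e, "y": 0.5}, 0.5, ["x", "y"])
             for e in (0, .01, -.01, .02, -.02)],
            [ProbeResult(0.5, {"x": f1b + e, "y": 0.5}, 0.5, ["x", "y"])
             for e in (0, .01, -.01, .02, -.02)])
        a, b = mk(0.9, 0.2)
        df = compare_probe_f1(a, b)
        assert df.set_index("class").loc["x", "p_bh"] < 0.05
        assert df.set_index("class").loc["y", "p_bh"] == 1.0


class TestParalogChance:
    def test_simulator_reproducible_and_bounded(self):
        rng = np.random.default_rng(10)
        cand = rng.standard_normal((40, 6))
        a = paralog_chance_simulation(cand, [3, 7, 11], n_iter=50, seed=1)
        b = paralog_chance_simulation(cand, [3, 7, 11], n_iter=50, seed=1)
        np.testing.assert_array_equal(a, b)
        assert a.max() <= 3 and a.min() >= 0

    def test_single_candidate_always_matches(self):
        cand = np.zeros((1, 4))
        counts = paralog_chance_simulation(cand, [0, 0], n_iter=10, seed=0)
        assert (counts == 2).all()


class TestTaxonomyAndSilhouette:
    def test_disjoint_classes_high_ap_and_null_at_prevalence(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.standard_normal((50, 5)) + 6,
                       rng.standard_normal((50, 5))])
        y = ["arch"] * 50 + ["bact"] * 50
        res = taxonomy_classifier(X, y, k=5)
        assert res.mean_ap > 0.95
        perm = rng.permutation(y)
        null = taxonomy_classifier(X, list(perm), k=5)
        assert null.mean_ap < 0.75
        assert res.confusion.sum() == 100

    def test_identical_embeddings_at_chance(self):
        X = np.ones((40, 3))
        y = ["a"] * 20 + ["b"] * 20
        res = taxonomy_classifier(X, y, k=5)
        assert abs(res.mean_ap - 0.5) < 0.1

    def test_small_class_rejected_by_name(self):
        X = np.random.rand(12, 2)
        y = ["a"] * 9 + ["rare"] * 3
        with pytest.raises(ValueError, match="rare"):
            taxonomy_classifier(X, y, k=5)

    def test_silhouette_limits(self):
        rng = np.random.default_rng(12)
        tight = np.vstack([rng.standard_normal((30, 3)) * 0.01,
                           rng.standard_normal((30, 3)) * 0.01 + 100])
        labels = ["a"] * 30 + ["b"] * 30
        assert silhouette(tight, labels) > 0.99
        one_blob = rng.standard_normal((60, 3))
        assert abs(silhouette(one_blob, labels)) < 0.1

    def test_silhouette_validation(self):
        with pytest.raises(ValueError):
            silhouette(np.random.rand(5, 2), ["a"] * 5)
        with pytest.raises(ValueError):
            silhouette(np.random.rand(2, 2), ["a", "b"])
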