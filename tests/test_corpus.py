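"""Normalization, label construction, masking and corpus IO."""

import numpy as np
import pytest

from contiglm import corpus as cio
from contiglm import synthetic as syn
from contiglm.corpus import (FORWARD, REVERSE, GeneRecord, SubContig,
                             apply_normalizer, contig_labels,
                             fit_label_projector, fit_normalizer, make_label,
                             mask_batch)


def gene(gid, emb, ori=FORWARD):
    return GeneRecord(gid, np.asarray(emb, float), ori)


class TestNormalizer:
    def test_two_point_statistics(self):
        norm = fit_normalizer([gene("a", [0, 0]), gene("b", [2, 2])])
        np.testing.assert_allclose(norm.feature_means, [1, 1])
        np.testing.assert_allclose(norm.feature_stds, [1, 1])  # population sd
        refit = fit_normalizer([gene("a", [0, 0]), gene("b", [2, 2])])
        np.testing.assert_array_equal(norm.feature_means, refit.feature_means)

    def test_constant_feature_maps_to_zero(self):
        norm = fit_normalizer([gene("a", [5.0, 1.0]), gene("b", [5.0, 3.0])])
        assert norm.feature_stds[0] == 1.0
        out = apply_normalizer(norm, gene("c", [5.0, 2.0]))
        assert out.embedding[0] == 0.0

    def test_outlier_clipped_to_bound_exactly(self):
        norm = fit_normalizer([gene("a", [0.0]), gene("b", [2.0])],
                              clip_bound=10.0)
        out = apply_normalizer(norm, gene("c", [1e6]))
        assert out.embedding[0] == 10.0

    @pytest.mark.parametrize("mult,expect", [(0, 0.0), (3, 3.0), (20, 10.0)])
    def test_zscore_then_clip(self, mult, expect):
        rng = np.random.default_rng(0)
        embs = rng.standard_normal((50, 4))
        genes = [gene(f"g{i}", e) for i, e in enumerate(embs)]
        norm = fit_normalizer(genes, clip_bound=10.0)
        out = apply_normalizer(
            norm, gene("q", norm.feature_means + mult * norm.feature_stds))
        np.testing.assert_allclose(out.embedding, expect, atol=1e-12)

    def test_bound_holds_for_any_input(self):
        rng = np.random.default_rng(1)
        genes = [gene(f"g{i}", e) for i, e in
                 enumerate(rng.standard_normal((20, 3)))]
        norm = fit_normalizer(genes, clip_bound=10.0)
        wild = apply_normalizer(norm, gene("w", [1e9, -1e9, 0.0]))
        assert np.abs(wild.embedding).max() <= 10.0

    def test_shape_mismatch_raises(self):
        norm = fit_normalizer([gene("a", [0, 0]), gene("b", [1, 1])])
        with pytest.raises(ValueError):
            apply_normalizer(norm, gene("c", [1, 2, 3]))


class TestLabelProjector:
    def test_whitened_scores_have_unit_variance(self):
        rng = np.random.default_rng(0)
        embs = rng.standard_normal((10_000, 6))
        genes = [gene(f"g{i}", e) for i, e in enumerate(embs)]
        proj = fit_label_projector(genes, k_pc=2)
        scores = np.stack([proj.project(e) for e in embs])
        np.testing.assert_allclose(scores.var(axis=0, ddof=1), 1.0, atol=0.05)
        # components uncorrelated
        assert abs(np.corrcoef(scores.T)[0, 1]) < 0.05
        # rows orthonormal
        np.testing.assert_allclose(proj.components @ proj.components.T,
                                   np.eye(2), atol=1e-10)

    def test_rank_one_data_fully_explained(self):
        t = np.linspace(-1, 1, 50)
        embs = np.outer(t, [1.0, 2.0, -1.0])
        genes = [gene(f"g{i}", e) for i, e in enumerate(embs)]
        proj = fit_label_projector(genes, k_pc=1)
        assert proj.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_refit_is_identical_with_fixed_sign_convention(self):
        rng = np.random.default_rng(2)
        embs = rng.standard_normal((200, 5))
        genes = [gene(f"g{i}", e) for i, e in enumerate(embs)]
        a = fit_label_projector(genes, k_pc=3)
        b = fit_label_projector(genes, k_pc=3)
        np.testing.assert_array_equal(a.components, b.components)
        for row in a.components:
            assert row[np.abs(row).argmax()] > 0

    def test_parameter_errors(self):
        genes = [gene(f"g{i}", np.arange(3.0) + i) for i in range(4)]
        with pytest.raises(ValueError):
            fit_label_projector(genes, k_pc=3)   # k_pc >= E
        with pytest.raises(ValueError):
            fit_label_projector(genes, k_pc=5)   # k_pc >= corpus size


class TestMakeLabel:
    @pytest.fixture()
    def proj(self):
        rng = np.random.default_rng(3)
        genes = [gene(f"g{i}", e) for i, e in
                 enumerate(rng.standard_normal((100, 4)))]
        return fit_label_projector(genes, k_pc=2)

    def test_mean_maps_to_origin(self, proj):
        lab = make_label(proj, gene("q", proj.pca_mean, FORWARD))
        np.testing.assert_allclose(lab, [0, 0, 0.5], atol=1e-12)

    def test_orientation_is_last_coordinate(self, proj):
        emb = proj.pca_mean + 1.0
        f = make_label(proj, gene("q", emb, FORWARD))
        r = make_label(proj, gene("q", emb, REVERSE))
        np.testing.assert_array_equal(f[:-1], r[:-1])
        assert (f[-1], r[-1]) == (0.5, -0.5)

    def test_full_scale_label_width(self):
        rng = np.random.default_rng(4)
        genes = [gene(f"g{i}", e) for i, e in
                 enumerate(rng.standard_normal((150, 120)))]
        proj = fit_label_projector(genes, k_pc=99)
        assert proj.label_dim == 100
        assert make_label(proj, genes[0]).shape == (100,)


class TestMaskBatch:
    @pytest.fixture()
    def setup(self):
        cat = syn.build_family_catalog(6, 8, 0.1, seed=0)
        corpus = syn.sample_corpus(cat, [], [], 60, (15, 15), seed=1)
        genes = [g for c in corpus.contigs for g in c.genes]
        proj = fit_label_projector(genes, k_pc=4)
        return corpus.contigs, proj

    def test_at_least_one_mask_per_contig(self, setup):
        contigs, proj = setup
        batch = mask_batch(contigs, 0.02, proj, seed=0)
        masked_per = np.zeros(len(contigs), int)
        for b, _ in batch.masked_positions:
            masked_per[b] += 1
        assert masked_per.min() >= 1

    def test_masked_tokens_are_constant_minus_one(self, setup):
        contigs, proj = setup
        batch = mask_batch(contigs, 0.15, proj, seed=1)
        for b, i in batch.masked_positions:
            np.testing.assert_array_equal(batch.tokens[b, i],
                                          -np.ones(batch.tokens.shape[-1]))

    def test_labels_match_unmasked_records(self, setup):
        contigs, proj = setup
        batch = mask_batch(contigs, 0.15, proj, seed=2)
        for k, (b, i) in enumerate(batch.masked_positions):
            np.testing.assert_array_equal(
                batch.labels[k], make_label(proj, contigs[b].genes[i]))
            assert batch.labels[k][-1] == contigs[b].genes[i].orientation

    def test_empirical_rate(self):
        cat = syn.build_family_catalog(6, 8, 0.1, seed=0)
        corpus = syn.sample_corpus(cat, [], [], 10_000, (30, 30), seed=1)
        genes = [g for c in corpus.contigs[:50] for g in c.genes]
        proj = fit_label_projector(genes, k_pc=4)
        batch = mask_batch(corpus.contigs, 0.15, proj, seed=3)
        rate = batch.n_masked / (10_000 * 30)
        assert abs(rate - 0.15) < 0.005

    def test_rate_validation(self, setup):
        contigs, proj = setup
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                mask_batch(contigs, bad, proj, seed=0)

    def test_padding_never_masked_or_attended(self, setup):
        contigs, proj = setup
        mixed = contigs[:3] + [SubContig("short", contigs[0].genes[:5])]
        batch = mask_batch(mixed, 0.3, proj, seed=4)
        assert batch.attention_mask[3, 5:].sum() == 0
        for b, i in batch.masked_positions:
            assert batch.attention_mask[b, i]


class TestCorpusIO:
    def _corpus(self):
        cat = syn.build_family_catalog(4, 6, 0.1, seed=0)
        c = syn.sample_corpus(cat, [syn.OperonTemplate((0, 1), 0.5)], [],
                              3, (4, 6), seed=1)
        return c.contigs

    def test_round_trip(self, tmp_path):
        contigs = self._corpus()
        cio.write_corpus(contigs, tmp_path / "corp")
        back = cio.read_corpus(tmp_path / "corp")
        assert len(back) == len(contigs)
        for a, b in zip(contigs, back):
            assert a.contig_id == b.contig_id
            np.testing.assert_array_equal(a.operon_pairs, b.operon_pairs)
            for ga, gb in zip(a.genes, b.genes):
                assert (ga.gene_id, ga.orientation, ga.family_id) == \
                    (gb.gene_id, gb.orientation, gb.family_id)
                np.testing.assert_array_equal(ga.embedding, gb.embedding)

    def test_malformed_index_line_names_line(self, tmp_path):
        contigs = self._corpus()
        cio.write_corpus(contigs, tmp_path / "corp")
        idx = tmp_path / "corp" / "index.jsonl"
        lines = idx.read_text().splitlines()
        lines[1] = "{broken json"
        idx.write_text("\n".join(lines) + "\n")
        with pytest.raises(cio.CorpusFormatError, match="line 2"):
            cio.read_corpus(tmp_path / "corp")

    def test_truncated_blob_raises_not_partial(self, tmp_path):
        contigs = self._corpus()
        cio.write_corpus(contigs, tmp_path / "corp")
        blob = tmp_path / "corp" / "embeddings.npz"
        blob.write_bytes(blob.read_bytes()[:40])
        with pytest.raises(cio.CorpusFormatError):
            cio.read_corpus(tmp_path / "corp")

    def test_missing_gene_embedding(self, tmp_path):
        contigs = self._corpus()
        cio.write_corpus(contigs, tmp_path / "corp")
        arrays = dict(np.load(tmp_path / "corp" / "embeddings.npz"))
        arrays.pop(contigs[0].genes[0].gene_id)
        np.savez(tmp_path / "corp" / "embeddings.npz", **arrays)
        with pytest.raises(cio.CorpusFormatError, match="missing"):
            cio.read_corpus(tmp_path / "corp")

    def test_empty_corpus_warns(self, tmp_path):
        (tmp_path / "corp").mkdir()
        (tmp_path / "corp" / "index.jsonl").write_text("")
        np.savez(tmp_path / "corp" / "embeddings.npz")
        with pytest.warns(UserWarning, match="empty"):
            assert cio.read_corpus(tmp_path / "corp") == []

    def test_tsv_fixture_reader(self, tmp_path):
        tsv = tmp_path / "fix.tsv"
        tsv.write_text(
            "# contig gene ori fam emb...\n"
            "c1\tg1\t0.5\tFA\t1.0\t2.0\n"
            "c1\tg2\t-0.5\t-\t0.5\t0.25\n"
            "c2\tg3\t0.5\tFB\t0\t1\n"
            "c2\tg4\t0.5\tFB\t1\t0\n")
        contigs = cio.read_corpus_tsv(tsv)
        assert [c.contig_id for c in contigs] == ["c1", "c2"]
        assert contigs[0].genes[1].family_id is None
        np.testing.assert_array_equal(contigs[0].genes[0].embedding, [1, 2])

    def test_operon_pairs_tsv(self, tmp_path):
        contigs = self._corpus()
        pairs = tmp_path / "ops.tsv"
        g = contigs[0].genes
        pairs.write_text(f"{g[0].gene_id}\t{g[1].gene_id}\n")
        out = cio.read_operon_pairs_tsv(pairs, contigs)
        assert out[0].operon_pairs[0]
        assert not out[0].operon_pairs[1:].any()


def test_gene_record_validation():
    with pytest.raises(ValueError):
        GeneRecord("g", np.ones(3), 1.0)
    with pytest.raises(ValueError):
        GeneRecord("g", np.array([np.inf, 0.0]), FORWARD)
    with pytest.raises(ValueError):
        SubContig("c", [gene("g", [1, 2])])


def test_contig_labels_shape():
    rng = np.random.default_rng(5)
    genes = [gene(f"g{i}", e) for i, e in
             enumerate(rng.standard_normal((30, 4)))]
    proj = fit_label_projector(genes, k_pc=2)
    contig = SubContig("c", genes[:6])
    labs = contig_labels(proj, contig)
    assert labs.shape == (6, 3)
    np.testing.assert_array_equal(labs[:, -1], [g.orientation
                                                for g in genes[:6]])
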