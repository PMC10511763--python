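"""Quantile normalization, XPN/CuBlock transforms, rescaling and the pipeline."""

import numpy as np
import pandas as pd
import pytest

import shambhala as sh
from shambhala.harmonize import (
    CuBlockParams,
    HarmonizationConfig,
    XPNParams,
    intersect_and_filter_genes,
    quantile_normalize,
    rescale,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# gene intersection
# ---------------------------------------------------------------------------

class TestIntersectGenes:
    def _mats(self, *gene_sets):
        return [make_matrix(np.ones((len(g), 2)), genes=list(g)) for g in gene_sets]

    def test_intersection_is_sorted(self):
        R, P, Q = self._mats("abc", "bcd", "cb")
        assert intersect_and_filter_genes(R, P, Q) == ["b", "c"]

    def test_identical_sets_all_retained(self):
        genes = [f"g{i}" for i in range(100)]
        R, P, Q = self._mats(genes, genes, genes)
        assert intersect_and_filter_genes(R, P, Q) == sorted(genes)

    def test_disjoint_sets_error(self):
        R, P, Q = self._mats("ab", "cd", "ef")
        with pytest.raises(ValueError, match="namespace"):
            intersect_and_filter_genes(R, P, Q)

    def test_top_n_by_p_median(self):
        R = make_matrix(np.ones((3, 2)), genes=["a", "b", "c"])
        P = make_matrix([[1, 1], [9, 9], [5, 5]], genes=["a", "b", "c"])
        Q = make_matrix(np.ones((3, 2)), genes=["a", "b", "c"])
        assert intersect_and_filter_genes(R, P, Q, top_n_by_p_median=2) == ["b", "c"]


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def test_hand_example_two_samples(self):
        m = make_matrix(np.array([[2, 1], [4, 3], [6, 5]], dtype=float))
        q = quantile_normalize(m)
        np.testing.assert_allclose(q.values, [[1.5, 1.5], [3.5, 3.5], [5.5, 5.5]])

    def test_rank_order_preserved(self):
        m = make_matrix(np.array([[2, 5], [4, 1], [6, 3]], dtype=float))
        q = quantile_normalize(m)
        for j in range(2):
            assert (np.argsort(q.values[:, j]) == np.argsort(m.values[:, j])).all()

    def test_identical_samples_fixed_point(self):
        col = np.array([3.0, 1.0, 7.0, 5.0])
        m = make_matrix(np.column_stack([col, col, col]))
        np.testing.assert_allclose(quantile_normalize(m).values, m.values)

    def test_idempotence(self, random_matrix):
        m = random_matrix(40, 6, seed=5)
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_ties_averaged(self):
        # sample 1 has a two-way tie: both tied entries share the mean reference
        m = make_matrix(np.array([[1, 1], [1, 2], [5, 3]], dtype=float))
        q = quantile_normalize(m)
        assert q.values[0, 0] == q.values[1, 0]

    def test_single_sample_identity_with_warning(self, caplog):
        m = make_matrix([[1.0], [2.0]])
        with caplog.at_level("WARNING", logger="shambhala"):
            q = quantile_normalize(m)
        np.testing.assert_allclose(q.values, m.values)
        assert "single-sample" in caplog.text


# ---------------------------------------------------------------------------
# XPN transform
# ---------------------------------------------------------------------------

def _xpn_params():
    return XPNParams(gene_clusters=8, sample_clusters=3, n_repeats=3)


class TestXpnTransform:
    def test_null_distortion_is_near_identity(self, random_matrix):
        # P' statistically identical to Q (same generator draw, renamed samples)
        Q = random_matrix(300, 25, seed=11, role="Q")
        P = make_matrix(Q.values, genes=list(Q.gene_ids),
                        samples=[f"p{j}" for j in range(25)], role="Pprime")
        out = sh.xpn_transform(P, Q, _xpn_params(), seed=1)
        shift = np.abs(out.values.mean(axis=1) - P.values.mean(axis=1)).mean()
        assert shift < 0.05

    def test_constant_shift_absorbed(self, random_matrix):
        Q = random_matrix(300, 25, seed=13, role="Q")
        P = make_matrix(Q.values + 3.0, genes=list(Q.gene_ids), role="Pprime")
        out = sh.xpn_transform(P, Q, _xpn_params(), seed=2)
        resid = np.abs(out.values.mean(axis=1) - Q.values.mean(axis=1)).mean()
        assert resid < 0.1

    def test_seeded_determinism(self, random_matrix):
        Q = random_matrix(200, 20, seed=14, role="Q")
        P = random_matrix(200, 20, seed=15, role="Pprime")
        a = sh.xpn_transform(P, Q, XPNParams(gene_clusters=6, sample_clusters=3, n_repeats=2), seed=9)
        b = sh.xpn_transform(P, Q, XPNParams(gene_clusters=6, sample_clusters=3, n_repeats=2), seed=9)
        assert np.array_equal(a.values, b.values)

    def test_symmetric_weights_land_midway(self, random_matrix):
        # classic XPN averaging: with equal platform weights a +3 shift is
        # only half absorbed, the fused model sitting between the platforms
        Q = random_matrix(300, 25, seed=16, role="Q")
        P = make_matrix(Q.values + 3.0, genes=list(Q.gene_ids), role="Pprime")
        params = XPNParams(gene_clusters=8, sample_clusters=3, n_repeats=3,
                           reference_weight=0.5)
        out = sh.xpn_transform(P, Q, params, seed=6)
        mid_shift = (out.values.mean(axis=1) - Q.values.mean(axis=1)).mean()
        assert 1.0 < mid_shift < 2.0

    def test_too_many_clusters_error(self, random_matrix):
        Q = random_matrix(10, 20, seed=1, role="Q")
        P = random_matrix(10, 20, seed=2, role="Pprime")
        with pytest.raises(ValueError, match="gene clusters"):
            sh.xpn_transform(P, Q, XPNParams(gene_clusters=50, sample_clusters=3), seed=0)


# ---------------------------------------------------------------------------
# CuBlock transform
# ---------------------------------------------------------------------------

def _zscore(vals):
    return (vals - vals.mean(1, keepdims=True)) / vals.std(1, ddof=1, keepdims=True)


class TestCublockTransform:
    def test_identity_fixed_point_on_z_scale(self, random_matrix):
        Q = random_matrix(200, 30, seed=21, role="Q")
        out = sh.cublock_transform(Q.with_role("Pprime"), Q, CuBlockParams(n_blocks=4), seed=3)
        np.testing.assert_allclose(out.values, _zscore(Q.values), atol=1e-6)

    def test_cubic_distortion_recovered_single_block(self, random_matrix):
        # P' carries a cube-root distortion of Q's z-scores, so the quantile
        # map P' -> Q is exactly a cubic and a single block recovers it
        Q = random_matrix(400, 60, seed=22, role="Q")
        zq = _zscore(Q.values)
        P = make_matrix(np.cbrt(zq), genes=list(Q.gene_ids), role="Pprime")
        out = sh.cublock_transform(P, Q, CuBlockParams(n_blocks=1), seed=4)
        rmse = np.sqrt(np.mean((np.sort(out.values.ravel()) - np.sort(zq.ravel())) ** 2))
        assert rmse < 0.1

    def test_seeded_determinism(self, random_matrix):
        Q = random_matrix(150, 20, seed=23, role="Q")
        P = random_matrix(150, 20, seed=24, role="Pprime")
        a = sh.cublock_transform(P, Q, CuBlockParams(n_blocks=5), seed=8)
        b = sh.cublock_transform(P, Q, CuBlockParams(n_blocks=5), seed=8)
        assert np.array_equal(a.values, b.values)

    def test_monotone_clamp_keeps_output_ordered(self, random_matrix):
        Q = random_matrix(300, 25, seed=25, role="Q")
        P = random_matrix(300, 25, seed=26, role="Pprime")
        out = sh.cublock_transform(P, Q, CuBlockParams(n_blocks=3, clamp=True), seed=5)
        # within one gene, input order must be preserved (monotone map per block)
        for g in range(0, 300, 50):
            order_in = np.argsort(P.values[g])
            assert np.all(np.diff(out.values[g][order_in]) >= -1e-12)

    def test_tiny_block_linear_fallback(self, caplog):
        Q = make_matrix(np.random.default_rng(0).normal(size=(2, 3)), role="Q")
        P = make_matrix(np.random.default_rng(1).normal(size=(2, 3)), genes=list(Q.gene_ids),
                        role="Pprime")
        with caplog.at_level("WARNING", logger="shambhala"):
            sh.cublock_transform(P, Q, CuBlockParams(n_blocks=1), seed=0)
        assert "linear fit" in caplog.text


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

class TestRescale:
    def test_qbr_hand_example(self):
        Hraw = make_matrix([[1.0, 2.0, 3.0]], role="H")
        sumQ = sh.GeneSummary(["g1"], [10.0], [2.0], "Q")
        sumH = sh.gene_summaries(Hraw, "H")
        out = rescale(Hraw, "QBR", sumQ, sumH)
        np.testing.assert_allclose(out.values, [[8.0, 10.0, 12.0]])

    def test_pbr_hand_example(self):
        Hraw = make_matrix([[-1.0, 0.0, 1.0]], role="H")
        sumQ = sh.GeneSummary(["g1"], [5.0], [2.0], "Q")
        out = rescale(Hraw, "PBR", sumQ)
        np.testing.assert_allclose(out.values, [[3.0, 5.0, 7.0]])

    def test_rbr_hand_example(self):
        Hraw = make_matrix([[0.0, 2.0]], role="H")
        sumQ = sh.GeneSummary(["g1"], [0.0], [1.0], "Q")
        sumH = sh.gene_summaries(Hraw, "H")  # mu=1, sigma=sqrt(2)
        sumR = sh.GeneSummary(["g1"], [4.0], [2.0 * np.sqrt(2.0)], "R")
        out = rescale(Hraw, "RBR", sumQ, sumH, sumR)
        np.testing.assert_allclose(out.values, [[2.0, 6.0]])

    def test_qbr_exact_moment_matching(self, random_matrix):
        Hraw = random_matrix(60, 9, seed=31, role="H")
        rng = np.random.default_rng(32)
        sumQ = sh.GeneSummary(list(Hraw.gene_ids), rng.normal(5, 3, 60), rng.uniform(0.5, 4, 60), "Q")
        out = rescale(Hraw, "QBR", sumQ, sh.gene_summaries(Hraw, "H"))
        np.testing.assert_allclose(out.values.mean(axis=1), sumQ.mu, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), sumQ.sigma, atol=1e-9)

    def test_zero_variance_gene_maps_to_target_mean(self, caplog):
        Hraw = make_matrix([[2.0, 2.0, 2.0]], role="H")
        sumQ = sh.GeneSummary(["g1"], [7.0], [3.0], "Q")
        with caplog.at_level("WARNING", logger="shambhala"):
            out = rescale(Hraw, "QBR", sumQ, sh.gene_summaries(Hraw, "H"))
        np.testing.assert_allclose(out.values, [[7.0, 7.0, 7.0]])

    def test_misaligned_summary_error(self):
        Hraw = make_matrix([[1.0, 2.0]], role="H")
        sumQ = sh.GeneSummary(["other"], [0.0], [1.0], "Q")
        with pytest.raises(KeyError, match="absent"):
            rescale(Hraw, "PBR", sumQ)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_world():
    cfg = sh.SyntheticConfig(seed=3, n_genes=400, n_tissues=2, n_per_cell=3,
                             n_aux_samples=16, n_pathways=4, pathway_size=5, planted=[])
    mats, truth = sh.generate_multiplatform(cfg)
    P, Q = sh.generate_auxiliary(cfg)
    return mats, truth, P, Q


class TestShambhalize:
    def test_output_genes_are_the_intersection(self, small_world):
        mats, _, P, Q = small_world
        R = mats[0].subset_samples(list(mats[0].sample_ids[:3]))
        H = sh.shambhalize(R, P, Q, HarmonizationConfig(seed=1))
        expected = sorted(set(R.gene_ids) & set(P.gene_ids) & set(Q.gene_ids))
        assert list(H.gene_ids) == expected
        assert list(H.sample_ids) == list(R.sample_ids)

    def test_pbr_per_sample_independence(self, small_world):
        mats, _, P, Q = small_world
        R = mats[1].subset_samples(list(mats[1].sample_ids[:3]))
        cfg = HarmonizationConfig(method="shambhala2", rescale_mode="PBR", seed=7)
        batch = sh.shambhalize(R, P, Q, cfg)
        alone = sh.shambhalize(R.subset_samples([R.sample_ids[1]]), P, Q, cfg)
        assert np.array_equal(batch.values[:, 1], alone.values[:, 0])

    def test_qbr_depends_on_batch_composition(self, small_world):
        mats, _, P, Q = small_world
        R = mats[0].subset_samples(list(mats[0].sample_ids[:4]))
        cfg = HarmonizationConfig(method="shambhala2", rescale_mode="QBR", seed=7)
        batch = sh.shambhalize(R, P, Q, cfg)
        pair = sh.shambhalize(R.subset_samples(list(R.sample_ids[:2])), P, Q, cfg)
        assert not np.allclose(batch.values[:, 0], pair.values[:, 0])

    def test_qbr_matches_q_moments(self, small_world):
        mats, _, P, Q = small_world
        R = mats[0].subset_samples(list(mats[0].sample_ids[:4]))
        H = sh.shambhalize(R, P, Q, HarmonizationConfig(rescale_mode="QBR", seed=2))
        sq = sh.gene_summaries(Q.subset_genes(list(H.gene_ids)))
        np.testing.assert_allclose(H.values.mean(axis=1), sq.mu, atol=1e-9)
        np.testing.assert_allclose(H.values.std(axis=1, ddof=1), sq.sigma, atol=1e-9)

    def test_seeded_determinism_both_methods(self, small_world):
        mats, _, P, Q = small_world
        R = mats[0].subset_samples(list(mats[0].sample_ids[:2]))
        for method, params in (("shambhala2", {}),):
            cfg = HarmonizationConfig(method=method, seed=11)
            a = sh.shambhalize(R, P, Q, cfg)
            b = sh.shambhalize(R, P, Q, cfg)
            assert np.array_equal(a.values, b.values)

    def test_harmonization_raises_same_tissue_cross_platform_correlation(self, small_world):
        from scipy import stats

        mats, truth, P, Q = small_world
        cfg = HarmonizationConfig(method="shambhala2", rescale_mode="PBR", seed=4)
        H0 = sh.shambhalize(mats[0], P, Q, cfg)
        H1 = sh.shambhalize(mats[1], P, Q, cfg)
        genes = list(H0.gene_ids)
        ann = truth.samples.data

        def med_rho(m0, m1):
            rhos = []
            for t in ann["tissue_type"].unique():
                ids0 = [s for s in m0.sample_ids if ann.loc[s, "tissue_type"] == t]
                ids1 = [s for s in m1.sample_ids if ann.loc[s, "tissue_type"] == t]
                v0 = np.median(m0.values[:, [list(m0.sample_ids).index(s) for s in ids0]], axis=1)
                v1 = np.median(m1.values[:, [list(m1.sample_ids).index(s) for s in ids1]], axis=1)
                rhos.append(stats.spearmanr(v0, v1).statistic)
            return float(np.median(rhos))

        pre = med_rho(mats[0].subset_genes(genes), mats[1].subset_genes(genes))
        post = med_rho(H0, H1)
        assert post > pre

    def test_rbr_matches_r_moments(self, small_world):
        mats, _, P, Q = small_world
        R = mats[0].subset_samples(list(mats[0].sample_ids[:4]))
        H = sh.shambhalize(R, P, Q, HarmonizationConfig(rescale_mode="RBR", seed=2))
        sr = sh.gene_summaries(R.subset_genes(list(H.gene_ids)))
        np.testing.assert_allclose(H.values.mean(axis=1), sr.mu, atol=1e-9)
        np.testing.assert_allclose(H.values.std(axis=1, ddof=1), sr.sigma, atol=1e-9)

    def test_projection_merge_mode_runs_and_differs(self, small_world):
        mats, _, P, Q = small_world
        R = mats[0].subset_samples(list(mats[0].sample_ids[:2]))
        merge = sh.shambhalize(R, P, Q, HarmonizationConfig(seed=5, qn_merge="merge"))
        proj = sh.shambhalize(R, P, Q, HarmonizationConfig(seed=5, qn_merge="project"))
        # the two single-sample merge conventions are close but not identical
        assert not np.array_equal(merge.values, proj.values)
        assert np.abs(merge.values - proj.values).mean() < 0.5

    def test_small_auxiliary_sets_rejected(self, small_world):
        mats, _, P, Q = small_world
        tiny = P.subset_samples(list(P.sample_ids[:5]))
        with pytest.raises(ValueError, match=">= 10 samples"):
            sh.shambhalize(mats[0], tiny, Q, HarmonizationConfig())
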