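"""Normalized-log PCA: filters, blockwise Gram, decomposition, correlates."""

import numpy as np
import pytest
import scipy.sparse as sp

from junctionscope.classify import EvidenceCategory, classify_table
from junctionscope.model import Junction, JunctionTable, SampleMeta
from junctionscope.pca import (
    NormalizedMatrix,
    correlate_components,
    decompose,
    gram_blockwise,
    normalize,
    pca_pipeline,
    select_pca_input,
)

from conftest import random_table


def _meta_for(t, mapped=1000, read_len=76):
    return [
        SampleMeta(s, mapped_reads=mapped, read_length=read_len)
        for s in t.sample_ids
    ]


class TestSelectPCAInput:
    def test_identity_when_all_novel_and_thresholds_trivial(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, n_junctions=20, n_samples=5, density=1.0)
        cats = {j.key: EvidenceCategory.NOVEL for j in t.junctions}
        sub = select_pca_input(t, cats, _meta_for(t), min_prevalence=1, min_reads=0)
        assert sub.junctions == t.junctions and sub.sample_ids == t.sample_ids

    def test_all_annotated_is_empty_error(self):
        rng = np.random.default_rng(1)
        t = random_table(rng, n_junctions=10, n_samples=4)
        cats = {j.key: EvidenceCategory.FULLY_ANNOTATED for j in t.junctions}
        with pytest.raises(ValueError, match="unannotated"):
            select_pca_input(t, cats, _meta_for(t), 1, 0)

    def test_matches_bruteforce_filter(self, small_cohort):
        _, ann, table, meta = small_cohort
        cats, _ = classify_table(table, ann.index)
        min_prev, min_reads = 10, 300_000
        sub = select_pca_input(table, cats, meta, min_prev, min_reads)
        prev = dict(zip([j.key for j in table.junctions],
                        table.sample_prevalence()))
        expected_j = [
            j for j in table.junctions
            if cats[j.key] is not EvidenceCategory.FULLY_ANNOTATED
            and prev[j.key] >= min_prev
        ]
        reads = {m.sample_id: m.mapped_reads for m in meta}
        expected_s = [s for s in table.sample_ids if reads[s] >= min_reads]
        assert sub.junctions == expected_j
        assert sub.sample_ids == expected_s

    def test_novel_only_flag(self, small_cohort):
        _, ann, table, meta = small_cohort
        cats, _ = classify_table(table, ann.index)
        sub = select_pca_input(table, cats, meta, 1, 0, unannotated="novel")
        assert all(cats[j.key] is EvidenceCategory.NOVEL for j in sub.junctions)


class TestNormalize:
    def test_log2_values(self):
        j = Junction("chr1", 10, 90, "+")
        t = JunctionTable([j], ["a", "b"], sp.csr_matrix(np.array([[0, 100]])))
        meta = [SampleMeta("a", mapped_reads=100),
                SampleMeta("b", mapped_reads=100)]
        nm = normalize(t, meta)
        x = nm.x.toarray()
        assert x[0, 0] == 0.0  # zero count stays exactly zero
        assert x[0, 1] == pytest.approx(1.0)  # c == C -> log2(2)

    def test_zero_mapped_reads_rejected(self):
        j = Junction("chr1", 10, 90, "+")
        t = JunctionTable([j], ["a"], sp.csr_matrix(np.array([[5]])))
        with pytest.raises(ValueError):
            normalize(t, [SampleMeta("a", mapped_reads=0)])

    def test_centered_rows_sum_to_zero_and_match_dense(self):
        rng = np.random.default_rng(2)
        t = random_table(rng, n_junctions=25, n_samples=7)
        meta = _meta_for(t, mapped=50_000)
        nm = normalize(t, meta)
        A = nm.dense_centered()
        assert np.allclose(A.sum(axis=1), 0, atol=1e-9 * t.n_samples)
        dense = np.log2(t.counts.toarray() / 50_000 + 1)
        assert np.allclose(A, dense - dense.mean(axis=1, keepdims=True))


class TestGramBlockwise:
    @pytest.mark.parametrize("block_rows", [1, 3, 7, 1000])
    def test_independent_of_block_size(self, block_rows):
        rng = np.random.default_rng(3)
        t = random_table(rng, n_junctions=40, n_samples=9)
        nm = normalize(t, _meta_for(t, mapped=10_000))
        A = nm.dense_centered()
        ref = A.T @ A
        got = gram_blockwise(nm, block_rows)
        assert np.linalg.norm(got - ref) <= 1e-8 * max(np.linalg.norm(ref), 1)
        assert np.allclose(got, got.T)
        assert np.linalg.eigvalsh(got).min() > -1e-8

    def test_orthonormal_columns_give_identity(self):
        q, _ = np.linalg.qr(np.random.default_rng(4).normal(size=(6, 4)))
        nm = NormalizedMatrix(
            x=sp.csr_matrix(q), row_means=np.zeros(6),
            sample_ids=[f"s{i}" for i in range(4)],
        )
        assert np.allclose(gram_blockwise(nm, 2), np.eye(4), atol=1e-12)


class TestDecompose:
    def test_rank_one_concentrates_variance(self):
        u = np.ones((5, 1)) / np.sqrt(5)
        gram = 7.0 * (u @ u.T)
        res = decompose(gram, 2, [f"s{i}" for i in range(5)])
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_matches_direct_svd_of_A(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(6, 4))
        A -= A.mean(axis=1, keepdims=True)
        res = decompose(A.T @ A, 3, list("abcd"))
        _, s, vt = np.linalg.svd(A, full_matrices=False)
        assert np.allclose(res.singular_values[:3], s[:3], atol=1e-8)
        total = (s**2).sum()
        assert np.allclose(res.variance_fraction[:3], s[:3] ** 2 / total,
                           atol=1e-8)
        for k in range(3):
            dot = abs(res.components[:, k] @ vt[k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_full_decomposition_variance_sums_to_one(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(10, 5))
        res = decompose(A.T @ A, 5, [f"s{i}" for i in range(5)])
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(res.components.T @ res.components, np.eye(5),
                           atol=1e-8)

    def test_randomized_matches_exact_on_decaying_spectrum(self):
        rng = np.random.default_rng(7)
        # 50 x 30 with geometrically decaying singular values
        u, _ = np.linalg.qr(rng.normal(size=(50, 30)))
        v, _ = np.linalg.qr(rng.normal(size=(30, 30)))
        s = 10.0 * 0.7 ** np.arange(30)
        A = u @ np.diag(s) @ v.T
        gram = A.T @ A
        sids = [f"s{i}" for i in range(30)]
        exact = decompose(gram, 5, sids, method="exact")
        rand = decompose(gram, 5, sids, method="randomized", seed=0)
        assert np.allclose(
            exact.variance_fraction, rand.variance_fraction, atol=1e-6
        )

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            decompose(np.eye(3), 4, list("abc"))


class TestPipelineEquivalence:
    @pytest.mark.parametrize("shape", [(20, 10), (200, 100)])
    def test_pipeline_equals_direct_dense_svd(self, shape):
        """normalize -> blockwise Gram -> exact eig == dense SVD of A."""
        rng = np.random.default_rng(8)
        n, m = shape
        t = random_table(rng, n_junctions=n, n_samples=m, density=0.3)
        meta = _meta_for(t, mapped=200_000)
        nm = normalize(t, meta)
        gram = gram_blockwise(nm, block_rows=17)
        k = 5
        res = decompose(gram, k, nm.sample_ids)
        A = nm.dense_centered()
        _, s, vt = np.linalg.svd(A, full_matrices=False)
        assert np.allclose(res.variance_fraction[:k], s[:k] ** 2 / (s**2).sum(),
                           atol=1e-8)
        for i in range(k):
            assert abs(res.components[:, i] @ vt[i]) == pytest.approx(1.0,
                                                                      abs=1e-7)

    def test_scale_invariance(self):
        """Scaling all counts and all C_j by one constant leaves x unchanged."""
        rng = np.random.default_rng(9)
        t = random_table(rng, n_junctions=30, n_samples=6)
        m1 = _meta_for(t, mapped=10_000)
        t10 = JunctionTable(t.junctions, t.sample_ids, t.counts * 10)
        m10 = _meta_for(t, mapped=100_000)
        x1 = normalize(t, m1).x.toarray()
        x10 = normalize(t10, m10).x.toarray()
        assert np.allclose(x1, x10)


class TestCorrelates:
    def test_pc_proportional_to_depth_has_r_one(self):
        # construct x whose column sums equal PC1 exactly
        rng = np.random.default_rng(10)
        t = random_table(rng, n_junctions=30, n_samples=8, density=1.0)
        meta = _meta_for(t)
        nm = normalize(t, meta)
        s_j = np.asarray(nm.x.sum(axis=0)).ravel()
        res = decompose(np.outer(s_j, s_j), 1, nm.sample_ids)
        corr = correlate_components(res, nm, meta)
        assert corr.loc["s_depth", "r_pc1"] == pytest.approx(1.0)

    def test_zero_variance_correlate_flagged_not_zero(self):
        rng = np.random.default_rng(11)
        t = random_table(rng, n_junctions=20, n_samples=6, density=1.0)
        meta = _meta_for(t, read_len=76)  # constant read length
        nm = normalize(t, meta)
        res = decompose(gram_blockwise(nm, 5), 2, nm.sample_ids)
        corr = correlate_components(res, nm, meta)
        assert not corr.loc["l_read_length", "defined"]
        assert np.isnan(corr.loc["l_read_length", "r_pc1"])
        assert abs(corr.loc["s_depth", "r_pc1"]) <= 1.0

    def test_depth_driven_cohort_has_high_pc1_depth_correlation(self):
        from junctionscope.simulate import (
            depth_driven_config, generate_annotation, generate_cohort,
        )

        cfg = depth_driven_config(seed=0)
        ann = generate_annotation(cfg)
        table, meta = generate_cohort(cfg, ann)
        cats, _ = classify_table(table, ann.index)
        res, corr, _ = pca_pipeline(table, cats, meta, min_prevalence=5,
                                    min_reads=0, n_components=2)
        assert corr.loc["s_depth", "r_pc1"] > 0.9
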