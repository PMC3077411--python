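import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

import litcohesion.semantic as sem
from litcohesion import (
    GeneDocument,
    apply_log_entropy,
    cosine,
    fit_from_documents,
    fit_lsi,
    similarity_matrix,
    top_neighbors,
)
from tests.oracles import (
    best_rank_k_error,
    column_cosine_matrix,
    log_entropy_weights_scalar,
    top_n_sorted,
)


def fit_matrix(weights, k=None, **kw):
    n_terms, n_genes = weights.shape
    terms = [f"t{i}" for i in range(n_terms)]
    genes = [f"g{j}" for j in range(n_genes)]
    return fit_lsi(weights, terms, genes, k=k, **kw)


class TestLogEntropy:
    def test_single_gene_term_has_g_one(self):
        counts = np.array([[5, 0, 0], [1, 1, 1]])
        _, g = apply_log_entropy(counts)
        assert g[0] == pytest.approx(1.0)

    def test_uniform_term_has_g_zero(self):
        counts = np.array([[7, 7, 7, 7], [3, 0, 0, 0]])
        weights, g = apply_log_entropy(counts)
        assert g[0] == pytest.approx(0.0, abs=1e-12)
        assert weights.toarray()[0] == pytest.approx(np.zeros(4), abs=1e-12)

    def test_toy_matrix_matches_scalar_oracle(self):
        counts = np.array(
            [[2, 0, 1, 0],
             [1, 1, 1, 1],
             [0, 3, 0, 5]]
        )
        weights, _ = apply_log_entropy(counts)
        expected = log_entropy_weights_scalar(counts)
        np.testing.assert_allclose(weights.toarray(), expected, atol=1e-12)

    def test_zero_iff_count_zero_or_g_zero(self):
        counts = np.array([[2, 0, 1], [4, 4, 4], [0, 9, 0]])
        weights, g = apply_log_entropy(counts)
        dense = weights.toarray()
        for i in range(3):
            for j in range(3):
                if counts[i, j] == 0 or g[i] < 1e-12:
                    assert dense[i, j] == pytest.approx(0.0, abs=1e-12)
                else:
                    assert dense[i, j] > 0

    def test_single_gene_matrix_rejected(self):
        with pytest.raises(ValueError):
            apply_log_entropy(np.array([[1], [2]]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            apply_log_entropy(np.array([[1, -1]]))

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        )
    )
    def test_g_in_unit_interval(self, rows):
        counts = np.array(rows).T  # 3 terms x n genes
        if (counts.sum(axis=1) == 0).any():
            counts = counts + 1
        _, g = apply_log_entropy(counts)
        assert np.all(g >= 0.0) and np.all(g <= 1.0)

    def test_g_decreases_toward_uniform(self):
        # 2-gene family (1, t): t = 1 is uniform; g grows with skew
        gs = []
        for t in (1, 2, 4, 8, 16):
            _, g = apply_log_entropy(np.array([[1, t], [1, 1]]))
            gs.append(g[0])
        assert gs[0] == pytest.approx(0.0, abs=1e-12)
        assert all(a < b for a, b in zip(gs, gs[1:]))

    def test_weight_scale_leaves_cosines_unchanged(self):
        # a uniform rescale of the weights (e.g. a different log base in the
        # local factor) cannot change any cosine
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 6, size=(12, 6))
        weights, _ = apply_log_entropy(counts)
        m1 = fit_matrix(weights, k=4)
        m2 = fit_matrix(weights * np.log(2.0) ** 2, k=4)
        np.testing.assert_allclose(
            similarity_matrix(m1).cosines, similarity_matrix(m2).cosines,
            atol=1e-10,
        )


class TestFitLsi:
    def test_rank_one_outer_product(self):
        w = np.outer([1.0, 2.0, 3.0], [4.0, 5.0])
        model = fit_matrix(w, k=1)
        assert model.singular_values[0] > 0
        recon = (model.term_factors * model.singular_values) @ (
            model.gene_vectors / model.singular_values
        ).T
        np.testing.assert_allclose(recon, w, atol=1e-10)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        w = rng.random((5, 4))
        model = fit_matrix(w, k=4)
        recon = model.term_factors @ model.gene_vectors.T
        np.testing.assert_allclose(recon, w, atol=1e-10)

    def test_frobenius_error_matches_eigen_oracle(self):
        rng = np.random.default_rng(1)
        w = rng.random((6, 5))
        model = fit_matrix(w, k=2)
        recon = model.term_factors @ model.gene_vectors.T
        err = np.linalg.norm(w - recon, "fro")
        assert err == pytest.approx(best_rank_k_error(w, 2), abs=1e-9)

    def test_singular_values_non_increasing_and_orthonormal_factors(self):
        rng = np.random.default_rng(2)
        model = fit_matrix(rng.random((20, 10)), k=6)
        s = model.singular_values
        assert np.all(s[:-1] >= s[1:] - 1e-12)
        np.testing.assert_allclose(
            model.term_factors.T @ model.term_factors, np.eye(6), atol=1e-10
        )

    def test_monotone_reconstruction_error_in_k(self):
        rng = np.random.default_rng(3)
        w = rng.random((15, 8))
        errs = []
        for k in range(1, 9):
            model = fit_matrix(w, k=k)
            recon = model.term_factors @ model.gene_vectors.T
            errs.append(np.linalg.norm(w - recon, "fro"))
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    @pytest.mark.parametrize("k", [0, -1, 99])
    def test_bad_k_rejected(self, k):
        with pytest.raises(ValueError):
            fit_matrix(np.ones((4, 3)), k=k)

    def test_default_k_capped_at_rank(self):
        w = np.outer(np.arange(1, 7), np.arange(1, 5))  # rank 1
        model = fit_matrix(w)
        assert model.rank == 1

    def test_sparse_and_dense_paths_agree(self, monkeypatch):
        rng = np.random.default_rng(4)
        w = rng.random((40, 25))
        dense_model = fit_matrix(w, k=5)
        monkeypatch.setattr(sem, "_DENSE_SVD_LIMIT", 0)
        sparse_model = fit_matrix(sp.csr_matrix(w), k=5)
        np.testing.assert_allclose(
            similarity_matrix(dense_model).cosines,
            similarity_matrix(sparse_model).cosines,
            atol=1e-8,
        )

    def test_unscaled_gene_vectors_option(self):
        rng = np.random.default_rng(6)
        w = rng.random((10, 6))
        scaled = fit_matrix(w, k=3)
        plain = fit_matrix(w, k=3, scale_by_singular_values=False)
        np.testing.assert_allclose(
            plain.gene_vectors * scaled.singular_values,
            scaled.gene_vectors,
            atol=1e-10,
        )


class TestCosine:
    def test_identical_documents_have_cosine_one(self):
        docs = [
            GeneDocument("a", "kinase binds receptor kinase", 1),
            GeneDocument("b", "kinase binds receptor kinase", 1),
            GeneDocument("c", "channel gates sodium flux", 1),
        ]
        model, _ = fit_from_documents(docs)
        assert cosine(model, "a", "b") == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, model):
        genes = model.genes[:8]
        for a in genes:
            for b in genes:
                assert cosine(model, a, b) == pytest.approx(
                    cosine(model, b, a), abs=1e-12
                )

    def test_self_cosine_is_one(self, model):
        assert cosine(model, model.genes[0], model.genes[0]) == 1.0

    def test_unknown_gene_named_in_error(self, model):
        with pytest.raises(KeyError, match="nope"):
            cosine(model, model.genes[0], "nope")

    def test_full_rank_cosine_equals_direct_column_cosine(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 5, size=(30, 12))
        counts[0] += 1  # no all-zero gene columns
        weights, _ = apply_log_entropy(counts)
        dense = weights.toarray()
        k = np.linalg.matrix_rank(dense)
        model = fit_matrix(dense, k=k)
        np.testing.assert_allclose(
            similarity_matrix(model).cosines,
            column_cosine_matrix(dense),
            atol=1e-8,
        )

    def test_zero_vector_gene_scores_zero_with_warning(self):
        model = sem.LsiModel(
            rank=2,
            terms=["t0", "t1"],
            genes=["a", "z"],
            term_factors=np.eye(2),
            singular_values=np.array([1.0, 0.5]),
            gene_vectors=np.array([[1.0, 0.0], [0.0, 0.0]]),
        )
        with pytest.warns(RuntimeWarning):
            assert cosine(model, "a", "z") == 0.0


class TestSimilarityMatrix:
    def test_single_gene_matrix(self):
        model = sem.LsiModel(
            rank=1, terms=["t"], genes=["g"],
            term_factors=np.array([[1.0]]),
            singular_values=np.array([1.0]),
            gene_vectors=np.array([[2.0]]),
        )
        np.testing.assert_array_equal(similarity_matrix(model).cosines, [[1.0]])

    def test_symmetric_unit_diagonal_bounded(self, similarity):
        c = similarity.cosines
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert c.min() >= -1.0 and c.max() <= 1.0

    def test_entries_match_pairwise_cosine_calls(self, model, similarity):
        genes = model.genes[:10]
        for a in genes:
            for b in genes:
                assert similarity.value(a, b) == pytest.approx(
                    cosine(model, a, b), abs=1e-12
                )

    def test_document_order_invariance(self, documents):
        model1, _ = fit_from_documents(documents)
        model2, _ = fit_from_documents(list(reversed(documents)))
        np.testing.assert_allclose(
            similarity_matrix(model1).cosines,
            similarity_matrix(model2).cosines,
            atol=1e-9,
        )

    def test_gene_relabeling_permutes_but_preserves_values(self, documents):
        sim1 = similarity_matrix(fit_from_documents(documents)[0])
        # reverse the sort order of the gene ids
        relabeled = [
            GeneDocument("zz" + d.gene_id, d.text, d.abstract_count)
            for d in documents[::-1]
        ]
        sim2 = similarity_matrix(fit_from_documents(relabeled)[0])
        for a in sim1.genes[:10]:
            for b in sim1.genes[:10]:
                assert sim2.value("zz" + a, "zz" + b) == pytest.approx(
                    sim1.value(a, b), abs=1e-8
                )

    def test_pairs_tsv_export(self, similarity, tmp_path):
        path = tmp_path / "pairs.tsv"
        n = similarity.to_pairs_tsv(path, floor=0.5)
        lines = path.read_text().splitlines()
        assert lines[0] == "gene_a\tgene_b\tcosine"
        assert len(lines) == n + 1
        for line in lines[1:]:
            assert float(line.split("\t")[2]) >= 0.5


class TestTopNeighbors:
    @staticmethod
    def tiny_similarity():
        genes = ["A", "B", "C"]
        c = np.array(
            [[1.0, 0.9, 0.2],
             [0.9, 1.0, 0.4],
             [0.2, 0.4, 1.0]]
        )
        return sem.SimilarityMatrix(genes=genes, cosines=c)

    def test_three_gene_example(self):
        top, mean = top_neighbors(self.tiny_similarity(), "A", n=2)
        assert top == [("B", 0.9), ("C", 0.2)]
        assert mean == pytest.approx(0.55)

    def test_n_larger_than_population(self):
        top, mean = top_neighbors(self.tiny_similarity(), "C", n=10)
        assert top == [("B", 0.4), ("A", 0.2)]
        assert mean == pytest.approx(0.3)

    def test_matches_brute_force_sort(self, similarity):
        for gene in similarity.genes[:5]:
            i = similarity.index(gene)
            pairs = [
                (g, float(similarity.cosines[i, j]))
                for j, g in enumerate(similarity.genes)
                if g != gene
            ]
            expected = top_n_sorted(pairs, 10)
            assert top_neighbors(similarity, gene, 10)[0] == expected

    def test_ties_broken_by_gene_id(self):
        genes = ["A", "B", "C", "D"]
        c = np.ones((4, 4)) * 0.5
        np.fill_diagonal(c, 1.0)
        top, _ = top_neighbors(
            sem.SimilarityMatrix(genes=genes, cosines=c), "C", n=3
        )
        assert [g for g, _ in top] == ["A", "B", "D"]

    def test_unknown_gene(self, similarity):
        with pytest.raises(KeyError):
            top_neighbors(similarity, "missing")


class TestPersistence:
    def test_model_roundtrip_bit_compatible(self, model, tmp_path):
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = sem.LsiModel.load(path)
        assert loaded.genes == model.genes
        assert loaded.terms == model.terms
        assert loaded.rank == model.rank
        assert loaded.fingerprint == model.fingerprint
        np.testing.assert_array_equal(loaded.gene_vectors, model.gene_vectors)
        np.testing.assert_array_equal(loaded.singular_values, model.singular_values)
        np.testing.assert_array_equal(loaded.term_factors, model.term_factors)

    def test_term_gene_matrix_roundtrip(self, tgm, tmp_path):
        path = tmp_path / "weights.npz"
        sem.save_term_gene_matrix(tgm, path)
        loaded = sem.load_term_gene_matrix(path)
        assert loaded.terms == tgm.terms
        assert loaded.genes == tgm.genes
        assert (loaded.raw_counts != tgm.raw_counts).nnz == 0
        assert (loaded.weights != tgm.weights).nnz == 0

    def test_no_allzero_rows_or_columns(self, tgm):
        raw = tgm.raw_counts
        assert np.all(np.asarray(raw.sum(axis=1)).ravel() > 0)
        assert np.all(np.asarray(raw.sum(axis=0)).ravel() > 0)
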