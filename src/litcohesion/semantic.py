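"""Weighted term-by-gene matrix, truncated-SVD model, and gene-gene cosines.

The matrix entries are log-entropy weighted term frequencies: a local
log-damped count times a global weight equal to one minus the normalized
entropy of the term's count distribution across genes. The weighted matrix
is factorized by SVD; genes are represented by their singular-value-scaled
right factors and compared by cosine.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg

from .corpus import DEFAULT_TOKENIZER, GeneDocument, TokenizerConfig, tokenize

DEFAULT_RANK = 300

#: matrices with min dimension at or below this use a dense LAPACK SVD
_DENSE_SVD_LIMIT = 1500

_MODEL_FORMAT_VERSION = 1


class UnknownGeneError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Term-by-gene matrix
# ---------------------------------------------------------------------------

@dataclass
class TermGeneMatrix:
    """Raw and (optionally) log-entropy weighted term-by-gene counts.

    ``raw_counts`` and ``weights`` are terms x genes sparse CSR matrices.
    Vocabulary rows and gene columns are each sorted and contain no all-zero
    row or column.
    """

    terms: list[str]
    genes: list[str]
    raw_counts: sp.csr_matrix
    weights: sp.csr_matrix | None = None
    global_weights: np.ndarray | None = None  # per-term g in [0, 1]

    @classmethod
    def from_documents(
        cls,
        documents: Sequence[GeneDocument],
        rules: TokenizerConfig = DEFAULT_TOKENIZER,
    ) -> "TermGeneMatrix":
        """Tokenize documents and assemble the sparse count matrix.

        Genes whose documents tokenize to nothing are dropped (they would
        be all-zero columns); vocabulary is the sorted union of tokens.
        """
        token_maps = {}
        for doc in sorted(documents, key=lambda d: d.gene_id):
            counts = tokenize(doc.text, rules)
            if counts:
                token_maps[doc.gene_id] = counts
        genes = sorted(token_maps)
        terms = sorted({t for m in token_maps.values() for t in m})
        term_index = {t: i for i, t in enumerate(terms)}
        rows, cols, data = [], [], []
        for j, gene in enumerate(genes):
            for term, n in token_maps[gene].items():
                rows.append(term_index[term])
                cols.append(j)
                data.append(n)
        raw = sp.csr_matrix(
            (data, (rows, cols)), shape=(len(terms), len(genes)), dtype=np.float64
        )
        return cls(terms=terms, genes=genes, raw_counts=raw)

    @property
    def shape(self) -> tuple[int, int]:
        return self.raw_counts.shape

    def apply_weighting(self) -> "TermGeneMatrix":
        """Compute and attach log-entropy weights (in place); returns self."""
        self.weights, self.global_weights = apply_log_entropy(self.raw_counts)
        return self


def save_term_gene_matrix(tgm: TermGeneMatrix, path: str | Path) -> None:
    """Persist a weighted term-gene matrix as a versioned .npz archive."""
    if tgm.weights is None:
        raise ValueError("matrix has no weights; call apply_weighting() first")
    coo_r = tgm.raw_counts.tocoo()
    coo_w = tgm.weights.tocoo()
    np.savez(
        path,
        format_version=np.int64(_MODEL_FORMAT_VERSION),
        terms=np.asarray(tgm.terms, dtype=object),
        genes=np.asarray(tgm.genes, dtype=object),
        shape=np.asarray(tgm.shape, dtype=np.int64),
        raw_row=coo_r.row, raw_col=coo_r.col, raw_data=coo_r.data,
        w_row=coo_w.row, w_col=coo_w.col, w_data=coo_w.data,
        global_weights=tgm.global_weights,
    )


def load_term_gene_matrix(path: str | Path) -> TermGeneMatrix:
    with np.load(path, allow_pickle=True) as z:
        version = int(z["format_version"])
        if version != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported matrix format version {version}")
        shape = tuple(z["shape"])
        raw = sp.csr_matrix(
            (z["raw_data"], (z["raw_row"], z["raw_col"])), shape=shape
        )
        weights = sp.csr_matrix(
            (z["w_data"], (z["w_row"], z["w_col"])), shape=shape
        )
        return TermGeneMatrix(
            terms=[str(t) for t in z["terms"]],
            genes=[str(g) for g in z["genes"]],
            raw_counts=raw,
            weights=weights,
            global_weights=z["global_weights"],
        )


def apply_log_entropy(
    raw_counts: sp.spmatrix | np.ndarray,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Log-entropy weighting of a terms x genes count matrix.

    For term i with counts f_ij over n genes and p_ij = f_ij / sum_j f_ij:

        l_ij = log2(1 + f_ij)
        g_i  = 1 + sum_j p_ij * log2(p_ij) / log2(n)
        w_ij = g_i * l_ij

    g_i is 1 for a term confined to one gene and 0 for a term spread
    uniformly over all genes. Returns (weights, g).
    """
    counts = sp.csr_matrix(raw_counts, dtype=np.float64)
    n_terms, n_genes = counts.shape
    if n_genes < 2:
        raise ValueError("log-entropy weighting needs at least 2 genes")
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("raw counts must be non-negative")

    row_sums = np.asarray(counts.sum(axis=1)).ravel()
    g = np.ones(n_terms)
    # entropy over the nonzero entries only: p*log2(p) -> 0 as p -> 0
    coo = counts.tocoo()
    nz = coo.data > 0
    rows, vals = coo.row[nz], coo.data[nz]
    p = vals / row_sums[rows]
    contrib = p * np.log2(p)
    ent = np.zeros(n_terms)
    np.add.at(ent, rows, contrib)
    g += ent / np.log2(n_genes)
    g = np.clip(g, 0.0, 1.0)  # guard roundoff at the uniform limit

    weights = counts.copy()
    weights.data = np.log2(1.0 + weights.data)
    weights = sp.csr_matrix(sp.diags(g) @ weights)
    weights.eliminate_zeros()
    return weights, g


# ---------------------------------------------------------------------------
# LSI model
# ---------------------------------------------------------------------------

@dataclass
class LsiModel:
    """Rank-k SVD of the weighted matrix; genes as k-dimensional vectors.

    ``gene_vectors`` holds V_k scaled by the singular values (one row per
    gene); set ``scale_by_singular_values=False`` at fit time for plain V_k.
    Cosines between genes are identical under either convention at full rank.
    """

    rank: int
    terms: list[str]
    genes: list[str]
    term_factors: np.ndarray       # terms x k, orthonormal columns
    singular_values: np.ndarray    # k, non-increasing
    gene_vectors: np.ndarray       # genes x k
    scaled: bool = True
    fingerprint: str = ""
    _gene_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._gene_index:
            self._gene_index = {g: i for i, g in enumerate(self.genes)}
        if not self.fingerprint:
            self.fingerprint = _fingerprint(self.genes, self.gene_vectors)

    def vector(self, gene_id: str) -> np.ndarray:
        try:
            return self.gene_vectors[self._gene_index[gene_id]]
        except KeyError:
            raise UnknownGeneError(f"gene {gene_id!r} is not in the model")

    def save(self, path: str | Path) -> None:
        """Write the model as a versioned .npz archive (round-trips exactly)."""
        np.savez(
            path,
            format_version=np.int64(_MODEL_FORMAT_VERSION),
            rank=np.int64(self.rank),
            terms=np.asarray(self.terms, dtype=object),
            genes=np.asarray(self.genes, dtype=object),
            term_factors=self.term_factors,
            singular_values=self.singular_values,
            gene_vectors=self.gene_vectors,
            scaled=np.bool_(self.scaled),
            fingerprint=np.str_(self.fingerprint),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LsiModel":
        with np.load(path, allow_pickle=True) as z:
            version = int(z["format_version"])
            if version != _MODEL_FORMAT_VERSION:
                raise ValueError(f"unsupported model format version {version}")
            return cls(
                rank=int(z["rank"]),
                terms=[str(t) for t in z["terms"]],
                genes=[str(g) for g in z["genes"]],
                term_factors=z["term_factors"],
                singular_values=z["singular_values"],
                gene_vectors=z["gene_vectors"],
                scaled=bool(z["scaled"]),
                fingerprint=str(z["fingerprint"]),
            )


def _fingerprint(genes: Sequence[str], gene_vectors: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update("\x00".join(genes).encode())
    h.update(np.ascontiguousarray(np.round(gene_vectors, 9)).tobytes())
    return h.hexdigest()[:16]


def fit_lsi(
    weights: sp.spmatrix | np.ndarray,
    terms: Sequence[str],
    genes: Sequence[str],
    k: int | None = None,
    scale_by_singular_values: bool = True,
) -> LsiModel:
    """Truncated SVD of the weighted terms x genes matrix.

    ``k`` defaults to min(300, numerical rank). Dense LAPACK SVD is used for
    small matrices and ARPACK ``svds`` for large ones; the two agree to
    within 1e-8.
    """
    W = sp.csr_matrix(weights, dtype=np.float64)
    n_terms, n_genes = W.shape
    min_dim = min(n_terms, n_genes)
    if k is None:
        k = min(DEFAULT_RANK, effective_rank(W))
    if k < 1 or k > min_dim:
        raise ValueError(f"k must be in [1, {min_dim}], got {k}")

    if min_dim <= _DENSE_SVD_LIMIT or k >= min_dim - 1:
        U, s, Vt = np.linalg.svd(W.toarray(), full_matrices=False)
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
    else:
        U, s, Vt = scipy.sparse.linalg.svds(W, k=k)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]

    gene_vectors = Vt.T * (s if scale_by_singular_values else 1.0)
    return LsiModel(
        rank=k,
        terms=list(terms),
        genes=list(genes),
        term_factors=U,
        singular_values=s,
        gene_vectors=gene_vectors,
        scaled=scale_by_singular_values,
    )


def effective_rank(weights: sp.spmatrix | np.ndarray, tol: float | None = None) -> int:
    """Numerical rank of the (densified) weight matrix."""
    dense = weights.toarray() if sp.issparse(weights) else np.asarray(weights)
    return int(np.linalg.matrix_rank(dense, tol=tol))


def fit_from_documents(
    documents: Sequence[GeneDocument],
    k: int | None = None,
    rules: TokenizerConfig = DEFAULT_TOKENIZER,
) -> tuple[LsiModel, TermGeneMatrix]:
    """Convenience: documents -> counts -> weights -> model."""
    tgm = TermGeneMatrix.from_documents(documents, rules).apply_weighting()
    model = fit_lsi(tgm.weights, tgm.terms, tgm.genes, k=k)
    return model, tgm


# ---------------------------------------------------------------------------
# Similarities
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Symmetric gene-by-gene cosine matrix with unit diagonal."""

    genes: list[str]
    cosines: np.ndarray
    fingerprint: str = ""
    _gene_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._gene_index:
            self._gene_index = {g: i for i, g in enumerate(self.genes)}

    def index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise UnknownGeneError(f"gene {gene_id!r} is not in the similarity matrix")

    def value(self, gene_a: str, gene_b: str) -> float:
        return float(self.cosines[self.index(gene_a), self.index(gene_b)])

    def submatrix(self, gene_ids: Sequence[str]) -> np.ndarray:
        idx = np.asarray([self.index(g) for g in gene_ids])
        return self.cosines[np.ix_(idx, idx)]

    def __len__(self) -> int:
        return len(self.genes)

    def to_pairs_tsv(self, path: str | Path, floor: float = 0.0) -> int:
        """Write gene_a, gene_b, cosine rows for pairs with cosine >= floor."""
        n_written = 0
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_a\tgene_b\tcosine\n")
            iu = np.triu_indices(len(self.genes), k=1)
            for i, j in zip(*iu):
                c = self.cosines[i, j]
                if c >= floor:
                    fh.write(f"{self.genes[i]}\t{self.genes[j]}\t{c:.6f}\n")
                    n_written += 1
        return n_written


def _unit_rows(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(vectors, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return vectors / safe[:, None], zero


def cosine(model: LsiModel, gene_a: str, gene_b: str) -> float:
    """Cosine similarity of two modeled genes.

    Self-similarity is 1.0; a pair involving a zero vector scores 0.0 (with
    a warning) so such genes contribute no edges.
    """
    va, vb = model.vector(gene_a), model.vector(gene_b)
    if gene_a == gene_b:
        return 1.0
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        warnings.warn(
            f"zero vector for gene {gene_a if na == 0 else gene_b!r}; cosine set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.clip(va @ vb / (na * nb), -1.0, 1.0))


def similarity_matrix(model: LsiModel) -> SimilarityMatrix:
    """All pairwise gene cosines; entry (a, b) equals ``cosine(model, a, b)``."""
    unit, zero = _unit_rows(model.gene_vectors)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} gene(s) have zero vectors; their cosines are 0",
            RuntimeWarning,
            stacklevel=2,
        )
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    cos = (cos + cos.T) / 2.0
    np.fill_diagonal(cos, 1.0)
    return SimilarityMatrix(
        genes=list(model.genes), cosines=cos, fingerprint=model.fingerprint
    )


def top_neighbors(
    similarity: SimilarityMatrix,
    gene_id: str,
    n: int = 10,
) -> tuple[list[tuple[str, float]], float]:
    """The gene's n highest-cosine neighbors (self excluded) and their mean.

    Descending cosine; ties broken by ascending gene id. Returns fewer than
    n pairs when the matrix is small, with the mean over what is returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = similarity.index(gene_id)
    others = [
        (other, float(similarity.cosines[i, j]))
        for j, other in enumerate(similarity.genes)
        if j != i
    ]
    others.sort(key=lambda t: (-t[1], t[0]))
    top = others[:n]
    mean = float(np.mean([c for _, c in top])) if top else float("nan")
    return top, mean
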