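"""Independent brute-force oracles used to verify the package's fast paths.

Everything here is deliberately written with scalar loops, exact rational /
big-integer arithmetic, or naive enumeration, and must stay independent of
the implementation routes it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# Fisher / hypergeometric
# ---------------------------------------------------------------------------

def exact_fisher_tail(k: int, m: int, K: int, M: int) -> Fraction:
    """P(X >= k) for the 2x2 table [[k, m-k], [K, M-K]], exact rational.

    X is hypergeometric with population m + M, successes k + K, draws m.
    """
    N, c = m + M, k + K
    num = sum(
        math.comb(c, x) * math.comb(N - c, m - x)
        for x in range(k, min(m, c) + 1)
    )
    return Fraction(num, math.comb(N, m))


def pascal_table(n_max: int, r_max: int) -> np.ndarray:
    """Exact-integer Pascal triangle C[n, r] as an object array (0 if r > n)."""
    C = np.zeros((n_max + 1, r_max + 1), dtype=object)
    C[:, 0] = 1
    for n in range(1, n_max + 1):
        hi = min(n, r_max)
        C[n, 1 : hi + 1] = C[n - 1, 0:hi] + C[n - 1, 1 : hi + 1]
    return C


def exact_fisher_tail_grid(m: int, M: int, C: np.ndarray) -> np.ndarray:
    """Exact upper-tail p for every (c, k); integer sums, float only at the end.

    Entry [c, k] equals ``float(exact_fisher_tail(k, m, c-k, M))``; invalid
    (c, k) combinations are not masked (callers mask). ``C`` is a
    ``pascal_table(m + M, m)`` or larger.
    """
    N = m + M
    cs = np.arange(N + 1)
    xs = np.arange(m + 1)
    pmf_num = C[cs[:, None], xs[None, :]] * C[(N - cs)[:, None], (m - xs)[None, :]]
    tail_num = np.cumsum(pmf_num[:, ::-1], axis=1)[:, ::-1]
    return tail_num.astype(np.float64) / float(C[N][m])


# ---------------------------------------------------------------------------
# Log-entropy weighting, scalar reference
# ---------------------------------------------------------------------------

def log_entropy_weights_scalar(counts) -> np.ndarray:
    """Entry-by-entry log-entropy weights with plain Python floats."""
    counts = np.asarray(counts, dtype=float)
    n_terms, n_genes = counts.shape
    out = np.zeros_like(counts)
    for i in range(n_terms):
        total = counts[i].sum()
        entropy = 0.0
        for j in range(n_genes):
            if counts[i, j] > 0:
                p = counts[i, j] / total
                entropy += p * math.log2(p)
        g = 1.0 + entropy / math.log2(n_genes)
        for j in range(n_genes):
            out[i, j] = g * math.log2(1.0 + counts[i, j])
    return out


# ---------------------------------------------------------------------------
# Cosines and ranking
# ---------------------------------------------------------------------------

def column_cosine_matrix(matrix) -> np.ndarray:
    """Pairwise column cosines by the naive double loop; unit diagonal."""
    A = np.asarray(matrix, dtype=float)
    n = A.shape[1]
    out = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            na, nb = np.linalg.norm(A[:, a]), np.linalg.norm(A[:, b])
            c = 0.0 if na == 0 or nb == 0 else float(A[:, a] @ A[:, b] / (na * nb))
            out[a, b] = out[b, a] = c
    return out


def top_n_sorted(pairs: list[tuple[str, float]], n: int) -> list[tuple[str, float]]:
    """Full sort then slice: descending score, ascending id on ties."""
    return sorted(pairs, key=lambda t: (-t[1], t[0]))[:n]


def nearest_rank_percentile_scalar(scores, percentile: float) -> float:
    pool = sorted(float(s) for s in np.asarray(scores).ravel())
    rank = math.ceil(percentile / 100.0 * len(pool))
    return pool[rank - 1]


def count_pairs_above(gene_ids, similarity, threshold: float) -> tuple[int, int]:
    """Exhaustive double loop over unordered pairs."""
    ids = sorted(set(gene_ids))
    m = k = 0
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            m += 1
            if similarity.value(ids[a], ids[b]) > threshold:
                k += 1
    return m, k


def best_rank_k_error(matrix, k: int) -> float:
    """Frobenius error of the best rank-k approximation via the eigenvalues
    of the Gram matrix (independent of any SVD routine)."""
    A = np.asarray(matrix, dtype=float)
    gram = A.T @ A if A.shape[0] >= A.shape[1] else A @ A.T
    eigvals = np.linalg.eigvalsh(gram)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    return float(np.sqrt(eigvals[k:].sum()))
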