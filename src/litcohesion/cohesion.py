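"""Edge-threshold calibration and the literature p-value (LPv).

The cosine cut-off is calibrated empirically: many random gene sets are
drawn, their within-set pairwise cosines pooled, and the threshold set at a
nearest-rank percentile (default 95th) of the pooled scores. A gene set's
cohesion is then the Fisher's-exact-test p-value of its count of
above-threshold pairs against the calibration background.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .semantic import SimilarityMatrix

DEFAULT_N_SETS = 1000
DEFAULT_SIZE_RANGE = (50, 400)
DEFAULT_PERCENTILE = 95.0


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Empirical pooled-cosine summary and the derived edge threshold.

    ``background_above`` (K) and ``background_total`` (M) are the counts of
    pooled scores strictly above the threshold and of all pooled scores;
    they form the background row of every downstream contingency table.
    """

    threshold: float
    percentile: float
    n_sets: int
    size_range: tuple[int, int]
    pooled_count: int
    fraction_above: float
    seed: int
    background_above: int
    background_total: int
    per_set_fractions: list[float] = field(default_factory=list)
    model_fingerprint: str = ""

    def to_json(self, path: str | Path) -> None:
        obj = asdict(self)
        obj["size_range"] = list(self.size_range)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResult":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        obj["size_range"] = tuple(obj["size_range"])
        return cls(**obj)


def nearest_rank_percentile(scores: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest observation."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    pool = np.sort(np.asarray(scores, dtype=float).ravel())
    if pool.size == 0:
        raise ValueError("empty score pool")
    rank = math.ceil(percentile / 100.0 * pool.size)
    return float(pool[rank - 1])


def calibrate_threshold(
    similarity: SimilarityMatrix,
    n_sets: int = DEFAULT_N_SETS,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    percentile: float = DEFAULT_PERCENTILE,
    seed: int = 0,
) -> CalibrationResult:
    """Derive the edge threshold from random gene sets.

    Draws ``n_sets`` sets with sizes uniform over the inclusive
    ``size_range`` (capped below the number of genes, with a warning, when
    the matrix is small), pools all within-set pairwise cosines, and takes
    the nearest-rank percentile. The seed fully determines the result.
    """
    n_genes = len(similarity)
    if n_genes < 2:
        raise ValueError("calibration needs at least 2 genes")
    lo, hi = size_range
    if lo < 2 or hi < lo:
        raise ValueError(f"bad size range {size_range}")
    if hi >= n_genes:
        capped = (min(lo, n_genes - 1), n_genes - 1)
        warnings.warn(
            f"size range {size_range} capped to {capped} for a "
            f"{n_genes}-gene matrix",
            stacklevel=2,
        )
        lo, hi = capped

    rng = np.random.default_rng(seed)
    pools = []
    set_slices = []
    iu_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for _ in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(n_genes, size=size, replace=False)
        if size not in iu_cache:
            iu_cache[size] = np.triu_indices(size, k=1)
        sub = similarity.cosines[np.ix_(idx, idx)]
        scores = sub[iu_cache[size]]
        set_slices.append(scores)
        pools.append(scores)
    pooled = np.concatenate(pools)
    threshold = nearest_rank_percentile(pooled, percentile)
    above = int(np.sum(pooled > threshold))
    return CalibrationResult(
        threshold=threshold,
        percentile=percentile,
        n_sets=n_sets,
        size_range=(lo, hi),
        pooled_count=int(pooled.size),
        fraction_above=above / pooled.size,
        seed=seed,
        background_above=above,
        background_total=int(pooled.size),
        per_set_fractions=[float(np.mean(s > threshold)) for s in set_slices],
        model_fingerprint=similarity.fingerprint,
    )


def background_from_proportion(
    proportion: float, pseudo_total: int
) -> tuple[int, int]:
    """Fixed-proportion background as integer counts over a pseudo-total."""
    if not 0 < proportion < 1:
        raise ValueError("proportion must be in (0, 1)")
    if pseudo_total < 1:
        raise ValueError("pseudo_total must be >= 1")
    return round(proportion * pseudo_total), pseudo_total


# ---------------------------------------------------------------------------
# Edge counting and Fisher's exact test
# ---------------------------------------------------------------------------

def count_edges(
    gene_ids: Sequence[str],
    similarity: SimilarityMatrix,
    threshold: float,
) -> tuple[int, int]:
    """(m, k_above): total unordered pairs and pairs with cosine > threshold.

    Strictly-greater semantics; self-pairs excluded.
    """
    ids = sorted(set(gene_ids))
    n = len(ids)
    if n < 2:
        raise ValueError(
            "cohesion undefined for fewer than two genes with abstracts"
        )
    sub = similarity.submatrix(ids)
    iu = np.triu_indices(n, k=1)
    scores = sub[iu]
    return int(scores.size), int(np.sum(scores > threshold))


def fisher_lpv(
    k_above: int,
    m: int,
    background_above: int,
    background_total: int,
    alternative: str = "greater",
) -> float:
    """One-sided Fisher's exact p-value for the 2x2 table
    [[k_above, m - k_above], [K, M - K]].

    With ``alternative='greater'`` (the default) this is the hypergeometric
    upper tail: the probability of at least ``k_above`` above-threshold
    pairs among ``m`` draws from a pool with ``k_above + K`` successes out
    of ``m + M``. ``alternative='two-sided'`` delegates to
    ``scipy.stats.fisher_exact``.
    """
    K, M = background_above, background_total
    if min(k_above, m - k_above, K, M - K) < 0 or m < 1 or M < 1:
        raise ValueError(
            f"inconsistent contingency counts: k={k_above}, m={m}, K={K}, M={M}"
        )
    if alternative == "two-sided":
        from scipy.stats import fisher_exact

        table = [[k_above, m - k_above], [K, M - K]]
        return float(fisher_exact(table, alternative="two-sided")[1])
    if alternative != "greater":
        raise ValueError(f"unknown alternative {alternative!r}")
    # sf(k-1) = P(X >= k) for X ~ Hypergeom(N=m+M, successes=k+K, draws=m)
    p = float(hypergeom.sf(k_above - 1, m + M, k_above + K, m))
    return min(p, 1.0)


def fisher_lpv_grid(m: int, background_total: int) -> np.ndarray:
    """Upper-tail p-values for every table with row totals (m, M).

    Entry [c, k] is ``fisher_lpv(k, m, c - k, M)`` for column-one total c;
    entries with k > min(m, c) or c - k > M are NaN. Used for bulk
    diagnostics and exhaustive verification.
    """
    M = background_total
    N = m + M
    cs = np.arange(N + 1)[:, None]
    ks = np.arange(m + 1)[None, :]
    with np.errstate(invalid="ignore"):
        p = hypergeom.sf(ks - 1, N, cs, m)
    invalid = (ks > np.minimum(m, cs)) | (cs - ks > M) | (cs - ks < 0)
    p = np.minimum(p, 1.0)
    p[invalid] = np.nan
    return p


# ---------------------------------------------------------------------------
# Gene-set resolution and the LPv pipeline
# ---------------------------------------------------------------------------

@dataclass
class GeneSetInput:
    """A requested gene list and the subset resolvable in the model."""

    requested_ids: list[str]
    resolved_ids: list[str]
    unresolved_ids: list[str]

    @property
    def n_input(self) -> int:
        return len(self.requested_ids)

    @property
    def n_with_abstracts(self) -> int:
        return len(self.resolved_ids)


def resolve_gene_set(
    requested_ids: Sequence[str],
    similarity: SimilarityMatrix,
    symbol_map: Mapping[str, str] | None = None,
) -> GeneSetInput:
    """Map symbols/ids to modeled gene ids, dropping duplicates and unknowns.

    ``n_input`` counts the raw request list; ``n_with_abstracts`` counts the
    unique resolved genes.
    """
    requested = [str(g).strip() for g in requested_ids if str(g).strip()]
    modeled = set(similarity.genes)
    resolved: list[str] = []
    unresolved: list[str] = []
    seen: set[str] = set()
    for raw in requested:
        gene = symbol_map.get(raw, raw) if symbol_map else raw
        if gene in modeled:
            if gene not in seen:
                seen.add(gene)
                resolved.append(gene)
        else:
            unresolved.append(raw)
    return GeneSetInput(
        requested_ids=requested,
        resolved_ids=sorted(resolved),
        unresolved_ids=unresolved,
    )


@dataclass
class CohesionResult:
    """Edge counts, contingency table, and LPv for one gene set."""

    gene_set: GeneSetInput
    threshold: float
    m: int
    k_above: int
    background_above: int
    background_total: int
    lpv: float

    @property
    def contingency(self) -> list[list[int]]:
        return [
            [self.k_above, self.m - self.k_above],
            [self.background_above, self.background_total - self.background_above],
        ]

    def to_dict(self) -> dict:
        return {
            "n_input": self.gene_set.n_input,
            "n_with_abstracts": self.gene_set.n_with_abstracts,
            "resolved_ids": self.gene_set.resolved_ids,
            "unresolved_ids": self.gene_set.unresolved_ids,
            "threshold": self.threshold,
            "m": self.m,
            "k_above": self.k_above,
            "contingency": self.contingency,
            "lpv": self.lpv,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def lpv_for_gene_set(
    requested_ids: Sequence[str],
    similarity: SimilarityMatrix,
    calibration: CalibrationResult,
    symbol_map: Mapping[str, str] | None = None,
    alternative: str = "greater",
) -> CohesionResult:
    """Resolve a gene list and score its literature cohesion.

    Raises ``ValueError`` (with the resolution report in the message) when
    fewer than two requested genes are modeled, and when the calibration's
    model fingerprint does not match the similarity matrix.
    """
    if (
        calibration.model_fingerprint
        and similarity.fingerprint
        and calibration.model_fingerprint != similarity.fingerprint
    ):
        raise ValueError(
            "calibration was computed from a different model "
            f"(fingerprint {calibration.model_fingerprint} != {similarity.fingerprint})"
        )
    gene_set = resolve_gene_set(requested_ids, similarity, symbol_map)
    if gene_set.n_with_abstracts < 2:
        raise ValueError(
            "cohesion undefined for fewer than two genes with abstracts; "
            f"resolved {gene_set.n_with_abstracts} of {gene_set.n_input} "
            f"(unresolved: {gene_set.unresolved_ids})"
        )
    m, k_above = count_edges(gene_set.resolved_ids, similarity, calibration.threshold)
    lpv = fisher_lpv(
        k_above,
        m,
        calibration.background_above,
        calibration.background_total,
        alternative=alternative,
    )
    return CohesionResult(
        gene_set=gene_set,
        threshold=calibration.threshold,
        m=m,
        k_above=k_above,
        background_above=calibration.background_above,
        background_total=calibration.background_total,
        lpv=lpv,
    )
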