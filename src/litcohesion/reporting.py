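"""Report outputs: cohesion network graph, common weighted terms, annotations."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohesion import resolve_gene_set
from .semantic import SimilarityMatrix, TermGeneMatrix

ENTREZ_GENE_URL = "https://www.ncbi.nlm.nih.gov/gene/{gene_id}"
PUBMED_URL = "https://pubmed.ncbi.nlm.nih.gov/?term={gene_id}"


def build_graph(
    gene_ids: Sequence[str],
    similarity: SimilarityMatrix,
    threshold: float,
    abstract_counts: Mapping[str, int] | None = None,
) -> nx.Graph:
    """Network over a gene set: nodes are genes, edges are pairs with
    cosine strictly above the threshold.

    All resolved genes appear as nodes, including isolated ones. The
    threshold is recorded in the graph metadata; edge weights live in the
    ``cosine`` attribute and nodes carry ``abstract_count`` when provided.
    """
    ids = sorted(set(gene_ids))
    graph = nx.Graph(threshold=float(threshold))
    for g in ids:
        attrs = {}
        if abstract_counts is not None and g in abstract_counts:
            attrs["abstract_count"] = int(abstract_counts[g])
        graph.add_node(g, **attrs)
    if len(ids) >= 2:
        sub = similarity.submatrix(ids)
        iu, ju = np.triu_indices(len(ids), k=1)
        for i, j in zip(iu, ju):
            c = float(sub[i, j])
            if c > threshold:
                graph.add_edge(ids[i], ids[j], cosine=c)
    return graph


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_sif(graph: nx.Graph, path: str | Path, relation: str = "cos") -> None:
    """Cytoscape SIF: one 'a cos b' line per edge, then isolated nodes."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        connected = set()
        for a, b in sorted(graph.edges()):
            fh.write(f"{a}\t{relation}\t{b}\n")
            connected.update((a, b))
        for node in sorted(graph.nodes()):
            if node not in connected:
                fh.write(f"{node}\n")


def read_sif(path: str | Path, relation: str = "cos") -> nx.Graph:
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                graph.add_node(parts[0])
            elif len(parts) == 3:
                graph.add_edge(parts[0], parts[2])
    return graph


def common_terms(
    gene_ids: Sequence[str],
    tgm: TermGeneMatrix,
    top_n: int = 20,
    min_genes: int = 2,
) -> list[tuple[str, float]]:
    """Terms shared by the gene set, ranked by summed log-entropy weight.

    Only terms with nonzero weight in at least ``min_genes`` of the set's
    genes qualify as "common". Ties break lexicographically. May return
    fewer than ``top_n`` entries.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if tgm.weights is None:
        raise ValueError("term-gene matrix has no weights; call apply_weighting()")
    gene_index = {g: i for i, g in enumerate(tgm.genes)}
    cols = [gene_index[g] for g in sorted(set(gene_ids)) if g in gene_index]
    if not cols:
        return []
    sub = tgm.weights[:, cols]
    presence = np.asarray((sub > 0).sum(axis=1)).ravel()
    sums = np.asarray(sub.sum(axis=1)).ravel()
    eligible = np.nonzero(presence >= min_genes)[0]
    ranked = sorted(
        ((tgm.terms[i], float(sums[i])) for i in eligible),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:top_n]


def annotation_table(
    requested_ids: Sequence[str],
    similarity: SimilarityMatrix,
    abstract_counts: Mapping[str, int],
    symbol_map: Mapping[str, str] | None = None,
    symbols: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One row per requested gene (resolved or not), in first-seen order.

    Columns: requested, gene_id, symbol, resolved, abstract_count,
    gene_url, abstracts_url. Unresolved rows keep empty id/count fields.
    URL fields are templates filled with the gene id; no network access.
    """
    resolution = resolve_gene_set(requested_ids, similarity, symbol_map)
    resolved = set(resolution.resolved_ids)
    rows = []
    seen: set[str] = set()
    for raw in resolution.requested_ids:
        if raw in seen:
            continue
        seen.add(raw)
        gene = symbol_map.get(raw, raw) if symbol_map else raw
        ok = gene in resolved
        rows.append(
            {
                "requested": raw,
                "gene_id": gene if ok else "",
                "symbol": (symbols or {}).get(gene, "") if ok else "",
                "resolved": ok,
                "abstract_count": (
                    int(abstract_counts.get(gene, 0)) if ok else pd.NA
                ),
                "gene_url": ENTREZ_GENE_URL.format(gene_id=gene) if ok else "",
                "abstracts_url": PUBMED_URL.format(gene_id=gene) if ok else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "requested", "gene_id", "symbol", "resolved",
            "abstract_count", "gene_url", "abstracts_url",
        ],
    )


def write_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")
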