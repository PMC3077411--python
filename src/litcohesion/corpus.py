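"""Corpus construction: abstract records, gene-citation links, gene documents.

The pipeline is: read abstracts and links, drop promiscuous citations
(linked to more than ``max_genes_per_citation`` genes), merge citation sets
across ortholog groups, and concatenate each gene's titles and abstracts
into a single bag-of-words document.

Filtering is applied *before* ortholog merging, so merging can never push a
citation over the promiscuity threshold.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

DEFAULT_MAX_GENES_PER_CITATION = 10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbstractRecord:
    """One citation: an opaque identifier plus title and abstract text."""

    citation_id: str
    title: str = ""
    body: str = ""

    def __post_init__(self) -> None:
        if not self.citation_id:
            raise ValueError("citation_id must be non-empty")
        if not self.title and not self.body:
            raise ValueError(
                f"citation {self.citation_id!r}: title and body cannot both be empty"
            )

    @property
    def text(self) -> str:
        return f"{self.title} {self.body}".strip()


@dataclass(frozen=True, order=True)
class GeneCitationLink:
    """A (gene, citation) cross-reference."""

    gene_id: str
    citation_id: str


@dataclass(frozen=True)
class GeneDocument:
    """A gene's concatenated literature text plus its citation count."""

    gene_id: str
    text: str
    abstract_count: int

    def __post_init__(self) -> None:
        if self.abstract_count < 1:
            raise ValueError(
                f"gene {self.gene_id!r}: abstract_count must be >= 1, "
                f"got {self.abstract_count}"
            )


class OrthologMap:
    """A partition of gene ids into ortholog groups.

    Each gene belongs to at most one group; the lexicographically smallest
    member is the group representative. Overlapping groups are rejected.
    """

    def __init__(self, groups: Iterable[Iterable[str]]):
        self._group_of: dict[str, frozenset[str]] = {}
        self.groups: list[frozenset[str]] = []
        for raw in groups:
            group = frozenset(raw)
            if not group:
                continue
            overlap = group & self._group_of.keys()
            if overlap:
                raise ValueError(
                    f"ortholog groups overlap on gene(s): {sorted(overlap)}"
                )
            self.groups.append(group)
            for g in group:
                self._group_of[g] = group
        self.representative = {
            g: min(group) for group in self.groups for g in group
        }

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologMap":
        """Build groups as connected components of the pair graph."""
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in pairs:
            for g in (a, b):
                parent.setdefault(g, g)
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        comps: dict[str, set[str]] = defaultdict(set)
        for g in parent:
            comps[find(g)].add(g)
        return cls(comps.values())

    def group_members(self, gene_id: str) -> frozenset[str]:
        """The gene's group, or a singleton if it is unmapped."""
        return self._group_of.get(gene_id, frozenset((gene_id,)))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._group_of

    def __len__(self) -> int:
        return len(self.groups)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def dedupe_links(links: Iterable[GeneCitationLink]) -> list[GeneCitationLink]:
    """Collapse duplicate (gene, citation) pairs, preserving sorted order."""
    return sorted(set(links))


def filter_promiscuous_citations(
    links: Iterable[GeneCitationLink],
    max_genes_per_citation: int = DEFAULT_MAX_GENES_PER_CITATION,
) -> tuple[list[GeneCitationLink], dict[str, int]]:
    """Remove all links of citations referring to more than the cutoff genes.

    The comparison is strict: a citation linked to exactly
    ``max_genes_per_citation`` genes is retained.

    Returns the retained links (sorted, deduplicated) and a removal report
    mapping each dropped citation_id to its distinct-gene count.
    """
    if max_genes_per_citation < 1:
        raise ValueError("max_genes_per_citation must be >= 1")
    links = dedupe_links(links)
    genes_per_citation = Counter(l.citation_id for l in links)
    removed = {
        cid: n for cid, n in genes_per_citation.items()
        if n > max_genes_per_citation
    }
    kept = [l for l in links if l.citation_id not in removed]
    if removed:
        logger.info(
            "removed %d promiscuous citation(s) (> %d genes), dropping %d links",
            len(removed), max_genes_per_citation, len(links) - len(kept),
        )
    return kept, removed


def merge_ortholog_citations(
    links: Iterable[GeneCitationLink],
    orthologs: OrthologMap,
) -> list[GeneCitationLink]:
    """Share citations across ortholog groups.

    Every member gene of a group receives the union of the group's citation
    sets, so each gene keeps its own (enlarged) document. Genes absent from
    the map pass through unchanged.
    """
    links = dedupe_links(links)
    group_citations: dict[frozenset[str], set[str]] = defaultdict(set)
    passthrough: list[GeneCitationLink] = []
    for link in links:
        if link.gene_id in orthologs:
            group_citations[orthologs.group_members(link.gene_id)].add(
                link.citation_id
            )
        else:
            passthrough.append(link)
    merged = passthrough
    for group, citations in group_citations.items():
        merged.extend(
            GeneCitationLink(g, c) for g in group for c in citations
        )
    return dedupe_links(merged)


def build_gene_documents(
    abstracts: Iterable[AbstractRecord],
    links: Iterable[GeneCitationLink],
) -> list[GeneDocument]:
    """Concatenate each gene's titles and abstracts into one document.

    Citations are concatenated in ascending citation_id order. Links whose
    citation_id has no AbstractRecord are logged and skipped; genes left
    with zero resolved citations are omitted.
    """
    by_id = {a.citation_id: a for a in abstracts}
    per_gene: dict[str, set[str]] = defaultdict(set)
    dangling: set[str] = set()
    for link in dedupe_links(links):
        if link.citation_id in by_id:
            per_gene[link.gene_id].add(link.citation_id)
        else:
            dangling.add(link.citation_id)
    if dangling:
        logger.warning("skipped %d unresolvable citation id(s)", len(dangling))
    documents = []
    for gene_id in sorted(per_gene):
        cids = sorted(per_gene[gene_id])
        text = " ".join(by_id[c].text for c in cids)
        documents.append(
            GeneDocument(gene_id=gene_id, text=text, abstract_count=len(cids))
        )
    return documents


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

def _load_default_stopwords() -> frozenset[str]:
    text = (
        resources.files("litcohesion").joinpath("data/stopwords.txt").read_text()
    )
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class TokenizerConfig:
    """Tokenization rules: lowercase alphabetic tokens, length floor, stop-list."""

    lowercase: bool = True
    token_pattern: str = r"[A-Za-z]+"
    min_length: int = 3
    stopwords: frozenset[str] = field(default_factory=_load_default_stopwords)


DEFAULT_TOKENIZER = TokenizerConfig()


def tokenize(text: str, rules: TokenizerConfig = DEFAULT_TOKENIZER) -> Counter:
    """Map document text to term counts under the given rules.

    Deterministic; stop-listed and sub-minimum-length tokens are removed
    after lowercasing.
    """
    pattern = re.compile(rules.token_pattern)
    counts: Counter = Counter()
    for token in pattern.findall(text):
        if rules.lowercase:
            token = token.lower()
        if len(token) < rules.min_length or token in rules.stopwords:
            continue
        counts[token] += 1
    return counts


# ---------------------------------------------------------------------------
# Readers / writers for the external formats
# ---------------------------------------------------------------------------

def read_abstracts_jsonl(path: str | Path) -> list[AbstractRecord]:
    """Read abstract records from JSON Lines with keys id, title, abstract."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            try:
                records.append(
                    AbstractRecord(
                        citation_id=str(obj["id"]),
                        title=obj.get("title", "") or "",
                        body=obj.get("abstract", "") or "",
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad abstract record: {exc}")
    seen = Counter(r.citation_id for r in records)
    dupes = [cid for cid, n in seen.items() if n > 1]
    if dupes:
        raise ValueError(f"{path}: duplicate citation id(s): {dupes[:5]}")
    return records


def write_abstracts_jsonl(records: Iterable[AbstractRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in records:
            fh.write(json.dumps(
                {"id": r.citation_id, "title": r.title, "abstract": r.body}
            ) + "\n")


def read_gene2pubmed(
    path: str | Path,
    tax_ids: set[str] | None = None,
) -> list[GeneCitationLink]:
    """Read gene-citation links from a gene2pubmed-style TSV.

    Expected columns: tax_id, GeneID, PubMed_ID (header row optional,
    detected by a leading '#' or a non-numeric tax_id field). ``tax_ids``
    optionally restricts to the given taxa.
    """
    links = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            tax, gene, pmid = parts[0], parts[1], parts[2]
            if lineno == 1 and not tax.isdigit() and tax.lower() == "tax_id":
                continue
            if tax_ids is not None and tax not in tax_ids:
                continue
            links.append(GeneCitationLink(gene_id=gene, citation_id=pmid))
    return dedupe_links(links)


def write_links_tsv(links: Iterable[GeneCitationLink], path: str | Path,
                    tax_id: str = "0") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#tax_id\tGeneID\tPubMed_ID\n")
        for l in sorted(set(links)):
            fh.write(f"{tax_id}\t{l.gene_id}\t{l.citation_id}\n")


def read_ortholog_pairs(path: str | Path) -> OrthologMap:
    """Read a two-column TSV of orthologous gene-id pairs."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((parts[0], parts[1]))
    return OrthologMap.from_pairs(pairs)


def read_gene_symbols(path: str | Path) -> dict[str, str]:
    """Read a gene_info-style TSV (GeneID, Symbol) into a symbol->id map.

    The returned mapping resolves both symbols and ids to ids (an id maps
    to itself), which is what gene-set resolution needs.
    """
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            gene_id, symbol = parts[0], parts[1]
            mapping[gene_id] = gene_id
            if symbol:
                mapping[symbol] = gene_id
    return mapping


def build_corpus(
    abstracts: Sequence[AbstractRecord],
    links: Iterable[GeneCitationLink],
    orthologs: OrthologMap | None = None,
    max_genes_per_citation: int = DEFAULT_MAX_GENES_PER_CITATION,
) -> tuple[list[GeneDocument], dict[str, int]]:
    """Full pipeline: filter promiscuous citations, merge orthologs, build docs.

    Returns the gene documents and the promiscuity-removal report.
    """
    filtered, removed = filter_promiscuous_citations(links, max_genes_per_citation)
    if orthologs is not None:
        filtered = merge_ortholog_citations(filtered, orthologs)
    return build_gene_documents(abstracts, filtered), removed
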