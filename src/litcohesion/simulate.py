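"""Synthetic literature corpora with known topic structure.

Generates abstract records and gene-citation links whose statistical shape
mimics a real gene-document collection: heavy-tailed abstracts-per-gene
counts (median of a few, many single-abstract genes, a long right tail),
latent topics so that designated gene sets share vocabulary, promiscuous
citations linked to many genes, and "well-studied" genes whose large
abstract sets mix many topics.

All randomness flows from one seed expanded into per-stage substreams, so
adding a later generation stage never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .corpus import (
    AbstractRecord,
    GeneCitationLink,
    write_abstracts_jsonl,
    write_links_tsv,
)

_LETTERS = "abcdefghij"


def _alpha(i: int) -> str:
    """Digits of i spelled with letters, so tokens stay alphabetic."""
    return "".join(_LETTERS[int(d)] for d in str(i))


def topic_word(topic: int, i: int) -> str:
    return f"t{_alpha(topic)}z{_alpha(i)}"


def background_word(i: int) -> str:
    return f"bgz{_alpha(i)}"


# ---------------------------------------------------------------------------
# Spec
# ---------------------------------------------------------------------------

@dataclass
class CorpusSpec:
    """Fully seeds-deterministic description of a synthetic corpus."""

    n_genes: int = 100
    n_topics: int = 4
    vocab_per_topic: int = 60
    background_vocab: int = 40
    background_mix: float = 0.2
    abstracts_family: str = "lognormal"  # or "fixed"
    abstracts_median: float = 3.0
    abstracts_sigma: float = 1.2
    words_per_abstract: float = 30.0
    wellstudied_fraction: float = 0.0
    wellstudied_boost: float = 15.0
    #: topics each well-studied gene mixes over (0 = all topics)
    wellstudied_topics: int = 3
    promiscuous_citations: int = 0
    promiscuous_genes_range: tuple[int, int] = (11, 25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_topics < 1:
            raise ValueError("n_genes and n_topics must be >= 1")
        if self.vocab_per_topic < 1:
            raise ValueError("topic vocabulary must be non-empty")
        for name in ("background_mix", "wellstudied_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_vocab < 1 and self.background_mix > 0:
            raise ValueError("background_mix > 0 requires background vocabulary")
        if self.abstracts_family not in ("lognormal", "fixed"):
            raise ValueError(f"unknown abstracts family {self.abstracts_family!r}")
        if self.abstracts_median < 1 or self.words_per_abstract < 1:
            raise ValueError("abstract and word count targets must be >= 1")
        if self.promiscuous_citations and self.n_genes <= self.promiscuous_genes_range[0]:
            raise ValueError(
                "promiscuous citations need more genes than the lower link bound"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "CorpusSpec":
        with open(path, encoding="utf-8") as fh:
            obj = yaml.safe_load(fh)
        if "promiscuous_genes_range" in obj:
            obj["promiscuous_genes_range"] = tuple(obj["promiscuous_genes_range"])
        return cls(**obj)

    def to_file(self, path: str | Path) -> None:
        obj = asdict(self)
        obj["promiscuous_genes_range"] = list(self.promiscuous_genes_range)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(obj, fh, sort_keys=True)


@dataclass
class TruthLabels:
    """Ground truth for a generated corpus."""

    topic_of: dict[str, int]
    wellstudied: set[str] = field(default_factory=set)
    n_topics: int = 1

    def genes_in_topic(self, topic: int) -> list[str]:
        return sorted(g for g, t in self.topic_of.items() if t == topic)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_id\ttopic\twellstudied\n")
            for g in sorted(self.topic_of):
                ws = int(g in self.wellstudied)
                fh.write(f"{g}\t{self.topic_of[g]}\t{ws}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthLabels":
        topic_of: dict[str, int] = {}
        wellstudied: set[str] = set()
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                g, t, ws = line.rstrip("\n").split("\t")
                topic_of[g] = int(t)
                if ws == "1":
                    wellstudied.add(g)
        n_topics = max(topic_of.values()) + 1 if topic_of else 1
        return cls(topic_of=topic_of, wellstudied=wellstudied, n_topics=n_topics)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _abstract_counts(spec: CorpusSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.abstracts_family == "fixed":
        return np.full(spec.n_genes, int(round(spec.abstracts_median)))
    # shifted discretized lognormal: 1 + floor(X), median(X) = abstracts_median
    x = rng.lognormal(math.log(spec.abstracts_median), spec.abstracts_sigma,
                      size=spec.n_genes)
    return 1 + np.floor(x).astype(int)


def generate_corpus(
    spec: CorpusSpec,
) -> tuple[list[AbstractRecord], list[GeneCitationLink], TruthLabels]:
    """Generate (abstracts, links, truth) deterministically from the spec.

    Each ordinary gene's abstracts draw ``1 - background_mix`` of their
    words from the gene's topic vocabulary and the rest from the shared
    background. Well-studied genes get boosted abstract counts and draw
    each abstract's topic uniformly from a per-gene random topic subset
    (``wellstudied_topics``; 0 means all topics). Promiscuous citations
    are extra background-vocabulary records linked to more than ten genes.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rng_ws = np.random.default_rng(streams[0])
    rng_counts = np.random.default_rng(streams[1])
    rng_text = np.random.default_rng(streams[2])
    rng_prom = np.random.default_rng(streams[3])

    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    topic_of = {g: i % spec.n_topics for i, g in enumerate(genes)}

    n_ws = int(round(spec.wellstudied_fraction * spec.n_genes))
    wellstudied = set(
        np.asarray(genes)[rng_ws.choice(spec.n_genes, size=n_ws, replace=False)]
    ) if n_ws else set()
    # each well-studied gene spans its own random handful of topics, so two
    # well-studied genes rarely share a literature profile
    n_mix = spec.wellstudied_topics
    if n_mix <= 0 or n_mix > spec.n_topics:
        n_mix = spec.n_topics
    mix_topics = {
        g: rng_ws.choice(spec.n_topics, size=n_mix, replace=False)
        for g in sorted(wellstudied)
    }

    counts = _abstract_counts(spec, rng_counts)
    for i, g in enumerate(genes):
        if g in wellstudied:
            counts[i] = max(counts[i], int(round(counts[i] * spec.wellstudied_boost)))

    topic_vocab = [
        [topic_word(t, i) for i in range(spec.vocab_per_topic)]
        for t in range(spec.n_topics)
    ]
    bg_vocab = [background_word(i) for i in range(max(spec.background_vocab, 1))]

    abstracts: list[AbstractRecord] = []
    links: list[GeneCitationLink] = []
    next_cid = 0

    def new_cid() -> str:
        nonlocal next_cid
        cid = f"pm{next_cid:08d}"
        next_cid += 1
        return cid

    for i, gene in enumerate(genes):
        for _ in range(counts[i]):
            if gene in wellstudied:
                pool = mix_topics[gene]
                topic = int(pool[rng_text.integers(len(pool))])
            else:
                topic = topic_of[gene]
            n_words = max(1, int(rng_text.poisson(spec.words_per_abstract)))
            from_bg = rng_text.random(n_words) < spec.background_mix
            words = [
                bg_vocab[rng_text.integers(len(bg_vocab))]
                if bg else topic_vocab[topic][rng_text.integers(spec.vocab_per_topic)]
                for bg in from_bg
            ]
            cut = min(3, len(words))
            cid = new_cid()
            abstracts.append(
                AbstractRecord(
                    citation_id=cid,
                    title=" ".join(words[:cut]),
                    body=" ".join(words[cut:]),
                )
            )
            links.append(GeneCitationLink(gene_id=gene, citation_id=cid))

    lo, hi = spec.promiscuous_genes_range
    hi = min(hi, spec.n_genes)
    for _ in range(spec.promiscuous_citations):
        n_linked = int(rng_prom.integers(lo, hi + 1))
        targets = rng_prom.choice(spec.n_genes, size=n_linked, replace=False)
        n_words = max(1, int(rng_prom.poisson(spec.words_per_abstract)))
        words = [bg_vocab[rng_prom.integers(len(bg_vocab))] for _ in range(n_words)]
        cid = new_cid()
        abstracts.append(
            AbstractRecord(
                citation_id=cid,
                title=" ".join(words[:3]),
                body=" ".join(words[3:]),
            )
        )
        links.extend(GeneCitationLink(gene_id=genes[t], citation_id=cid)
                     for t in targets)

    truth = TruthLabels(
        topic_of=topic_of, wellstudied=wellstudied, n_topics=spec.n_topics
    )
    return abstracts, links, truth


def make_gene_sets(
    labels: TruthLabels,
    n_cohesive: int,
    n_null: int,
    size: int,
    seed: int = 0,
) -> tuple[list[list[str]], list[list[str]]]:
    """Sample same-topic ("cohesive") and uniform-random ("null") gene sets.

    Cohesive sets are drawn within one topic chosen uniformly among topics
    with at least ``size`` genes; null sets are drawn from all genes. Sets
    contain no duplicates.
    """
    rng = np.random.default_rng(seed)
    all_genes = sorted(labels.topic_of)
    populations = [labels.genes_in_topic(t) for t in range(labels.n_topics)]
    viable = [p for p in populations if len(p) >= size]
    if n_cohesive and not viable:
        raise ValueError(
            f"no topic has {size} genes (max population "
            f"{max(len(p) for p in populations)})"
        )
    if size > len(all_genes):
        raise ValueError("set size exceeds the gene population")
    cohesive = []
    for _ in range(n_cohesive):
        pop = viable[int(rng.integers(len(viable)))]
        idx = rng.choice(len(pop), size=size, replace=False)
        cohesive.append(sorted(np.asarray(pop)[idx]))
    null = []
    for _ in range(n_null):
        idx = rng.choice(len(all_genes), size=size, replace=False)
        null.append(sorted(np.asarray(all_genes)[idx]))
    return cohesive, null


def write_corpus(
    out_dir: str | Path,
    abstracts: Sequence[AbstractRecord],
    links: Sequence[GeneCitationLink],
    truth: TruthLabels,
) -> dict[str, str]:
    """Write abstracts.jsonl, links.tsv and truth.tsv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abstracts": str(out / "abstracts.jsonl"),
        "links": str(out / "links.tsv"),
        "truth": str(out / "truth.tsv"),
    }
    write_abstracts_jsonl(abstracts, paths["abstracts"])
    write_links_tsv(links, paths["links"])
    truth.to_tsv(paths["truth"])
    return paths
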