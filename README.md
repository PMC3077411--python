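# litcohesion

Score the functional cohesion of a gene set from the literature alone.

Each gene is represented by a *document* — the concatenated titles and
abstracts of the citations cross-referenced to it. A term-by-gene matrix is
weighted with the log-entropy scheme, factorized with a truncated SVD
(latent semantic indexing), and genes are compared by the cosine of their
factor vectors. An edge threshold is calibrated empirically as the 95th
percentile of within-set cosines over many random gene sets, and a gene
set's **literature p-value (LPv)** is the one-sided Fisher's-exact-test
p-value of its count of above-threshold pairs against that calibrated
background. A small LPv means the set shares literature far beyond chance.

The package also ships a synthetic-corpus generator with known topic
structure (heavy-tailed abstracts-per-gene counts, promiscuous citations,
"well-studied" genes mixing several topics), so the whole pipeline is
testable without downloading anything.

## Library quick start

```python
import litcohesion as lc

# synthetic corpus with 12 topics
spec = lc.CorpusSpec(n_genes=240, n_topics=12, seed=7)
abstracts, links, truth = lc.generate_corpus(spec)

# documents -> weighted matrix -> rank-k model -> cosines
docs, removed = lc.build_corpus(abstracts, links)   # drops citations with > 10 genes
model, tgm = lc.fit_from_documents(docs)            # k = min(300, rank)
sim = lc.similarity_matrix(model)

# calibrate the edge threshold and score a gene set
calib = lc.calibrate_threshold(sim, n_sets=1000, size_range=(50, 400), seed=7)
result = lc.lpv_for_gene_set(["g00000", "g00012", "g00024"], sim, calib)
print(result.lpv, result.contingency)
```

## Command line

The `litcohesion` entry point chains the pipeline; every command writes a
`manifest.json` with the resolved config, seeds, and input fingerprints.

```sh
litcohesion simulate  --genes 240 --topics 12 --seed 7 --out run/corpus
litcohesion fit       --abstracts run/corpus/abstracts.jsonl \
                      --links run/corpus/links.tsv --out run/model
litcohesion calibrate --model run/model/model.npz --sets 1000 \
                      --min-size 50 --max-size 400 --seed 7 --out run/calib
litcohesion lpv       --model run/model/model.npz --genes my_genes.txt \
                      --calibration run/calib/calibration.json --out run/lpv
litcohesion graph     --model run/model/model.npz --genes my_genes.txt \
                      --calibration run/calib/calibration.json \
                      --counts run/model/abstract_counts.tsv \
                      --format graphml --out run/graph.graphml
```

Input formats: abstracts as JSON Lines (`id`, `title`, `abstract`); gene
links as gene2pubmed-style TSV (`tax_id`, `GeneID`, `PubMed_ID`); orthologs
as a two-column TSV of gene-id pairs; gene sets as newline-delimited ids or
symbols (`--symbols` takes a gene_info-style TSV). Graphs export to
GraphML, SIF, or a pair TSV.

`litcohesion lpv --threshold 0.6` bypasses calibration; it then needs an
explicit background, either `--background K M` or
`--background-proportion p --background-total N`.

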