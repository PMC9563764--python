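# ctpathway

Crosstalk-based pathway enrichment analysis.

Classical enrichment methods score each pathway in isolation from the genes
that happen to be differentially expressed inside it. `ctpathway` instead
propagates per-gene differential-expression (DE) scores over a merged gene
interaction network — pathway-derived interactions, protein–protein
interactions and TF→gene regulations combined into one undirected graph —
using a multi-seed random walk with restart. Every network gene receives a
propagated *risk score*; a pathway's enrichment score is the mean risk of
its member genes, so a pathway can rank highly through crosstalk with
perturbed neighbours even when few of its own genes pass a DE threshold.

Pipeline stages:

1. **gpcm** — assemble the global pathway crosstalk map from edge tables
   (with per-source filtering rules) and expose its column-stochastic
   transition operator.
2. **profiles** — parse DE tables and compute the fold-change/P-value DE
   score on [0, 1].
3. **propagation** — multi-seed random walk with restart (default restart
   0.7, L1 convergence 1e-10) with an ε-digit truncation of the crosstalk
   matrix (default ε = 3) for speed.
4. **scoring** — gene risk scores (crosstalk-weighted DE sums) and mean
   pathway scores.
5. **significance** — gene-label permutation null (default h = 1000),
   generalized-Pareto refinement of sub-resolution P-values,
   Benjamini–Hochberg FDR (significance at FDR < 0.01).
6. **redundancy** — Jaccard similarity network (cutoff 0.3) over significant
   pathways, Markov clustering, lowest-FDR representatives, display caps
   (20 clusters / 10 members).
7. **metrics** — benchmark formulas (rank difference, time difference, rank
   ratio, stability).
8. **fixtures** — synthetic scale-free networks, neighbourhood-sampled
   pathway collections and planted-signal DE profiles, so the whole pipeline
   is testable without external data.

## Command line

Generate a synthetic data set, run the pipeline, compute benchmark metrics:

```sh
ctpathway simulate --out sim --seed 1            # edges.tsv, pathways.gmt, profile.tsv
ctpathway run \
    --profile sim/profile.tsv --edges sim/edges.tsv --gmt sim/pathways.gmt \
    --out results --permutations 1000 --seed 1
ctpathway metrics --records benchmarks.tsv
```

`run` writes `results.tsv` (pathway_id, name, source_db, n, PS, p_empirical,
p_final, FDR, significant; sorted by FDR), `clusters.tsv`, the enrichment-map
tables `map_nodes.tsv`/`map_edges.tsv`, and `run_meta.tsv` (all parameters
plus input hashes — enough to reproduce the run byte-for-byte).

Input formats: edge TSV (`gene_a TAB gene_b [TAB origin]`, or a combined
file with a `source` column; separate `--edges-ppi`/`--edges-tf` flags are
also accepted), standard GMT gene sets, and a header-bearing profile TSV
(`gene`, `log2fc`/`fc`, `pvalue`; choose the fold-change scale with
`--fc-scale`). One identifier namespace (symbols or entrez) per run.

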