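# modrepo

Module-based drug repositioning from case/control expression data.

The pipeline has two arms:

1. **Disease-module mining** — genes passing an empirical-Bayes moderated
   differential-expression filter are clustered into co-expression modules
   (unsigned weighted network, topological-overlap dissimilarity,
   average-linkage tree with a static cut).  A GWAS seed gene list is
   expanded one regulatory layer, and each module is scored by the *signed
   log hypergeometric point probability* of its overlap with the expanded
   network: `f(pts) = sign(K/N − k/n) · log10(pmf(k; N, K, n))`.  Modules
   with positive scores are disease-specific; each gets a high-confidence
   PPI subnetwork annotated with dysregulation direction, candidate
   priority (1, 1/2, 1/4 for seed / one-layer-extension / other genes) and
   a node-importance RP-score.
2. **Drug scoring** — per (drug, target): a signed probability-weighted
   evidence sum `conf(d,p)`, a network weight
   `weight(p) = k·ln(strength) − ln(degree)`, and the pharmacology score
   `P-score = conf × weight`.  Per (drug, module), the Drug Effect Score
   (DES) sums `sign · log2|P-score| · log2(RP-score) · priority` over module
   targets, with positive sign exactly when the drug's net action opposes
   the gene's dysregulation.  The Drug Effect Sum Score
   `DESS = Σ DES(d,m) · f_m(pts)` over selected modules ranks the drugs;
   the top fraction (default 1%) is flagged.

A synthetic generator (`modrepo.synth`) produces every pipeline input with
known ground truth — planted co-expression blocks, per-tissue case shifts,
a scale-free-ish confidence-weighted PPI graph, seed-centred regulatory
edges, and a drug roster containing one designed therapeutic whose target
actions reverse every planted shift — so the whole pipeline is testable
offline.

## CLI

Stages are chained through a run directory of plain TSV artifacts; a
`manifest.json` records the configuration, seed, and input hashes.

```sh
# generate a synthetic bundle with ground truth
modrepo simulate --out-dir run --seed 1

# run everything: diffexpr -> modules -> expand -> enrich -> score
modrepo all --out-dir run --seed 1 \
    --expression run/expression.tsv --samples run/samples.tsv \
    --seeds run/seed_genes.txt --regulatory run/regulatory.tsv \
    --ppi run/ppi.tsv --drug-evidence run/drug_evidence.tsv
```

Stages can also be run individually (`diffexpr`, `modules`, `expand`,
`enrich`, `score`).  `enrich --counts counts.tsv` scores
`module, N, K, n, k` count rows directly.  Common knobs:
`--alpha`, `--power` (soft-threshold exponent; chosen by scale-free fit when
omitted), `--cut-height`, `--min-module-size`, `--ppi-threshold`,
`--k-const`, `--log-base`, `--top-fraction`, `--seed`.

Key outputs: `diffexpr.tsv` (per-gene statistics and accumulated
log-fold-change), `modules.tsv` (gene → module colour), `enrichment.tsv`
(`module, N, K, n, k, f_pts, rank, selected`), `module_<m>_{nodes,edges}.tsv`,
`drug_scores.tsv` (`dess`, per-module `des_*`, `rank`, `top`), and the
extended drug-target network node/edge tables.

## Layout

| module | role |
| --- | --- |
| `modrepo.io` | domain types, TSV readers/writers, run configuration |
| `modrepo.diffexpr` | probe aggregation, sample dispersion, moderated t/F |
| `modrepo.coexpr` | soft threshold, TOM, module detection, eigengenes |
| `modrepo.disease` | seed expansion, f(pts) enrichment, module networks |
| `modrepo.drugs` | conf/weight/P-score/RP-score/DES/DESS, ranking, exports |
| `modrepo.synth` | synthetic input bundles with ground truth |
| `modrepo.pipeline`, `modrepo.cli` | orchestration and the `modrepo` CLI |
| `modrepo.bench` | recovery benchmarks used by the acceptance suite |
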