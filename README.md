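# orthotype

Cross-species comparison of cell types from single-cell RNA-seq atlases.

When two species' atlases are profiled independently, their gene spaces are
incompatible: lineage-specific duplications mean one gene in species A may
correspond to several paralogues in species B. `orthotype` implements the
correlation-based homology workflow used for such comparisons:

1. **QC** — keep genes detected in ≥ 5 cells; drop cells with < 200 UMIs or
   an excessive mitochondrial fraction (5% or 10% depending on stage).
2. **Meta-genes** — sum the raw UMI counts of all paralogues belonging to
   the same orthogroup (an OrthoFinder-style orthology table), and replace
   species-specific gene IDs by numeric orthogroup indices 1..n shared by
   both species.
3. **Specificity index** — after log1p-CP10K normalization and selection of
   the top 3,000 highly variable meta-genes, average within annotated cell
   types and form

   s_{g,c} = g_c / ( (1/N) Σ_i g_i ),

   the mean expression of meta-gene *g* in type *c* divided by its mean
   over all *N* cells. s = 1 means unenriched; s > 1 means type-enriched.
4. **Matching** — Pearson correlation between the two species' specificity
   vectors over shared orthogroups; cell-type pairs are called as
   reciprocal best hits (RBH) of the correlation matrix, optionally
   restricted to a gene set such as transcription factors.
5. **Dendrograms** — complete-linkage clustering of all types of both
   species on the distance 1 − r, with clade support from a multiscale
   bootstrap over meta-genes: BP (bootstrap proportion at scale 1) and the
   approximately unbiased AU p-value fitted across resampling scales
   0.5–1.4 (1,000 replicates by default).
6. **Markers** — one-vs-rest Wilcoxon rank-sum marker detection
   (logFC ≥ 0.25, min.pct = 0.1, Bonferroni-adjusted P < 0.01).

Because real paired atlases are large downloads, the package ships a
first-class synthetic generator (`orthotype.simdata`) that emulates two
species with shared cell-type families, private types, gene duplications,
cell-type-specific expression programs and negative-binomial UMI counts —
with full ground truth, so the whole pipeline is testable offline.

## Worked example

```python
from orthotype import (QCParams, SimConfig, cluster_means, collapse_to_metagenes,
                       correlate_celltypes, normalize, qc_filter,
                       reciprocal_best_hits, simulate_atlas_pair, specificity_index)

data, truth = simulate_atlas_pair(SimConfig(seed=1))   # 2 x 3,200 cells
specs = {}
for sp in ("s1", "s2"):
    cm, ann = data[sp]
    cm, _ = qc_filter(cm, QCParams(mito_gene_ids=frozenset(truth.mito_genes[sp])))
    meta, _ = collapse_to_metagenes(cm, truth.orthomap, sp)
    nm = normalize(meta)
    means, sizes = cluster_means(nm, ann.subset(nm.cell_ids))
    specs[sp] = specificity_index(means, sizes)

corr = correlate_celltypes(specs["s1"], specs["s2"])
rbh = reciprocal_best_hits(corr)
```

With the default study conditions (1,500 orthogroups, 15% duplication per
species, 14 shared cell-type families plus 2 private types per species,
200 cells/type, 8-fold marker elevation, divergence 0.2) this prints:

```
RBH pairs: 15; true pairs recovered: 14/14
mean r of true pairs:  0.737
overall mean r:        0.000
```

All 14 planted homologous pairs are recovered as reciprocal best hits;
true pairs correlate at r ≈ 0.74 while the background sits at ≈ 0. The
same scripts live in `examples/` (simulation, QC/meta-genes, matching,
bootstrap dendrograms, markers), each printing the numbers it computes.

A thin CLI mirrors the library (`orthotype simulate|qc|collapse|
specificity|markers|compare|run|evaluate|config init`); `orthotype run
--config run.yaml` executes the full pipeline and writes a manifest with
SHA-256 hashes making every output reproducible from config + seed.

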