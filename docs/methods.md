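# Methods

This note documents the models, defaults and numerical choices behind
`orthotype`, and what the simulation-based tests do and do not demonstrate.

## The comparison model

Cross-species comparison of cell types assumes that homologous types retain
correlated gene-expression programs over orthologous genes. The unit of
comparison is the **orthogroup meta-gene**: the per-cell sum of raw UMI
counts over all of one species' paralogues in an orthogroup, indexed
identically (1..n) in both species. Summation is performed on raw counts
*before* normalization, so the meta-gene matrix is itself a valid UMI count
matrix and total counts over orthology-assigned genes are conserved exactly
(an integer identity, tested as such). Orthology genes absent from an
expression matrix contribute zero and are listed in the collapse report
rather than raising, tolerating annotation-version drift.

## Normalization and the specificity index

Counts are normalized as log1p-CP10K: x = log(1 + c·10⁴/total). The
specificity index

s_{g,c} = g_c / ḡ,  ḡ = (1/N) Σ_{i=1..N} g_i = Σ_c n_c g_c / N

is a ratio of means of the same normalized quantity, so it is invariant to
any global rescaling of the normalized matrix; consequently the choice of
per-cell normalization affects it only through relative cell weighting.
This is why a simple, fully documented normalization is used here rather
than a regularized negative-binomial model: the index, not the
normalization, carries the comparison. The normalization is recorded in
`normalization_tag` on every `SpecificityMatrix`.

Two readings of the index's denominator circulate: the grand mean over all
N cells (the interpretable one, default here) and a per-cluster sum
(1/N)Σ_{i∈c} g_i, which algebraically degenerates to s = N/n_c independent
of expression. The latter is available as
`specificity_index(..., denominator="within_cluster")` purely for
comparison. Genes with ḡ = 0 cannot be divided and are masked (listed in
`masked_genes`, excluded from correlation) instead of being set to an
arbitrary value. For every unmasked gene, Σ_c (n_c/N)·s_{g,c} = 1; the test
suite enforces this to 1e-9.

## QC

Filters run in a fixed, documented order: (1) genes detected (count > 0)
in fewer than 5 cells are removed; (2) cells with fewer than 200 UMIs are
removed; (3) cells whose mitochondrial fraction (computed on
post-gene-filter counts over an explicit mitochondrial gene list) exceeds
the threshold are removed. Defaults: 5 cells, 200 UMIs, mito 10% (adult) or
5% (larval) via `QCParams.for_stage`. Each removed cell is attributed to
exactly one filter, so report counts partition the input. The cell filters
are idempotent for a fixed gene set. An explicit mitochondrial list is
required because contig-based assignment is annotation-specific.

## Highly variable genes

The HVG statistic is the per-gene variance of normalized values, z-scored
within 20 equal-count bins of the gene mean, top-k selected (k = 3,000 by
default; if fewer genes exist all are returned with a warning).
Zero-variance genes are assigned −∞ so a constant gene can never outrank a
variable one. Binning compares each gene only against genes of similar
expression level — which is also why the synthetic generator draws
heterogeneous baseline expression (below): with a perfectly uniform
baseline, marker genes segregate into their own mean bins and binned
statistics lose their meaning.

## Marker detection

One-vs-rest two-sided Wilcoxon rank-sum test (normal approximation with
tie correction and continuity correction). Genes where neither group
reaches 10% detection are not tested and by default do not enter the
Bonferroni denominator (`bonferroni="all"` restores the conservative
variant). The log fold change is the natural log of the ratio of
de-normalized group means with pseudocount 1,
ln((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1)) — the convention of the
dominant scRNA-seq ecosystem, so the 0.25 threshold is interpretable; base
and pseudocount are configurable and echoed in the result's `attrs`. A
marker passes with logFC ≥ 0.25, the pct pre-filter, and adjusted P < 0.01.
Under a negative-binomial null (μ = 2, dispersion 0.5, 1,000 genes,
100 vs 100 cells) this combination detects nothing in ≥ 95% of runs —
Bonferroni at 0.01 is conservative — which the acceptance suite measures.

## Correlation, matching, dendrograms

Cell-type correlation is Pearson r between specificity vectors over the
orthogroups unmasked in both species (optionally intersected with a user
gene set, e.g. transcription factors); fewer than 3 shared genes is an
error, and a zero-variance vector yields NaN entries that are excluded
from matching. Matching is reciprocal best hits: (c1, c2) is a pair iff
each is the other's row/column argmax; exact ties are broken by
lexicographic label and flagged. RBH is a deliberately strict, symmetric
operationalization of cross-species type mapping; the full correlation
matrix is always emitted so other readings remain possible.

The joint dendrogram is complete-linkage agglomeration on d = 1 − r
(bounded [0, 2]). The implementation is deterministic: among equally close
cluster pairs, the lexicographically smallest pair of leaf-label tuples
merges first. The test suite checks it against an independent
implementation (scipy's) on 100 random instances.

## Multiscale bootstrap

Support resamples **meta-genes** (features), not cells, matching the
feature-perturbation logic of multiscale bootstrap clade support. For each
scale r ∈ {0.5, 0.6, …, 1.4} and replicate b, ⌈r·G⌉ orthogroups are drawn
with replacement (replicate RNG streams derived from (seed, scale index,
b), so results are reproducible and independent of execution order). BP of
a clade at scale r is the fraction of replicate trees containing exactly
its leaf set; the reported BP is the r = 1 value × 100. AU is obtained by
fitting z_r = v√r + c/√r to z_r = Φ⁻¹(1 − BP(r)) by weighted least squares
(delta-method inverse-variance weights n_boot·φ(z)²/(BP(1−BP))) over scales
with 0 < BP < 1, giving AU = (1 − Φ(v − c))·100. Degenerate nodes (BP 0 or
1 at every scale) clamp AU to 0/100 with flag `degenerate_bp`; a single
usable scale yields flag `au_unavailable` with BP still reported. A flat
BP(r) = 0.5 curve fits to AU = 50 exactly; a clade of duplicated profiles
has BP = 100 at every scale because resampling cannot break an exact tie.
n_boot defaults to 1,000.

## The synthetic generator

`simdata` emulates the statistical structure the comparison relies on, not
any particular tissue:

- **Orthology**: each of n orthogroups carries 1 + Bernoulli(p_dup) genes
  per species (one possible duplication round), yielding 1:1, 1:2 and 2:2
  cases while keeping gene trees bounded. Expected expression within an
  orthogroup is split across paralogues by Dirichlet(1,…,1) weights fixed
  per orthogroup, so meta-gene summation recovers the orthogroup total
  regardless of the split.
- **Programs**: each orthogroup's baseline mean is
  baseline_mean·LogNormal(0, baseline_sigma), drawn once and shared by
  both species (conserved expression levels). Each cell type elevates its
  marker orthogroups (a fraction frac_marker_genes of all orthogroups)
  fold_up-fold. The two types of a shared family keep (1 − divergence) of
  their markers in common; the re-drawn remainder excludes only the kept
  markers, so divergence = 1 produces fully independent sets whose overlap
  is hypergeometric.
- **Counts**: gene g in a cell of type t is NB with mean L·μ_{t,g} and
  variance μ + α·μ² (Gamma–Poisson; α = 0 is exactly Poisson), with
  library factor L ~ LogNormal(0, libsize_sigma) per cell. Ten dedicated
  mitochondrial genes per species (prefix `MT-`) receive mito_frac_mean of
  each type's expression mass.

Defaults define the study conditions used throughout the tests and the
acceptance script: 1,500 orthogroups, p_dup = 0.15 per species, 14 shared
families + 2 private types per species, 200 cells/type, frac_marker_genes
= 0.05 (75 markers/type), fold_up = 8, divergence = 0.2, dispersion 0.5,
libsize_sigma = 0.5, baseline_mean = 0.2 (≈ 400 UMIs/cell, a realistic
droplet depth that also exercises the 200-UMI filter on the low-L tail),
baseline_sigma = 0.5, mito_frac_mean = 0.03. Unit tests use scaled-down
variants (fewer orthogroups and cells, proportionally raised baseline so
per-cell depth stays above the QC threshold); the acceptance checks state
their sizes explicitly.

**What the generator does not emulate**: batch effects, ambient RNA,
doublets, cell-type abundance imbalance, correlated gene modules beyond
the marker programs, or more than two species. Passing tests therefore
demonstrate the pipeline's correctness and its sensitivity under the
stated noise model — not robustness to the full messiness of real atlases.
The true-pair recovery numbers are properties of these synthetic
conditions, not of any real species pair.

## Determinism

Every stochastic component takes an explicit seed. A pipeline run writes a
manifest (parameters, seed, SHA-256 of every artifact); rerunning an
identical configuration reproduces all artifacts byte for byte, which the
acceptance suite verifies.

## Known limitations

- The specificity index weights clusters by size through the grand mean; a
  very large cluster can dominate ḡ.
- AU is asymptotic in n_boot and the scale grid; for clades observed at
  only one non-degenerate scale it is reported as unavailable rather than
  extrapolated.
- RBH produces at most min(#types) pairs and cannot express one-to-many
  homology; consult the correlation matrix and the dendrogram for those
  cases.
- Orthogroups missing from one species' expression data are zero-imputed
  (flagged), which biases their specificity toward 0 in that species.
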