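"""Normalization, highly variable gene selection, cluster averaging and the
gene specificity index.

Normalization is log1p-CP10K: each cell's counts are scaled to a common
library size (10,000 by default) and log(1 + x)-transformed.  The
specificity index of gene g in cell type c is

    s_{g,c} = g_c / g_bar,

where g_c is the mean normalized expression of g over the cells of type c
and g_bar its mean over ALL cells, computed from cluster means as
sum_c n_c * g_c / N.  A value of 1 means unenriched; values above 1 mark
type-enriched expression.  Because the index is a ratio of means of the
same normalized quantity, it is invariant to any global rescaling of the
normalized matrix.  Genes with zero overall mean are masked rather than
divided.

An alternative ``denominator="within_cluster"`` reading — normalizing each
cluster mean by (1/N) * sum over only that cluster's cells, which reduces
to s = N / n_c independent of expression — is provided for comparison with
the index's printed formula in the literature; the all-cells reading is the
default and the one with the intended interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import DataError, ValidationError
from .io import CellAnnotation, CountMatrix


@dataclass
class NormalizedMatrix:
    """Genes x cells matrix of log1p-CP10K (or similarly scaled) values."""

    values: sparse.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    species_tag: str = ""
    normalization_tag: str = "log1p_cp10k"

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class SpecificityMatrix:
    """Meta-genes x cell-types specificity indices with cluster sizes."""

    values: pd.DataFrame  # unmasked genes x cell types
    cluster_sizes: pd.Series  # cells per type
    N: int
    normalization_tag: str = "log1p_cp10k"
    masked_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.cluster_sizes.index):
            raise DataError("specificity columns and cluster_sizes disagree")
        if (self.values.to_numpy() < 0).any():
            raise DataError("negative specificity values")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


def normalize(m: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """log(1 + count * scale / cell_total), preserving the sparsity pattern."""
    totals = m.cell_totals()
    if np.any(totals == 0):
        bad = [c for c, t in zip(m.cell_ids, totals) if t == 0]
        raise DataError(f"cells with zero total counts: {bad[:10]}")
    mat = sparse.csc_matrix(m.counts, dtype=np.float64)
    # scale each column (cell) by scale/total, then log1p on stored entries
    mat = mat @ sparse.diags(scale / totals)
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(
        sparse.csr_matrix(mat),
        list(m.gene_ids),
        list(m.cell_ids),
        m.species_tag,
        "log1p_cp10k",
    )


def select_hvgs(nm: NormalizedMatrix, k: int = 3000, n_bins: int = 20) -> np.ndarray:
    """Indices of the top-*k* highly variable genes.

    The dispersion statistic is the variance of the normalized values,
    z-scored within equal-count bins of the gene mean so that highly
    expressed genes do not dominate.  Genes with zero variance are never
    ranked above genes with positive variance.  If fewer than *k* genes
    exist, all are returned with a warning.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    csr = sparse.csr_matrix(nm.values)
    n = nm.n_cells
    means = np.asarray(csr.mean(axis=1)).ravel()
    sq = csr.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = np.maximum(ex2 - means**2, 0.0) * (n / max(n - 1, 1))

    n_genes = nm.n_genes
    n_bins_eff = min(n_bins, n_genes)
    order = np.argsort(means, kind="stable")
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(n_genes) * n_bins_eff) // n_genes, n_bins_eff - 1
    )
    stat = np.empty(n_genes)
    for b in range(n_bins_eff):
        sel = bins == b
        v = var[sel]
        sd = v.std()
        stat[sel] = (v - v.mean()) / sd if sd > 0 else 0.0
    stat[var == 0] = -np.inf  # constant genes are never variable

    if n_genes <= k:
        warnings.warn(f"only {n_genes} genes available for k={k}; returning all")
        ranked = np.argsort(-stat, kind="stable")
        return ranked
    return np.argsort(-stat, kind="stable")[:k]


def cluster_means(
    nm: NormalizedMatrix, ann: CellAnnotation
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cluster arithmetic means of normalized values.

    Returns a genes x cell-types DataFrame and the cluster sizes, clusters
    ordered by label.  Every cell of the matrix must be annotated.
    """
    labels = ann.labels_for(nm.cell_ids)
    types = sorted(labels.unique())
    onehot_rows, onehot_cols = [], []
    type_index = {t: i for i, t in enumerate(types)}
    for j, lab in enumerate(labels):
        onehot_rows.append(j)
        onehot_cols.append(type_index[lab])
    onehot = sparse.csr_matrix(
        (np.ones(len(onehot_rows)), (onehot_rows, onehot_cols)),
        shape=(nm.n_cells, len(types)),
    )
    sizes = np.asarray(onehot.sum(axis=0)).ravel()
    sums = np.asarray((nm.values @ onehot).todense())
    means = sums / sizes[np.newaxis, :]
    df = pd.DataFrame(means, index=nm.gene_ids, columns=types)
    return df, pd.Series(sizes.astype(int), index=types, name="n_cells")


def specificity_index(
    means: pd.DataFrame,
    cluster_sizes: pd.Series,
    normalization_tag: str = "log1p_cp10k",
    denominator: str = "all_cells",
) -> SpecificityMatrix:
    """Transform cluster means into specificity indices s_{g,c}."""
    if list(means.columns) != list(cluster_sizes.index):
        raise DataError("means columns and cluster_sizes index disagree")
    if (cluster_sizes <= 0).any():
        empty = list(cluster_sizes.index[cluster_sizes <= 0])
        warnings.warn(f"dropping empty clusters: {empty}")
        means = means.drop(columns=empty)
        cluster_sizes = cluster_sizes.drop(index=empty)
    n_c = cluster_sizes.to_numpy(dtype=float)
    N = int(n_c.sum())

    g = means.to_numpy(dtype=float)
    if denominator == "all_cells":
        gbar = g @ n_c / N  # grand mean over all N cells
        mask = gbar > 0
        s = np.full_like(g, np.nan)
        s[mask] = g[mask] / gbar[mask, np.newaxis]
    elif denominator == "within_cluster":
        # literal per-cluster reading: (1/N) sum_{i in c} g_i = n_c*g_c/N
        denom = n_c[np.newaxis, :] * g / N
        mask = (g > 0).any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(denom > 0, g / denom, np.nan)
    else:
        raise ValidationError(f"unknown denominator mode {denominator!r}")

    masked = [gid for gid, ok in zip(means.index, mask) if not ok]
    values = pd.DataFrame(
        s[mask], index=means.index[mask], columns=means.columns
    )
    return SpecificityMatrix(
        values=values,
        cluster_sizes=cluster_sizes.astype(int),
        N=N,
        normalization_tag=f"{normalization_tag}|spec:{denominator}",
        masked_genes=masked,
    )
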