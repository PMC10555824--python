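"""Quality-control filters for UMI count matrices.

The filters and their defaults follow standard droplet scRNA-seq practice:
genes must be detected (count > 0) in at least 5 cells; cells must contain
at least 200 UMIs and at most a stage-dependent fraction of mitochondrial
UMIs (5% for larval tissue, 10% for adult).  The filter order is fixed and
documented: gene filter first, then the UMI filter, then the mitochondrial
filter, with the mitochondrial fraction computed on post-gene-filter counts
and each removed cell attributed to exactly one filter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, ValidationError
from .io import CountMatrix

MITO_FRAC_LARVA = 0.05
MITO_FRAC_ADULT = 0.10


@dataclass
class QCParams:
    min_cells_per_gene: int = 5
    min_umis_per_cell: int = 200
    max_mito_frac: float = MITO_FRAC_ADULT
    mito_gene_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.min_cells_per_gene < 0 or self.min_umis_per_cell < 0:
            raise ValidationError("QC thresholds must be non-negative")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValidationError("max_mito_frac must lie in [0, 1]")
        self.mito_gene_ids = frozenset(self.mito_gene_ids)

    @classmethod
    def for_stage(cls, stage: str, mito_gene_ids=frozenset(), **kw) -> "QCParams":
        frac = {"larva": MITO_FRAC_LARVA, "adult": MITO_FRAC_ADULT}.get(stage)
        if frac is None:
            raise ValidationError(f"unknown stage {stage!r} (larva|adult)")
        return cls(max_mito_frac=frac, mito_gene_ids=mito_gene_ids, **kw)


@dataclass
class QCReport:
    n_genes_in: int = 0
    n_cells_in: int = 0
    n_genes_removed: int = 0
    n_cells_removed_umi: int = 0
    n_cells_removed_mito: int = 0
    n_genes_out: int = 0
    n_cells_out: int = 0
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return Path(path)


def qc_filter(m: CountMatrix, params: QCParams) -> tuple[CountMatrix, QCReport]:
    """Apply gene -> UMI -> mitochondrial filters in that fixed order."""
    extras = params.mito_gene_ids - set(m.gene_ids)
    if extras:
        warnings.warn(
            f"{len(extras)} mitochondrial gene ids absent from matrix, ignored"
        )

    report = QCReport(
        n_genes_in=m.n_genes,
        n_cells_in=m.n_cells,
        params={
            "min_cells_per_gene": params.min_cells_per_gene,
            "min_umis_per_cell": params.min_umis_per_cell,
            "max_mito_frac": params.max_mito_frac,
            "n_mito_genes": len(params.mito_gene_ids & set(m.gene_ids)),
        },
    )

    # 1. gene filter: detected (count > 0) in >= min_cells_per_gene cells
    cells_per_gene = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= params.min_cells_per_gene
    report.n_genes_removed = int((~keep_genes).sum())
    counts = m.counts[keep_genes]
    gene_ids = [g for g, k in zip(m.gene_ids, keep_genes) if k]

    # 2. cell UMI filter on post-gene-filter counts
    totals = np.asarray(counts.sum(axis=0)).ravel()
    keep_umi = totals >= params.min_umis_per_cell
    report.n_cells_removed_umi = int((~keep_umi).sum())

    # 3. mitochondrial fraction filter among cells surviving step 2
    mito_mask = np.array([g in params.mito_gene_ids for g in gene_ids])
    if mito_mask.any():
        mito_counts = np.asarray(counts[mito_mask].sum(axis=0)).ravel()
    else:
        mito_counts = np.zeros(counts.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep_mito = mito_frac <= params.max_mito_frac
    report.n_cells_removed_mito = int((keep_umi & ~keep_mito).sum())

    keep_cells = keep_umi & keep_mito
    if not keep_cells.any():
        raise DataError("empty matrix after QC: all cells removed")

    counts = counts[:, keep_cells]
    cell_ids = [c for c, k in zip(m.cell_ids, keep_cells) if k]
    report.n_genes_out = counts.shape[0]
    report.n_cells_out = counts.shape[1]
    return CountMatrix(counts, gene_ids, cell_ids, m.species_tag), report
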