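"""Containers and readers/writers for the formats the pipeline touches.

Count matrices are genes x cells sparse integer matrices, read and written
either as a 10x-style MatrixMarket triplet (``matrix.mtx`` + ``genes.tsv`` +
``barcodes.tsv``) or as a dense TSV with gene rows and cell columns.
Orthology tables follow the OrthoFinder ``Orthogroups.tsv`` dialect: one row
per orthogroup, one column per species, gene lists joined by ", ".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import DataError, ValidationError
from .orthomap import OrthoMap


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = sorted(set(seen[seen.duplicated()]))
        raise DataError(f"duplicate {what}: {dup[:10]}")


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix for one species."""

    counts: sparse.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    species_tag: str = ""

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise DataError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids / {len(self.cell_ids)} cell ids"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise DataError("negative counts present")
            if not np.allclose(data, np.round(data)):
                raise DataError("non-integer counts present")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()


@dataclass
class CellAnnotation:
    """Per-cell cluster / cell-type labels with optional extra metadata."""

    table: pd.DataFrame  # indexed by cell_id, column "cell_type" (+ extras)

    def __post_init__(self) -> None:
        if "cell_type" not in self.table.columns:
            raise DataError("annotation table lacks a 'cell_type' column")
        _check_unique(self.table.index, "annotated cell ids")
        labels = self.table["cell_type"].astype(str)
        if (labels.str.len() == 0).any():
            raise DataError("empty cell-type labels present")
        self.table = self.table.copy()
        self.table["cell_type"] = labels

    @classmethod
    def from_labels(cls, cell_ids, labels, **extra) -> "CellAnnotation":
        df = pd.DataFrame({"cell_type": list(labels)}, index=list(cell_ids))
        for k, v in extra.items():
            df[k] = v
        df.index.name = "cell_id"
        return cls(df)

    def labels_for(self, cell_ids: list[str]) -> pd.Series:
        missing = [c for c in cell_ids if c not in self.table.index]
        if missing:
            raise DataError(f"cells without annotation: {missing[:10]}")
        return self.table.loc[cell_ids, "cell_type"]

    def subset(self, cell_ids: list[str]) -> "CellAnnotation":
        keep = [c for c in cell_ids if c in self.table.index]
        return CellAnnotation(self.table.loc[keep])


# ---------------------------------------------------------------------------
# count matrix I/O


def write_mtx_triplet(m: CountMatrix, out_dir: str | Path) -> Path:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` into *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coo = sparse.coo_matrix(m.counts).astype(np.int64)
    spio.mmwrite(out / "matrix.mtx", coo, field="integer")
    with open(out / "genes.tsv", "w") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(out / "barcodes.tsv", "w") as fh:
        for c in m.cell_ids:
            fh.write(f"{c}\n")
    return out


def write_dense_tsv(m: CountMatrix, path: str | Path) -> Path:
    df = pd.DataFrame(
        m.counts.toarray(), index=m.gene_ids, columns=m.cell_ids, dtype=np.int64
    )
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    return Path(path)


def read_count_matrix(
    path: str | Path, dialect: str = "mtx_triplet", species_tag: str = ""
) -> CountMatrix:
    """Read a count matrix in the named *dialect*.

    ``mtx_triplet`` expects a directory with matrix.mtx, genes.tsv and
    barcodes.tsv; ``dense_tsv`` a single TSV with gene rows and cell columns.
    """
    path = Path(path)
    if dialect == "mtx_triplet":
        mat = spio.mmread(path / "matrix.mtx")
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        if mat.shape != (len(genes), len(cells)):
            raise DataError(
                f"matrix.mtx declares {mat.shape} but genes.tsv has "
                f"{len(genes)} rows and barcodes.tsv {len(cells)}"
            )
        return CountMatrix(
            sparse.csr_matrix(mat), list(genes), list(cells), species_tag
        )
    if dialect == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.allclose(
            arr, np.round(arr)
        ):
            raise DataError(f"non-integer entries in dense TSV {path}")
        return CountMatrix(
            sparse.csr_matrix(arr.astype(np.int64)),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            species_tag,
        )
    raise ValidationError(f"unknown count-matrix dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# annotation I/O


def read_annotation(path: str | Path) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns or "cell_type" not in df.columns:
        raise DataError(
            f"annotation TSV {path} must have 'cell_id' and 'cell_type' columns"
        )
    df = df.set_index("cell_id")
    return CellAnnotation(df)


def write_annotation(ann: CellAnnotation, path: str | Path) -> Path:
    out = ann.table.copy()
    out.index.name = "cell_id"
    out.to_csv(path, sep="\t")
    return Path(path)


# ---------------------------------------------------------------------------
# orthology I/O


@dataclass
class OrthologyReadReport:
    n_rows: int = 0
    n_kept: int = 0
    n_dropped_empty: int = 0
    dropped_ids: list[str] = field(default_factory=list)


def read_orthology(
    path: str | Path,
    species_columns: tuple[str, str] | None = None,
) -> tuple[OrthoMap, OrthologyReadReport]:
    """Parse an Orthogroups.tsv-dialect file into an :class:`OrthoMap`.

    Rows with an empty gene list for either species are dropped (counted in
    the report); a gene appearing in two orthogroups is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    if species_columns is None:
        rest = [c for c in df.columns if c != og_col]
        if len(rest) != 2:
            raise ValidationError(
                f"{path}: expected exactly two species columns, found {rest}; "
                "pass species_columns explicitly"
            )
        species_columns = (rest[0], rest[1])
    for col in species_columns:
        if col not in df.columns:
            raise ValidationError(f"unknown species column {col!r} in {path}")

    report = OrthologyReadReport(n_rows=len(df))
    genes_s1: list[tuple[str, ...]] = []
    genes_s2: list[tuple[str, ...]] = []
    for _, row in df.iterrows():
        g1 = tuple(g for g in (s.strip() for s in row[species_columns[0]].split(",")) if g)
        g2 = tuple(g for g in (s.strip() for s in row[species_columns[1]].split(",")) if g)
        if not g1 or not g2:
            report.n_dropped_empty += 1
            report.dropped_ids.append(str(row[og_col]))
            continue
        genes_s1.append(g1)
        genes_s2.append(g2)
    report.n_kept = len(genes_s1)
    omap = OrthoMap(genes_s1=genes_s1, genes_s2=genes_s2, provenance=str(path))
    if report.n_dropped_empty:
        warnings.warn(
            f"{path}: dropped {report.n_dropped_empty} orthogroups empty on one side"
        )
    return omap, report


def write_orthology(
    omap: OrthoMap,
    path: str | Path,
    species_names: tuple[str, str] = ("species1", "species2"),
) -> Path:
    with open(path, "w") as fh:
        fh.write(f"Orthogroup\t{species_names[0]}\t{species_names[1]}\n")
        for i in range(omap.n):
            fh.write(
                f"OG{i + 1:07d}\t"
                + ", ".join(omap.genes_s1[i])
                + "\t"
                + ", ".join(omap.genes_s2[i])
                + "\n"
            )
    return Path(path)
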