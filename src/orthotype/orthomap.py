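"""Orthogroup structure and paralogue-collapsing "meta-gene" aggregation.

An :class:`OrthoMap` links the gene sets of two species through shared
numeric orthogroup indices (1..n).  Collapsing a species' count matrix sums
the raw UMI counts of all paralogues in each orthogroup into a single
meta-gene row indexed identically in both species, so downstream
comparisons operate on a common feature space regardless of
lineage-specific duplications.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import DataError


@dataclass
class OrthoMap:
    """Bipartite orthogroup map: index i (1-based i+1) -> gene sets per species."""

    genes_s1: list[tuple[str, ...]]
    genes_s2: list[tuple[str, ...]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.genes_s1) != len(self.genes_s2):
            raise DataError("orthogroup lists differ in length between species")
        for side in ("s1", "s2"):
            seen: dict[str, int] = {}
            for idx, genes in enumerate(getattr(self, f"genes_{side}")):
                if len(genes) == 0:
                    raise DataError(f"orthogroup {idx + 1} empty on side {side}")
                for g in genes:
                    if g in seen:
                        raise DataError(
                            f"gene {g!r} appears in orthogroups "
                            f"{seen[g] + 1} and {idx + 1} ({side})"
                        )
                    seen[g] = idx

    @property
    def n(self) -> int:
        return len(self.genes_s1)

    def genes(self, side: str) -> list[tuple[str, ...]]:
        if side not in ("s1", "s2"):
            raise DataError(f"side must be 's1' or 's2', got {side!r}")
        return self.genes_s1 if side == "s1" else self.genes_s2

    def gene_index(self, side: str) -> dict[str, int]:
        """Map gene id -> 0-based orthogroup index for one species."""
        out: dict[str, int] = {}
        for idx, genes in enumerate(self.genes(side)):
            for g in genes:
                out[g] = idx
        return out

    def metagene_ids(self) -> list[str]:
        return [str(i + 1) for i in range(self.n)]


@dataclass
class CollapseReport:
    n_metagenes: int = 0
    n_genes_assigned: int = 0
    n_genes_dropped: int = 0
    missing_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_metagenes": self.n_metagenes,
            "n_genes_assigned": self.n_genes_assigned,
            "n_genes_dropped": self.n_genes_dropped,
            "n_missing_genes": len(self.missing_genes),
        }


def collapse_to_metagenes(m, ortho: OrthoMap, side: str):
    """Sum paralogue rows of *m* into orthogroup meta-gene rows.

    Returns a genes(=meta-genes) x cells :class:`~orthotype.io.CountMatrix`
    whose row ids are the shared numeric orthogroup indices, plus a
    :class:`CollapseReport`.  Genes of *m* not assigned to any orthogroup
    are dropped (counted); orthology genes absent from *m* contribute zero
    (listed).  Per-cell totals over assigned genes are conserved exactly.
    """
    from .io import CountMatrix  # local import to avoid cycle

    gidx = ortho.gene_index(side)
    rows, cols = [], []
    present = set()
    n_dropped = 0
    for j, g in enumerate(m.gene_ids):
        if g in gidx:
            rows.append(gidx[g])
            cols.append(j)
            present.add(g)
        else:
            n_dropped += 1
    if not rows:
        raise DataError("no overlap between matrix and orthology")

    indicator = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(ortho.n, m.n_genes),
    )
    collapsed = sparse.csr_matrix(indicator @ m.counts)

    missing = sorted(
        g for genes in ortho.genes(side) for g in genes if g not in present
    )
    if missing:
        warnings.warn(
            f"{len(missing)} orthology genes absent from matrix contribute zero"
        )
    report = CollapseReport(
        n_metagenes=ortho.n,
        n_genes_assigned=len(rows),
        n_genes_dropped=n_dropped,
        missing_genes=missing,
    )
    out = CountMatrix(
        collapsed, ortho.metagene_ids(), list(m.cell_ids), m.species_tag
    )
    return out, report
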