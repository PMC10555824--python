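"""Synthetic paired-species atlas generator with known ground truth.

The generator emulates the statistical structure required to exercise a
cross-species cell-type homology comparison: two species sharing a set of
homologous cell-type families plus lineage-specific types, gene
duplications creating 1:1, 1:2 and 2:2 orthology relations, cell-type
specific expression programs of elevated-mean marker orthogroups, and
negative-binomial UMI counts with log-normal library-size variation.

Counts for gene g in a cell of type t are drawn as
NB(mean = L * mu_{t,g}, variance = mu + alpha * mu^2) with per-cell
library factor L ~ LogNormal(0, libsize_sigma); alpha = 0 reduces to
Poisson.  Each orthogroup's expected expression is split across its
paralogues by Dirichlet(1, ..., 1) weights fixed per orthogroup, so
meta-gene summation recovers the orthogroup total regardless of the
split.  Ten dedicated mitochondrial genes per species (ID prefix "MT-")
receive a configurable share of the expression mass so the mitochondrial
QC filter can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import sparse

from .errors import ValidationError
from .io import (
    CellAnnotation,
    CountMatrix,
    write_annotation,
    write_mtx_triplet,
    write_orthology,
)
from .orthomap import OrthoMap

MITO_PREFIX = "MT-"


@dataclass
class SimConfig:
    """Study conditions for the paired-species simulation."""

    n_orthogroups: int = 1500
    p_dup_s1: float = 0.15
    p_dup_s2: float = 0.15
    n_shared_families: int = 14
    n_private_s1: int = 2
    n_private_s2: int = 2
    cells_per_type: int = 200
    frac_marker_genes: float = 0.05
    fold_up: float = 8.0
    divergence: float = 0.2
    nb_dispersion: float = 0.5
    libsize_sigma: float = 0.5
    mito_frac_mean: float = 0.03
    baseline_mean: float = 0.2
    baseline_sigma: float = 0.5
    n_mito_genes: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("p_dup_s1", "p_dup_s2", "divergence", "frac_marker_genes",
                     "mito_frac_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_orthogroups", "n_shared_families", "cells_per_type"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_private_s1 < 0 or self.n_private_s2 < 0:
            raise ValidationError("private type counts must be >= 0")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        if self.libsize_sigma < 0 or self.baseline_sigma < 0:
            raise ValidationError("libsize_sigma and baseline_sigma must be >= 0")
        if self.baseline_mean <= 0 or self.fold_up <= 0:
            raise ValidationError("baseline_mean and fold_up must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def type_names(self, species: str) -> list[str]:
        fams = [f"F{i + 1:02d}" for i in range(self.n_shared_families)]
        n_priv = self.n_private_s1 if species == "s1" else self.n_private_s2
        priv = [f"{species}.P{i + 1:02d}" for i in range(n_priv)]
        return fams + priv


@dataclass
class SimTruth:
    """Ground truth of a simulated atlas pair."""

    config: SimConfig
    orthomap: OrthoMap
    true_pairs: list[tuple[str, str]]
    # (species, type) -> per-orthogroup expected mean (before library factor)
    program_table: dict[tuple[str, str], np.ndarray]
    marker_sets: dict[tuple[str, str], frozenset[int]]  # 0-based og indices
    split_weights: dict[str, list[np.ndarray]]
    mito_genes: dict[str, list[str]]
    cell_labels: dict[str, list[str]] = field(default_factory=dict)

    def marker_orthogroups(self, species: str) -> frozenset[int]:
        out: set[int] = set()
        for (sp, _), s in self.marker_sets.items():
            if sp == species:
                out |= s
        return frozenset(out)


def simulate_gene_forest(config: SimConfig, rng: np.random.Generator) -> OrthoMap:
    """Draw the two species' gene complements over shared orthogroups.

    Each orthogroup holds 1 + Bernoulli(p_dup) genes per species (a single
    possible duplication round), producing 1:1, 1:2, 2:1 and 2:2 cases.
    """
    genes_s1, genes_s2 = [], []
    dup1 = rng.random(config.n_orthogroups) < config.p_dup_s1
    dup2 = rng.random(config.n_orthogroups) < config.p_dup_s2
    for i in range(config.n_orthogroups):
        base1 = f"s1g{i + 1:05d}"
        base2 = f"s2g{i + 1:05d}"
        genes_s1.append((base1, base1 + "b") if dup1[i] else (base1,))
        genes_s2.append((base2, base2 + "b") if dup2[i] else (base2,))
    return OrthoMap(genes_s1=genes_s1, genes_s2=genes_s2, provenance="simulation")


def simulate_programs(
    config: SimConfig, ortho: OrthoMap, rng: np.random.Generator
) -> SimTruth:
    """Assign marker orthogroups and expected means to every cell type.

    Each orthogroup receives a baseline mean baseline_mean scaled by a
    log-normal(0, baseline_sigma) factor drawn once and shared by both
    species (orthologous genes keep conserved expression levels); a type's
    marker orthogroups are elevated fold_up-fold above that baseline.  The
    two types of a shared family keep a (1 - divergence) fraction of
    markers in common, the rest re-drawn independently per species;
    private types draw independent sets.
    """
    n_og = config.n_orthogroups
    n_markers = int(round(config.frac_marker_genes * n_og))
    if n_markers < 1:
        raise ValidationError("no program genes: frac_marker_genes * n_orthogroups < 1")

    def draw_set(exclude: frozenset[int] = frozenset(), size: int = n_markers):
        pool = np.array(sorted(set(range(n_og)) - exclude))
        return frozenset(rng.choice(pool, size=size, replace=False).tolist())

    marker_sets: dict[tuple[str, str], frozenset[int]] = {}
    true_pairs: list[tuple[str, str]] = []
    fams = [f"F{i + 1:02d}" for i in range(config.n_shared_families)]
    n_keep = int(round((1.0 - config.divergence) * n_markers))
    for fam in fams:
        s1_set = draw_set()
        kept = frozenset(
            rng.choice(np.array(sorted(s1_set)), size=n_keep, replace=False).tolist()
        )
        # re-drawn markers exclude only the kept ones, so divergence=1 gives
        # a fully independent draw (chance overlap at hypergeometric level)
        redraw = draw_set(exclude=kept, size=n_markers - n_keep)
        marker_sets[("s1", fam)] = s1_set
        marker_sets[("s2", fam)] = kept | redraw
        true_pairs.append((fam, fam))
    for sp, n_priv in (("s1", config.n_private_s1), ("s2", config.n_private_s2)):
        for p in range(n_priv):
            marker_sets[(sp, f"{sp}.P{p + 1:02d}")] = draw_set()

    baseline = config.baseline_mean * rng.lognormal(
        0.0, config.baseline_sigma, size=n_og
    )
    program_table: dict[tuple[str, str], np.ndarray] = {}
    for sp in ("s1", "s2"):
        for t in config.type_names(sp):
            mu = baseline.copy()
            mu[sorted(marker_sets[(sp, t)])] *= config.fold_up
            program_table[(sp, t)] = mu

    split_weights = {
        "s1": [rng.dirichlet(np.ones(len(g))) for g in ortho.genes_s1],
        "s2": [rng.dirichlet(np.ones(len(g))) for g in ortho.genes_s2],
    }
    mito_genes = {
        sp: [f"{MITO_PREFIX}{sp}-{i + 1:02d}" for i in range(config.n_mito_genes)]
        for sp in ("s1", "s2")
    }
    return SimTruth(
        config=config,
        orthomap=ortho,
        true_pairs=true_pairs,
        program_table=program_table,
        marker_sets=marker_sets,
        split_weights=split_weights,
        mito_genes=mito_genes,
    )


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB with variance mu + dispersion*mu^2, via the Gamma-Poisson mixture;
    dispersion 0 is exactly Poisson."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    config: SimConfig, truth: SimTruth, rng: np.random.Generator
) -> dict[str, tuple[CountMatrix, CellAnnotation]]:
    """Sample both species' UMI count matrices from the programs."""
    out = {}
    for sp in ("s1", "s2"):
        ortho_genes = truth.orthomap.genes(sp)
        gene_ids: list[str] = []
        gene_mu_weight: list[tuple[int, float]] = []  # (og index, split weight)
        for og_idx, genes in enumerate(ortho_genes):
            w = truth.split_weights[sp][og_idx]
            for g, wg in zip(genes, w):
                gene_ids.append(g)
                gene_mu_weight.append((og_idx, wg))
        gene_ids.extend(truth.mito_genes[sp])

        types = config.type_names(sp)
        n_cells = config.cells_per_type * len(types)
        og_index = np.array([i for i, _ in gene_mu_weight])
        weights = np.array([w for _, w in gene_mu_weight])
        n_real = len(og_index)
        n_mito = config.n_mito_genes

        counts = np.empty((len(gene_ids), n_cells), dtype=np.int64)
        labels: list[str] = []
        col = 0
        for t in types:
            mu_og = truth.program_table[(sp, t)]
            mu_genes = weights * mu_og[og_index]
            mito_total = (
                config.mito_frac_mean / (1.0 - config.mito_frac_mean) * mu_og.sum()
            )
            mu_full = np.concatenate(
                [mu_genes, np.full(n_mito, mito_total / n_mito)]
            )
            lib = rng.lognormal(0.0, config.libsize_sigma, size=config.cells_per_type)
            mean_block = mu_full[:, None] * lib[None, :]
            counts[:, col : col + config.cells_per_type] = _nb_sample(
                rng, mean_block, config.nb_dispersion
            )
            labels.extend([t] * config.cells_per_type)
            col += config.cells_per_type

        cell_ids = [f"{sp}_c{i + 1:05d}" for i in range(n_cells)]
        cm = CountMatrix(sparse.csr_matrix(counts), gene_ids, cell_ids, sp)
        ann = CellAnnotation.from_labels(cell_ids, labels, species=sp)
        truth.cell_labels[sp] = labels
        out[sp] = (cm, ann)
    return out


def simulate_atlas_pair(
    config: SimConfig,
) -> tuple[dict[str, tuple[CountMatrix, CellAnnotation]], SimTruth]:
    """Full simulation: gene forest, programs, counts. Deterministic in seed."""
    rng = np.random.default_rng(config.seed)
    ortho = simulate_gene_forest(config, rng)
    truth = simulate_programs(config, ortho, rng)
    data = simulate_counts(config, truth, rng)
    return data, truth


def write_atlas(
    data: dict[str, tuple[CountMatrix, CellAnnotation]],
    truth: SimTruth,
    out_dir: str | Path,
) -> Path:
    """Write the simulated pair as MTX triplets, annotation and truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, (cm, ann) in data.items():
        write_mtx_triplet(cm, out / sp)
        write_annotation(ann, out / f"annotation_{sp}.tsv")
        with open(out / f"mito_genes_{sp}.txt", "w") as fh:
            fh.write("\n".join(truth.mito_genes[sp]) + "\n")
    write_orthology(truth.orthomap, out / "orthogroups.tsv", ("s1", "s2"))
    with open(out / "true_pairs.tsv", "w") as fh:
        fh.write("s1_type\ts2_type\n")
        for a, b in truth.true_pairs:
            fh.write(f"{a}\t{b}\n")
    with open(out / "marker_sets.tsv", "w") as fh:
        fh.write("species\tcell_type\torthogroup_indices\n")
        for (sp, t), s in sorted(truth.marker_sets.items()):
            fh.write(f"{sp}\t{t}\t" + ",".join(str(i + 1) for i in sorted(s)) + "\n")
    return out
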