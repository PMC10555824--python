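"""End-to-end orchestration: simulate/load -> QC -> meta-gene collapse ->
normalize -> HVG -> specificity -> correlate/RBH -> bootstrap dendrogram.

Every run writes its artifacts plus a manifest recording parameters, seed
and SHA-256 hashes of all outputs, so a rerun with the same configuration
reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DataError, ValidationError
from .homology import (
    DEFAULT_SCALES,
    BootstrapSupport,
    bootstrap_support,
    build_dendrogram,
    correlate_celltypes,
    joint_profiles,
    reciprocal_best_hits,
)
from .io import (
    CellAnnotation,
    CountMatrix,
    read_annotation,
    read_count_matrix,
    read_orthology,
)
from .orthomap import OrthoMap, collapse_to_metagenes
from .preprocess import (
    SpecificityMatrix,
    cluster_means,
    normalize,
    select_hvgs,
    specificity_index,
)
from .qc import QCParams, qc_filter
from .simdata import MITO_PREFIX, SimConfig, SimTruth, simulate_atlas_pair


@dataclass
class SpeciesInputs:
    """File-system inputs for one species (unused in simulated runs)."""

    matrix: str = ""
    dialect: str = "mtx_triplet"
    annotation: str = ""
    mito_list: str = ""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: SimConfig | None = field(default_factory=SimConfig)
    species1: SpeciesInputs | None = None
    species2: SpeciesInputs | None = None
    orthology: str = ""
    qc1: QCParams = field(default_factory=QCParams)
    qc2: QCParams = field(default_factory=QCParams)
    hvg_k: int = 3000
    gene_set: str = ""  # optional file with one orthogroup index per line
    correlate_on: str = "specificity"  # or "means"
    n_boot: int = 1000
    scales: tuple[float, ...] = DEFAULT_SCALES
    seed: int = 1
    out_dir: str = "orthotype_run"

    def validate(self) -> None:
        if self.sim is None:
            for name, sp in (("species1", self.species1), ("species2", self.species2)):
                if sp is None or not sp.matrix or not sp.annotation:
                    raise ValidationError(f"{name}: matrix and annotation required")
                for p in (sp.matrix, sp.annotation):
                    if not Path(p).exists():
                        raise ValidationError(f"{name}: missing input {p}")
            if not self.orthology or not Path(self.orthology).exists():
                raise ValidationError(f"orthology table missing: {self.orthology!r}")
        if self.correlate_on not in ("specificity", "means"):
            raise ValidationError("correlate_on must be 'specificity' or 'means'")
        if self.hvg_k < 1 or self.n_boot < 1:
            raise ValidationError("hvg_k and n_boot must be >= 1")
        if self.gene_set and not Path(self.gene_set).exists():
            raise ValidationError(f"gene_set file missing: {self.gene_set}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig(**d["sim"])
        for k in ("species1", "species2"):
            if d.get(k) is not None:
                d[k] = SpeciesInputs(**d[k])
        for k in ("qc1", "qc2"):
            if d.get(k) is not None:
                qc = dict(d[k])
                qc["mito_gene_ids"] = frozenset(qc.get("mito_gene_ids", ()))
                d[k] = QCParams(**qc)
        if "scales" in d:
            d["scales"] = tuple(float(s) for s in d["scales"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        d = self.to_dict()
        for k in ("qc1", "qc2"):
            d[k]["mito_gene_ids"] = sorted(d[k]["mito_gene_ids"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    corr: pd.DataFrame
    rbh: pd.DataFrame
    support: BootstrapSupport
    spec1: SpecificityMatrix
    spec2: SpecificityMatrix
    truth: SimTruth | None
    manifest: dict
    out_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(msg: str, t0: float) -> None:
    print(f"[orthotype +{time.perf_counter() - t0:8.2f}s] {msg}", file=sys.stderr)


def _load_species(inputs: SpeciesInputs, tag: str) -> tuple[CountMatrix, CellAnnotation, frozenset[str]]:
    cm = read_count_matrix(inputs.matrix, inputs.dialect, species_tag=tag)
    ann = read_annotation(inputs.annotation)
    mito: frozenset[str] = frozenset()
    if inputs.mito_list:
        mito = frozenset(
            ln.strip() for ln in Path(inputs.mito_list).read_text().splitlines() if ln.strip()
        )
    return cm, ann, mito


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages in fixed order and write artifacts + manifest."""
    t0 = time.perf_counter()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth: SimTruth | None = None
    if config.sim is not None:
        _log("simulating atlas pair", t0)
        data, truth = simulate_atlas_pair(config.sim)
        (cm1, ann1), (cm2, ann2) = data["s1"], data["s2"]
        ortho = truth.orthomap
        mito1 = frozenset(truth.mito_genes["s1"])
        mito2 = frozenset(truth.mito_genes["s2"])
    else:
        _log("loading inputs", t0)
        cm1, ann1, mito1 = _load_species(config.species1, "s1")
        cm2, ann2, mito2 = _load_species(config.species2, "s2")
        ortho, _ = read_orthology(config.orthology)
        if not mito1:
            mito1 = frozenset(g for g in cm1.gene_ids if g.startswith(MITO_PREFIX))
        if not mito2:
            mito2 = frozenset(g for g in cm2.gene_ids if g.startswith(MITO_PREFIX))

    qc1 = QCParams(
        min_cells_per_gene=config.qc1.min_cells_per_gene,
        min_umis_per_cell=config.qc1.min_umis_per_cell,
        max_mito_frac=config.qc1.max_mito_frac,
        mito_gene_ids=config.qc1.mito_gene_ids or mito1,
    )
    qc2 = QCParams(
        min_cells_per_gene=config.qc2.min_cells_per_gene,
        min_umis_per_cell=config.qc2.min_umis_per_cell,
        max_mito_frac=config.qc2.max_mito_frac,
        mito_gene_ids=config.qc2.mito_gene_ids or mito2,
    )

    stage_reports = {}
    specs = []
    for tag, cm, ann, qc in (("s1", cm1, ann1, qc1), ("s2", cm2, ann2, qc2)):
        _log(f"{tag}: QC", t0)
        try:
            cm_f, qrep = qc_filter(cm, qc)
            ann_f = ann.subset(cm_f.cell_ids)
            _log(f"{tag}: collapsing to meta-genes", t0)
            meta, crep = collapse_to_metagenes(cm_f, ortho, tag)
            _log(f"{tag}: normalize + HVG + specificity", t0)
            nm = normalize(meta)
            hvg_idx = select_hvgs(nm, k=config.hvg_k)
            hvg_ids = frozenset(nm.gene_ids[i] for i in hvg_idx)
            means, sizes = cluster_means(nm, ann_f)
            means = means.loc[[g in hvg_ids for g in means.index]]
            spec = specificity_index(means, sizes, nm.normalization_tag)
            if config.correlate_on == "means":
                kept = means.index.difference(pd.Index(spec.masked_genes))
                spec = SpecificityMatrix(
                    values=means.loc[kept],
                    cluster_sizes=sizes.astype(int),
                    N=int(sizes.sum()),
                    normalization_tag=f"{nm.normalization_tag}|means",
                    masked_genes=list(spec.masked_genes),
                )
        except (DataError, ValidationError) as exc:
            raise DataError(f"stage failed for {tag}: {exc}") from exc
        stage_reports[tag] = {"qc": qrep.to_dict(), "collapse": crep.to_dict()}
        specs.append(spec)
    spec1, spec2 = specs

    gene_set = None
    if config.gene_set:
        gene_set = [
            ln.strip()
            for ln in Path(config.gene_set).read_text().splitlines()
            if ln.strip()
        ]

    _log("correlating cell types", t0)
    corr = correlate_celltypes(spec1, spec2, gene_set=gene_set)
    rbh = reciprocal_best_hits(corr)
    _log("building joint dendrogram + bootstrap", t0)
    profiles = joint_profiles(spec1, spec2, gene_set=gene_set)
    dendro = build_dendrogram(profiles)
    support = bootstrap_support(
        profiles,
        n_boot=config.n_boot,
        scales=config.scales,
        seed=config.seed,
        dendrogram=dendro,
    )

    # ---- write artifacts
    corr.to_csv(out / "correlation.tsv", sep="\t")
    rbh.to_csv(out / "rbh_pairs.tsv", sep="\t", index=False)
    support.table.to_csv(out / "support.tsv", sep="\t", index=False)
    (out / "dendrogram.nwk").write_text(support.newick() + "\n")
    report = {
        "stages": stage_reports,
        "n_shared_orthogroups": int(len(profiles.index)),
        "n_rbh_pairs": int(len(rbh)),
        "gene_set_tag": "restricted" if gene_set else "all-HVG",
        "correlate_on": config.correlate_on,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    artifacts = sorted(
        p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "orthotype_version": __version__,
        "config": _jsonable(config.to_dict()),
        "seed": config.seed,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _log("done", t0)
    return PipelineResult(
        corr=corr,
        rbh=rbh,
        support=support,
        spec1=spec1,
        spec2=spec2,
        truth=truth,
        manifest=manifest,
        out_dir=out,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def evaluate_against_truth(result: PipelineResult, truth: SimTruth | None = None) -> dict:
    """Score a simulated run against its ground truth.

    Reports RBH recovery (matched/total over true pairs), RBH precision,
    mean correlation of true pairs vs non-pairs, and per-true-pair clade
    support where the pair forms a clade of the joint dendrogram.
    """
    truth = truth or result.truth
    if truth is None:
        raise DataError("no simulation truth available for evaluation")
    corr = result.corr
    true_pairs = [
        (a, b)
        for a, b in truth.true_pairs
        if a in corr.index and b in corr.columns
    ]
    if not true_pairs:
        raise DataError("truth does not match the atlas cell types")

    rbh_set = {(r.s1_type, r.s2_type) for r in result.rbh.itertuples()}
    matched = sum(1 for p in true_pairs if p in rbh_set)
    true_r = [corr.loc[a, b] for a, b in true_pairs]
    non_r = [
        corr.loc[a, b]
        for a in corr.index
        for b in corr.columns
        if (a, b) not in set(true_pairs) and not np.isnan(corr.loc[a, b])
    ]
    support = {}
    for a, b in true_pairs:
        row = result.support.for_clade(frozenset({f"s1.{a}", f"s2.{b}"}))
        if row is not None:
            support[f"{a}~{b}"] = {"bp": float(row["bp"]), "au": float(row["au"])}
    private_pairs = [
        (r.s1_type, r.s2_type)
        for r in result.rbh.itertuples()
        if r.s1_type.startswith("s1.P") and r.s2_type.startswith("s2.P")
    ]
    return {
        "recovery": {
            "matched": int(matched),
            "total": int(len(true_pairs)),
            "rate": matched / len(true_pairs),
        },
        "precision": (
            sum(1 for p in rbh_set if p in set(true_pairs)) / len(rbh_set)
            if rbh_set
            else float("nan")
        ),
        "mean_true_pair_r": float(np.mean(true_r)),
        "mean_nonpair_r": float(np.mean(non_r)),
        "min_true_pair_r": float(np.min(true_r)),
        "private_private_rbh": private_pairs,
        "true_pair_clade_support": support,
    }
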