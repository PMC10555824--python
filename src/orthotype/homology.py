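"""Cross-species cell-type correlation, reciprocal-best-hit matching and
bootstrap-supported expression dendrograms.

Cell types of the two species are compared by the Pearson correlation of
their specificity-index vectors over the shared orthogroup meta-genes.
Matched pairs are reciprocal best hits (RBH) of the correlation matrix.
The joint dendrogram is built by complete-linkage agglomeration on the
correlation distance d = 1 - r, and clade support is assessed by
multiscale bootstrap resampling of the meta-genes: the bootstrap
proportion (BP) is the fraction of replicates whose tree contains the
clade exactly, and the approximately unbiased (AU) p-value is obtained by
fitting z_r = v*sqrt(r) + c/sqrt(r) to the probit-transformed BP across
resample-size scales r and evaluating 1 - Phi(v - c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DataError, ValidationError
from .preprocess import SpecificityMatrix

DEFAULT_SCALES = tuple(float(r) for r in np.round(np.arange(0.5, 1.45, 0.1), 1))


# ---------------------------------------------------------------------------
# correlation and matching


def correlate_celltypes(
    sp1: SpecificityMatrix,
    sp2: SpecificityMatrix,
    gene_set=None,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Pearson correlation between all cross-species cell-type pairs.

    Rows are species-1 types, columns species-2 types.  Only orthogroups
    unmasked in both species (optionally intersected with *gene_set*) are
    used.  A zero-variance specificity vector yields NaN entries, which are
    excluded from matching.
    """
    shared = sp1.values.index.intersection(sp2.values.index)
    if gene_set is not None:
        shared = shared.intersection(pd.Index([str(g) for g in gene_set]))
    if len(shared) < min_genes:
        raise DataError(
            f"only {len(shared)} shared orthogroups (need >= {min_genes})"
        )
    x1 = sp1.values.loc[shared].to_numpy(dtype=float)
    x2 = sp2.values.loc[shared].to_numpy(dtype=float)
    r = _pearson_columns(x1, x2)
    return pd.DataFrame(r, index=sp1.cell_types, columns=sp2.cell_types)


def _pearson_columns(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson r between two genes x types matrices."""
    c1 = x1 - x1.mean(axis=0)
    c2 = x2 - x2.mean(axis=0)
    n1 = np.sqrt((c1**2).sum(axis=0))
    n2 = np.sqrt((c2**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (c1.T @ c2) / np.outer(n1, n2)
    r[np.outer(n1 == 0, np.ones(len(n2), bool))] = np.nan
    r[np.outer(np.ones(len(n1), bool), n2 == 0)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r, where=~np.isnan(r))


def _argmax_lex(values: np.ndarray, labels) -> tuple[int | None, bool]:
    """Index of the maximum, ignoring NaN; exact ties broken by the
    lexicographically smallest label.  Returns (index, tie_flag)."""
    finite = ~np.isnan(values)
    if not finite.any():
        return None, False
    vmax = np.nanmax(values)
    cand = [i for i in np.flatnonzero(finite) if values[i] == vmax]
    if len(cand) == 1:
        return cand[0], False
    best = min(cand, key=lambda i: str(labels[i]))
    return best, True


def reciprocal_best_hits(corr: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal-best-hit pairs of the correlation matrix.

    (c1, c2) is a pair iff c2 is the argmax of row c1 AND c1 is the argmax
    of column c2.  The result is a partial matching; exact ties are broken
    lexicographically and flagged.
    """
    arr = corr.to_numpy(dtype=float)
    rows, cols = list(corr.index), list(corr.columns)
    col_best = {}
    for j in range(len(cols)):
        col_best[j] = _argmax_lex(arr[:, j], rows)
    out = []
    for i in range(len(rows)):
        j, tie_r = _argmax_lex(arr[i, :], cols)
        if j is None:
            continue
        i_back, tie_c = col_best[j]
        if i_back == i:
            out.append(
                {
                    "s1_type": rows[i],
                    "s2_type": cols[j],
                    "r": arr[i, j],
                    "tie": bool(tie_r or tie_c),
                }
            )
    return pd.DataFrame(out, columns=["s1_type", "s2_type", "r", "tie"])


def joint_profiles(
    sp1: SpecificityMatrix,
    sp2: SpecificityMatrix,
    gene_set=None,
    prefixes: tuple[str, str] = ("s1", "s2"),
) -> pd.DataFrame:
    """Concatenate both species' specificity profiles over shared
    orthogroups, cell-type columns prefixed by species."""
    shared = sp1.values.index.intersection(sp2.values.index)
    if gene_set is not None:
        shared = shared.intersection(pd.Index([str(g) for g in gene_set]))
    if len(shared) < 3:
        raise DataError(f"only {len(shared)} shared orthogroups for joint profiles")
    left = sp1.values.loc[shared].copy()
    left.columns = [f"{prefixes[0]}.{c}" for c in left.columns]
    right = sp2.values.loc[shared].copy()
    right.columns = [f"{prefixes[1]}.{c}" for c in right.columns]
    return pd.concat([left, right], axis=1)


# ---------------------------------------------------------------------------
# complete-linkage dendrogram


@dataclass
class Dendrogram:
    """Binary merge tree: leaves 0..n-1, internal node n+k for merge k."""

    labels: list[str]
    merges: list[tuple[int, int, float]]  # (left id, right id, height)

    def __post_init__(self) -> None:
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise DataError("dendrogram heights are not non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def clades(self) -> list[frozenset[str]]:
        """Leaf-label set of every internal node, in merge order."""
        sets: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        for k, (a, b, _) in enumerate(self.merges):
            s = sets[a] | sets[b]
            sets[self.n_leaves + k] = s
            out.append(s)
        return out

    def to_newick(self, support: dict[frozenset[str], str] | None = None) -> str:
        n = self.n_leaves
        sets: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        text: dict[int, str] = {i: _newick_escape(lab) for i, lab in enumerate(self.labels)}
        for k, (a, b, h) in enumerate(self.merges):
            node = n + k
            sets[node] = sets[a] | sets[b]
            height[node] = h
            la, lb = h - height[a], h - height[b]
            lab = ""
            if support is not None:
                lab = support.get(sets[node], "")
            text[node] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g}){lab}"
        return text[2 * n - 2] + ";"


def _newick_escape(label: str) -> str:
    if any(ch in label for ch in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def correlation_distance(x: np.ndarray, strict: bool = True, labels=None) -> np.ndarray:
    """Pairwise 1 - Pearson r between the columns of *x*.

    With ``strict`` a zero-variance column (NaN distance) is an error
    naming the offending pair; otherwise such distances are set to 1
    (r treated as 0), which is what bootstrap replicates use.
    """
    c = x - x.mean(axis=0)
    nrm = np.sqrt((c**2).sum(axis=0))
    zero = nrm == 0
    if strict and zero.any():
        lab = labels if labels is not None else list(range(x.shape[1]))
        bad = [str(lab[i]) for i in np.flatnonzero(zero)]
        raise DataError(f"zero-variance profiles give NaN distances: {bad}")
    nrm = np.where(zero, 1.0, nrm)
    r = (c.T @ c) / np.outer(nrm, nrm)
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    d = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def complete_linkage(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    """Deterministic complete-linkage agglomeration.

    At each step the pair of clusters at minimal maximum-distance is
    merged; exact ties are resolved by the lexicographically smallest pair
    of cluster label tuples, making the tree deterministic for any input.
    """
    n = len(labels)
    if n < 2:
        raise ValidationError("need at least 2 leaves")
    work = np.asarray(dist, dtype=float).copy()
    if work.shape != (n, n):
        raise DataError("distance matrix shape does not match labels")
    if np.isnan(work).any():
        i, j = np.argwhere(np.isnan(work))[0]
        raise DataError(f"NaN distance between {labels[i]!r} and {labels[j]!r}")
    np.fill_diagonal(work, np.inf)
    alive = np.ones(n, dtype=bool)
    keys: list[tuple[str, ...]] = [(lab,) for lab in labels]
    ids = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        sub = np.where(np.outer(alive, alive), work, np.inf)
        dmin = sub.min()
        cand = np.argwhere(sub == dmin)
        best = None
        for i, j in cand:
            if i >= j:
                continue
            ka, kb = sorted((keys[i], keys[j]))
            if best is None or (ka, kb) < best[0]:
                best = ((ka, kb), int(i), int(j))
        _, i, j = best
        merges.append((ids[i], ids[j], float(dmin)))
        newrow = np.maximum(work[i], work[j])
        work[i, :] = newrow
        work[:, i] = newrow
        work[i, i] = np.inf
        alive[j] = False
        keys[i] = tuple(sorted(keys[i] + keys[j]))
        ids[i] = next_id
        next_id += 1
    return Dendrogram(list(labels), merges)


def build_dendrogram(profiles: pd.DataFrame) -> Dendrogram:
    """Complete-linkage tree over cell types on correlation distance.

    *profiles* is genes x leaves; leaf order follows the columns.
    """
    labels = [str(c) for c in profiles.columns]
    d = correlation_distance(
        profiles.to_numpy(dtype=float), strict=True, labels=labels
    )
    return complete_linkage(d, labels)


# fast path used inside bootstrap replicates: first-index tie-break,
# returns only the merged leaf-index sets
def _linkage_clades(dist: np.ndarray) -> list[frozenset[int]]:
    n = dist.shape[0]
    work = dist.copy()
    np.fill_diagonal(work, np.inf)
    members: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    out = []
    for _ in range(n - 1):
        flat = np.argmin(work)
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        new = members[i] | members[j]
        out.append(new)
        newrow = np.maximum(work[i], work[j])
        work[i, :] = newrow
        work[:, i] = newrow
        work[i, i] = np.inf
        work[j, :] = np.inf
        work[:, j] = np.inf
        members[i] = new
    return out


# ---------------------------------------------------------------------------
# multiscale bootstrap


def fit_au(
    bp_values: np.ndarray, scales: tuple[float, ...], n_boot: int
) -> tuple[float, str]:
    """AU p-value (in %) from BP across resample-size scales.

    Fits z_r = v*sqrt(r) + c/sqrt(r) to z_r = Phi^{-1}(1 - BP(r)) by
    weighted least squares (delta-method inverse-variance weights for the
    probit of a binomial proportion) over scales with 0 < BP < 1, and
    returns AU = (1 - Phi(v - c)) * 100.  BP identically 0 or 1 at every
    scale clamps AU to 0 or 100 ("degenerate_bp"); fewer than two usable
    scales yields NaN ("au_unavailable").
    """
    bp_values = np.asarray(bp_values, dtype=float)
    r1 = tuple(scales).index(1.0)
    usable = (bp_values > 0) & (bp_values < 1)
    if not usable.any():
        return (100.0 if bp_values[r1] >= 0.5 else 0.0), "degenerate_bp"
    if usable.sum() < 2:
        return float("nan"), "au_unavailable"
    z = norm.ppf(1.0 - bp_values[usable])
    sr = np.sqrt(np.asarray(scales))[usable]
    design = np.column_stack([sr, 1.0 / sr])
    w = n_boot * norm.pdf(z) ** 2 / (bp_values[usable] * (1.0 - bp_values[usable]))
    wsq = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * wsq[:, None], z * wsq, rcond=None)
    v, c = coef
    return float(np.clip((1.0 - norm.cdf(v - c)) * 100.0, 0.0, 100.0)), ""


@dataclass
class BootstrapSupport:
    """Per-clade BP and AU support for a dendrogram."""

    dendrogram: Dendrogram
    table: pd.DataFrame  # clade, size, bp, au, flag + bp_<scale> columns
    n_boot: int
    scales: tuple[float, ...]
    seed: int
    _by_clade: dict[frozenset[str], int] = field(default_factory=dict)

    def for_clade(self, leaves: frozenset[str]) -> pd.Series | None:
        idx = self._by_clade.get(frozenset(leaves))
        return None if idx is None else self.table.loc[idx]

    def newick(self) -> str:
        ann = {}
        for _, row in self.table.iterrows():
            au = "NA" if row["au"] is None or (isinstance(row["au"], float) and math.isnan(row["au"])) else f"{row['au']:.0f}"
            ann[frozenset(row["clade"].split("|"))] = f"{au}/{row['bp']:.0f}"
        return self.dendrogram.to_newick(ann)


def bootstrap_support(
    profiles: pd.DataFrame,
    n_boot: int = 1000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
    dendrogram: Dendrogram | None = None,
) -> BootstrapSupport:
    """Multiscale bootstrap support for the complete-linkage dendrogram.

    For each scale r the meta-genes are resampled with replacement to size
    ceil(r*G), n_boot times; BP(node, r) is the fraction of replicate trees
    containing the node's exact leaf set.  The reported BP is BP at r = 1
    (in %); AU comes from a weighted least-squares fit of
    z_r = v*sqrt(r) + c/sqrt(r) to z_r = Phi^{-1}(1 - BP(r)) over scales
    with 0 < BP(r) < 1, as AU = (1 - Phi(v - c)) * 100.  Nodes whose BP is
    0 or 1 at every scale get AU clamped to 0 or 100 with a flag; nodes
    with fewer than two usable scales report BP only.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    scales = tuple(float(s) for s in scales)
    if 1.0 not in scales:
        raise ValidationError("scales must include 1.0 (BP is reported at r=1)")
    if dendrogram is None:
        dendrogram = build_dendrogram(profiles)
    labels = dendrogram.labels
    x = profiles.to_numpy(dtype=float)
    n_genes = x.shape[0]
    clade_labelsets = dendrogram.clades()
    label_pos = {lab: i for i, lab in enumerate(labels)}
    clade_indexsets = [
        frozenset(label_pos[lab] for lab in cl) for cl in clade_labelsets
    ]
    clade_lookup = {cl: k for k, cl in enumerate(clade_indexsets)}
    counts = np.zeros((len(scales), len(clade_indexsets)), dtype=np.int64)

    for si, r in enumerate(scales):
        m = max(2, int(np.ceil(r * n_genes)))
        for b in range(n_boot):
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), si, b))
            )
            idx = rng.integers(0, n_genes, size=m)
            d = correlation_distance(x[idx], strict=False)
            for cl in _linkage_clades(d):
                k = clade_lookup.get(cl)
                if k is not None:
                    counts[si, k] += 1

    bp = counts / n_boot
    r1 = scales.index(1.0)

    rows = []
    for k, cl in enumerate(clade_labelsets):
        bp_k = bp[:, k]
        au, flag = fit_au(bp_k, scales, n_boot)
        row = {
            "clade": "|".join(sorted(cl)),
            "size": len(cl),
            "bp": float(bp_k[r1] * 100.0),
            "au": au,
            "flag": flag,
        }
        for si, r in enumerate(scales):
            row[f"bp_{r:g}"] = float(bp_k[si])
        rows.append(row)

    table = pd.DataFrame(rows)
    by_clade = {cl: k for k, cl in enumerate(clade_labelsets)}
    return BootstrapSupport(
        dendrogram=dendrogram,
        table=table,
        n_boot=n_boot,
        scales=scales,
        seed=seed,
        _by_clade=by_clade,
    )
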