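"""One-vs-rest marker-gene detection.

Each gene is tested for differential expression between the cells of one
cluster and all remaining cells with a two-sided Wilcoxon rank-sum test
(normal approximation with tie correction).  Genes pass the marker filter
when logFC >= 0.25, at least one of the two groups expresses the gene in a
fraction >= 0.1 of cells (min.pct pre-filter), and the Bonferroni-adjusted
P value is below 0.01.  Genes failing the pre-filter are not tested and do
not enter the Bonferroni denominator (a flag restores the all-genes
denominator).

The log fold change follows the Seurat convention: natural log of the
ratio of de-normalized group means with a pseudocount of 1,
ln((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1)).  Base and
pseudocount are configurable and recorded in the result's attributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .errors import DataError, ValidationError
from .io import CellAnnotation
from .preprocess import NormalizedMatrix

DEFAULT_LOGFC_THRESHOLD = 0.25
DEFAULT_MIN_PCT = 0.1
DEFAULT_ALPHA = 0.01


def rank_markers(
    nm: NormalizedMatrix,
    ann: CellAnnotation,
    cluster: str,
    logfc_threshold: float = DEFAULT_LOGFC_THRESHOLD,
    min_pct: float = DEFAULT_MIN_PCT,
    alpha: float = DEFAULT_ALPHA,
    bonferroni: str = "tested",
    pseudocount: float = 1.0,
    log_base: float = np.e,
) -> pd.DataFrame:
    """Rank genes as markers of *cluster* against all other cells.

    Returns one row per pre-filter-passing gene with columns ``log_fc``,
    ``pct_in``, ``pct_out``, ``p_value``, ``p_adj`` and ``passed``, sorted
    by adjusted P then by decreasing logFC.
    """
    if bonferroni not in ("tested", "all"):
        raise ValidationError(f"bonferroni must be 'tested' or 'all', got {bonferroni!r}")
    labels = ann.labels_for(nm.cell_ids)
    in_mask = (labels == cluster).to_numpy()
    if not in_mask.any():
        raise DataError(f"unknown cluster label {cluster!r}")
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < 3 or n_out < 3:
        raise DataError(
            f"cluster {cluster!r} needs >= 3 cells on both sides "
            f"(has {n_in} vs {n_out})"
        )

    csr = sparse.csr_matrix(nm.values)
    x_in = np.asarray(csr[:, in_mask].todense())
    x_out = np.asarray(csr[:, ~in_mask].todense())

    pct_in = (x_in > 0).mean(axis=1)
    pct_out = (x_out > 0).mean(axis=1)
    tested = np.maximum(pct_in, pct_out) >= min_pct
    n_tested = int(tested.sum())
    if n_tested == 0:
        return _empty_table()

    # de-normalized means for the fold change
    mean_in = np.expm1(x_in[tested]).mean(axis=1)
    mean_out = np.expm1(x_out[tested]).mean(axis=1)
    log_fc = (
        np.log(mean_in + pseudocount) - np.log(mean_out + pseudocount)
    ) / np.log(log_base)

    res = stats.mannwhitneyu(
        x_in[tested],
        x_out[tested],
        axis=1,
        alternative="two-sided",
        method="asymptotic",
    )
    p_raw = np.asarray(res.pvalue)

    denom = n_tested if bonferroni == "tested" else nm.n_genes
    p_adj = np.minimum(p_raw * denom, 1.0)
    passed = (log_fc >= logfc_threshold) & (p_adj < alpha)

    genes = [g for g, t in zip(nm.gene_ids, tested) if t]
    table = pd.DataFrame(
        {
            "gene": genes,
            "log_fc": log_fc,
            "pct_in": pct_in[tested],
            "pct_out": pct_out[tested],
            "p_value": p_raw,
            "p_adj": p_adj,
            "passed": passed,
        }
    ).sort_values(["p_adj", "log_fc"], ascending=[True, False], kind="stable")
    table.attrs.update(
        {
            "cluster": cluster,
            "n_in": n_in,
            "n_out": n_out,
            "n_tested": n_tested,
            "bonferroni_denominator": denom,
            "logfc_threshold": logfc_threshold,
            "min_pct": min_pct,
            "alpha": alpha,
            "log_base": "e" if log_base == np.e else log_base,
            "pseudocount": pseudocount,
        }
    )
    return table.reset_index(drop=True)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene", "log_fc", "pct_in", "pct_out", "p_value", "p_adj", "passed"]
    )
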