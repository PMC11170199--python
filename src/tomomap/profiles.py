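"""Per-cluster expression profiles and rank-sum marker detection.

Normalization is counts-per-10k followed by log1p.  One-vs-rest fold
changes are computed on the de-logged (counts-per-10k) cluster means
with a small pseudocount; markers are two-sided Wilcoxon rank-sum
tests on the normalized log expression, Bonferroni-corrected over the
tested gene universe (all genes expressed in at least one cell of
either group), mirroring the default behavior of the standard
single-cell toolkits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from .qc import log_normalize_dense
from .ranksum import rank_sum_matrix

__all__ = ["ClusterProfiles", "pseudobulk_profile", "rank_markers",
           "top_markers", "EPSILON"]

#: pseudocount in the fold-change ratio of de-logged means
EPSILON = 1e-9


@dataclass
class ClusterProfiles:
    """Gene x cluster summaries of a labeled cell matrix.

    ``log2fc`` is the one-vs-rest log2 fold change of de-logged mean
    expression (NaN when there is a single cluster); ``pct_in`` /
    ``pct_out`` are the expressing-cell fractions inside / outside the
    cluster.
    """

    mean_log_expr: pd.DataFrame
    log2fc: pd.DataFrame
    pct_in: pd.DataFrame
    pct_out: pd.DataFrame

    @property
    def clusters(self) -> list[str]:
        return list(self.log2fc.columns)


def _dense_counts(adata: AnnData) -> np.ndarray:
    X = adata.X
    if sparse.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def _check_labels(adata: AnnData, labels) -> pd.Series:
    labels = pd.Series(labels, index=adata.obs_names if not isinstance(
        labels, pd.Series) else None)
    if isinstance(labels.index, pd.RangeIndex):
        labels.index = adata.obs_names
    labels = labels.reindex(adata.obs_names)
    if labels.isna().any():
        raise ValueError("every cell must carry a cluster label")
    return labels.astype(str)


def pseudobulk_profile(adata: AnnData, labels) -> ClusterProfiles:
    """Per-cluster mean log expression, one-vs-rest log2FC and pct stats.

    ``labels`` is a cluster assignment aligned with ``adata.obs_names``
    (Series, array or list).  Every cluster must have at least one
    cell.  With a single cluster the fold change is undefined and
    reported as NaN.
    """
    labels = _check_labels(adata, labels)
    clusters = sorted(labels.unique())
    counts = _dense_counts(adata)
    logn = log_normalize_dense(counts)
    cp10k = np.expm1(logn)  # de-logged normalized expression
    expressed = counts > 0

    genes = adata.var_names
    mean_log = pd.DataFrame(index=genes, columns=clusters, dtype=float)
    log2fc = pd.DataFrame(index=genes, columns=clusters, dtype=float)
    pct_in = pd.DataFrame(index=genes, columns=clusters, dtype=float)
    pct_out = pd.DataFrame(index=genes, columns=clusters, dtype=float)
    for c in clusters:
        mask = (labels == c).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"cluster {c!r} has no cells")
        mean_log[c] = logn[mask].mean(axis=0)
        pct_in[c] = expressed[mask].mean(axis=0)
        if mask.all():  # single-cluster input: no "rest"
            log2fc[c] = np.nan
            pct_out[c] = np.nan
        else:
            mean_in = cp10k[mask].mean(axis=0)
            mean_out = cp10k[~mask].mean(axis=0)
            log2fc[c] = np.log2((mean_in + EPSILON) / (mean_out + EPSILON))
            pct_out[c] = expressed[~mask].mean(axis=0)
    return ClusterProfiles(mean_log_expr=mean_log, log2fc=log2fc,
                           pct_in=pct_in, pct_out=pct_out)


def rank_markers(adata: AnnData, labels, cluster_id: str,
                 background: str = "rest",
                 correction: str = "bonferroni") -> pd.DataFrame:
    """Marker table for one cluster against a background.

    ``background='rest'`` uses all other cells (the default of the
    standard toolkits); a cluster ID restricts the comparison to that
    cluster (for within-lineage contrasts, e.g. among myocardial
    subclusters).  Genes expressed in no cell of either group are not
    tested.  Returns a DataFrame indexed by gene with columns log2fc,
    p_value, p_adjusted and rank (1 = strongest marker: smallest
    adjusted p, then largest \\|log2fc\\|).
    """
    labels = _check_labels(adata, labels)
    in_group = (labels == str(cluster_id)).to_numpy()
    if background == "rest":
        in_bg = ~in_group
    else:
        in_bg = (labels == str(background)).to_numpy()
    if in_group.sum() == 0 or in_bg.sum() == 0:
        raise ValueError("both comparison groups must be non-empty")

    counts = _dense_counts(adata)
    logn = log_normalize_dense(counts)
    used = in_group | in_bg
    tested = (counts[used] > 0).any(axis=0)
    genes = adata.var_names[tested]
    values = logn[:, tested][used].T  # genes x used-cells
    group_mask = in_group[used]

    pvals = rank_sum_matrix(values, group_mask)
    cp10k = np.expm1(logn[:, tested])
    mean_in = cp10k[in_group].mean(axis=0)
    mean_out = cp10k[in_bg].mean(axis=0)
    log2fc = np.log2((mean_in + EPSILON) / (mean_out + EPSILON))

    method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
    p_adj = multipletests(pvals, method=method)[1]
    table = pd.DataFrame({"log2fc": log2fc, "p_value": pvals,
                          "p_adjusted": p_adj}, index=genes)
    order = (table.assign(_negabs=-table["log2fc"].abs())
             .sort_values(["p_adjusted", "_negabs"], kind="stable").index)
    table["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order)
    return table.sort_values("rank")


def top_markers(table: pd.DataFrame, n: int = 100) -> list[str]:
    """The ``n`` highest-ranked significantly upregulated genes.

    Keeps genes with log2fc > 0 and adjusted p < 0.05; fewer than ``n``
    are returned if fewer qualify.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    sig = table[(table["log2fc"] > 0) & (table["p_adjusted"] < 0.05)]
    return list(sig.sort_values("rank").index[:n])
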