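"""Projection of cluster expression profiles onto a 1-D section reference.

The reference is a gene x section count table from serial sectioning
along the anterior→posterior axis (tomo-seq style, sections 1..S).
The pipeline, in order: drop weakly covered reference genes (maximum
read count below 20), LOESS-smooth each gene along sections
(span 0.15), convert smoothed values to per-section fold changes
against the gene's cross-section average, convert cluster log2 fold
changes to plain fold changes, match genes by ID dropping zeros, and
compute the Pearson correlation rho(x) between each cluster's
fold-change vector and each section's.  A cluster is placed at the
section where rho peaks; per-section compared-gene counts relative to
their average act as a quality proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loess import LoessConfig, loess_smooth_matrix

__all__ = [
    "CorrelationMap",
    "filter_reference_genes",
    "loess_smooth",
    "section_fold_changes",
    "cluster_fold_changes",
    "match_genes",
    "spatial_correlation",
    "quality_proxy",
    "assign_cluster_position",
    "subcluster_concordance",
    "map_clusters_to_sections",
    "plot_correlation_map",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMap:
    """Cluster x section correlation results.

    ``rho`` holds Pearson coefficients (NaN where fewer than
    ``min_matched`` gene pairs were available or a vector was
    constant); ``n_compared`` the pair counts.  Quality fields are
    filled by :func:`quality_proxy`, positions by
    :func:`assign_cluster_position`.
    """

    rho: pd.DataFrame
    n_compared: pd.DataFrame
    min_matched: int = 3
    avg_compared: float | None = None
    section_quality_ratio: pd.Series | None = None
    low_support: pd.Series | None = None
    assigned_section: pd.Series | None = None

    @property
    def sections(self) -> list:
        return list(self.rho.columns)

    @property
    def clusters(self) -> list:
        return list(self.rho.index)


def filter_reference_genes(ref: pd.DataFrame,
                           min_max_count: int = 20) -> pd.DataFrame:
    """Retain reference genes whose maximum section count is >= the cutoff.

    A gene peaking exactly at the cutoff is retained ("less than 20
    ... removed").
    """
    if ref.empty:
        raise ValueError("reference is empty")
    keep = ref.max(axis=1) >= min_max_count
    removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"all {len(ref)} reference genes fall below max count "
            f"{min_max_count}; review the threshold")
    logger.info("reference filter removed %d of %d genes", removed, len(ref))
    return ref.loc[keep]


def loess_smooth(ref: pd.DataFrame, cfg: LoessConfig | None = None) -> pd.DataFrame:
    """LOESS-smooth each gene's profile along sections (values >= 0)."""
    smoothed = loess_smooth_matrix(ref.to_numpy(dtype=float), cfg)
    return pd.DataFrame(smoothed, index=ref.index, columns=ref.columns)


def section_fold_changes(smoothed: pd.DataFrame) -> pd.DataFrame:
    """Per-section fold change of each gene against its section average.

    Genes with zero average yield all-zero rows, which the zero-drop
    matching rule later ignores.
    """
    vals = smoothed.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("smoothed values must be non-negative")
    means = vals.mean(axis=1, keepdims=True)
    fc = np.divide(vals, means, out=np.zeros_like(vals), where=means > 0)
    return pd.DataFrame(fc, index=smoothed.index, columns=smoothed.columns)


def cluster_fold_changes(log2fc: pd.DataFrame | pd.Series):
    """Convert per-cluster log2 fold changes to plain fold changes.

    Genes with missing log2FC are skipped (and logged).
    """
    missing = log2fc.isna()
    n_missing = int(np.asarray(missing).sum())
    if n_missing:
        logger.info("skipping %d gene entries with missing log2FC", n_missing)
    fc = np.power(2.0, log2fc)
    if isinstance(fc, pd.Series):
        return fc.dropna()
    return fc


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        return np.nan
    return float((xd @ yd) / denom)


def match_genes(cluster_fc: pd.Series, section_fc: pd.DataFrame,
                section_x) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair cluster and section fold changes at one section by gene ID.

    Genes outside the ID intersection, or with a zero value on either
    side, are ignored.  Returns (cluster values, section values,
    n_compared).
    """
    common = cluster_fc.index.intersection(section_fc.index)
    cv = cluster_fc.loc[common].to_numpy(dtype=float)
    sv = section_fc.loc[common, section_x].to_numpy(dtype=float)
    ok = (cv != 0) & (sv != 0) & ~np.isnan(cv) & ~np.isnan(sv)
    return cv[ok], sv[ok], int(ok.sum())


def spatial_correlation(cluster_fc: pd.DataFrame | pd.Series,
                        section_fc: pd.DataFrame,
                        min_matched: int = 3) -> CorrelationMap:
    """Pearson rho between every cluster and every section.

    ``cluster_fc``: gene x cluster fold changes (a Series is treated as
    one cluster); ``section_fc``: gene x section fold changes.  rho is
    NaN when fewer than ``min_matched`` gene pairs remain after the
    zero-drop rule or when either paired vector is constant.
    """
    if isinstance(cluster_fc, pd.Series):
        cluster_fc = cluster_fc.to_frame(cluster_fc.name or "cluster")
    sections = list(section_fc.columns)
    clusters = list(cluster_fc.columns)
    rho = pd.DataFrame(np.nan, index=clusters, columns=sections)
    ncmp = pd.DataFrame(0, index=clusters, columns=sections, dtype=int)
    common = cluster_fc.index.intersection(section_fc.index)
    cfc = cluster_fc.loc[common]
    sfc = section_fc.loc[common]
    for c in clusters:
        cv_all = cfc[c].to_numpy(dtype=float)
        for x in sections:
            sv_all = sfc[x].to_numpy(dtype=float)
            ok = (cv_all != 0) & (sv_all != 0) & ~np.isnan(cv_all) & ~np.isnan(sv_all)
            n = int(ok.sum())
            ncmp.loc[c, x] = n
            if n >= min_matched:
                rho.loc[c, x] = _pearson(cv_all[ok], sv_all[ok])
    return CorrelationMap(rho=rho, n_compared=ncmp, min_matched=min_matched)


def quality_proxy(cmap: CorrelationMap, low_ratio_flag: float = 0.5,
                  cluster_average_first: bool = True) -> CorrelationMap:
    """Per-section compared-gene ratios and low-support flags.

    The average compared-gene count is taken over clusters first, then
    sections (configurable); each section's ratio to that average flags
    sections with thin gene support (ratio below ``low_ratio_flag``).
    """
    per_section = cmap.n_compared.mean(axis=0)
    if cluster_average_first:
        avg = float(per_section.mean())
    else:
        avg = float(cmap.n_compared.to_numpy().mean())
    if avg == 0:
        logger.warning("no genes compared in any section; flagging all")
        ratio = per_section * np.nan
        flags = pd.Series(True, index=per_section.index)
    else:
        ratio = per_section / avg
        flags = ratio < low_ratio_flag
    cmap.avg_compared = avg
    cmap.section_quality_ratio = ratio
    cmap.low_support = flags
    return cmap


def assign_cluster_position(cmap: CorrelationMap) -> pd.Series:
    """Place each cluster at the section with maximal rho.

    Low-support sections (from :func:`quality_proxy`, if run) are
    excluded from the argmax; ties break toward the lowest section
    index; clusters with no defined rho are left unassigned (NA).
    """
    if cmap.low_support is not None:
        usable = [x for x in cmap.sections if not cmap.low_support[x]]
    else:
        usable = cmap.sections
    assigned = pd.Series(pd.NA, index=cmap.clusters, dtype="object")
    for c in cmap.clusters:
        row = cmap.rho.loc[c, usable]
        if row.notna().any():
            assigned[c] = row.idxmax()  # first (lowest section) on ties
    cmap.assigned_section = assigned
    return assigned


def subcluster_concordance(main_fc: pd.Series, sub_fc: pd.DataFrame,
                           main_rho: pd.Series, sub_rho: pd.DataFrame,
                           homogeneity_threshold: float = 0.6,
                           min_shared: int = 3) -> pd.DataFrame:
    """Gene- and space-level agreement of subclusters with their parent.

    ``gene_corr``: Pearson correlation of parent vs subcluster
    fold-change vectors over shared genes with non-zero values on both
    sides.  ``spatial_corr``: the same over sections where both rho
    vectors are defined.  A subcluster is flagged homogeneous when both
    correlations reach ``homogeneity_threshold``; with fewer than
    ``min_shared`` shared genes or sections the value is NaN and the
    flag False.
    """
    rows = []
    for sub in sub_fc.columns:
        common = main_fc.index.intersection(sub_fc.index)
        mv = main_fc.loc[common].to_numpy(dtype=float)
        sv = sub_fc.loc[common, sub].to_numpy(dtype=float)
        ok = (mv != 0) & (sv != 0) & ~np.isnan(mv) & ~np.isnan(sv)
        gene_corr = _pearson(mv[ok], sv[ok]) if ok.sum() >= min_shared else np.nan

        sec = main_rho.index.intersection(sub_rho.columns)
        mr = main_rho.loc[sec].to_numpy(dtype=float)
        sr = sub_rho.loc[sub, sec].to_numpy(dtype=float)
        both = ~np.isnan(mr) & ~np.isnan(sr)
        spatial_corr = (_pearson(mr[both], sr[both])
                        if both.sum() >= min_shared else np.nan)
        homogeneous = bool(
            not np.isnan(gene_corr) and not np.isnan(spatial_corr)
            and gene_corr >= homogeneity_threshold
            and spatial_corr >= homogeneity_threshold)
        rows.append({"subcluster": sub, "gene_corr": gene_corr,
                     "spatial_corr": spatial_corr, "homogeneous": homogeneous})
    return pd.DataFrame(rows).set_index("subcluster")


def map_clusters_to_sections(reference: pd.DataFrame,
                             cluster_log2fc: pd.DataFrame,
                             span: float = 0.15,
                             degree: int = 1,
                             min_max_count: int = 20,
                             min_matched: int = 3,
                             low_ratio_flag: float = 0.5) -> CorrelationMap:
    """Full mapping pipeline: filter → smooth → FC → match → rho → argmax.

    ``reference``: raw gene x section counts; ``cluster_log2fc``:
    gene x cluster log2 fold changes (one-vs-rest).  Returns a
    :class:`CorrelationMap` with correlations, quality proxies and
    positional assignments filled.
    """
    filtered = filter_reference_genes(reference, min_max_count)
    smoothed = loess_smooth(filtered, LoessConfig(span_alpha=span, degree=degree))
    sfc = section_fold_changes(smoothed)
    cfc = cluster_fold_changes(cluster_log2fc)
    cmap = spatial_correlation(cfc, sfc, min_matched=min_matched)
    quality_proxy(cmap, low_ratio_flag=low_ratio_flag)
    assign_cluster_position(cmap)
    return cmap


def plot_correlation_map(cmap: CorrelationMap, path=None, ax=None):
    """Heatmap of rho over clusters x sections (missing entries blank)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(
            figsize=(0.22 * len(cmap.sections) + 2,
                     0.35 * len(cmap.clusters) + 1.5))
    else:
        fig = ax.figure
    data = np.ma.masked_invalid(cmap.rho.to_numpy(dtype=float))
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(cmap.sections)),
                  [str(s) for s in cmap.sections], fontsize=6, rotation=90)
    ax.set_yticks(range(len(cmap.clusters)), cmap.clusters, fontsize=7)
    ax.set_xlabel("section (anterior → posterior)")
    fig.colorbar(im, ax=ax, label=r"Pearson $\rho$")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
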