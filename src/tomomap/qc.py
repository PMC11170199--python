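"""Per-cell quality control and doublet scoring.

The retention rule follows the study design for embryonic heart
droplets: 200 < genes per cell < 2500, mitochondrial read content
< 30% (high, because cardiomyocytes are mitochondria-rich), and
hemoglobin read content < 10% (erythrocyte contamination).  All
inequalities are strict, so boundary cells are removed.

Doublet scoring is an artificial-nearest-neighbor procedure: simulated
doublets (averages of random real-cell pairs) are co-embedded with the
real cells in PCA space of log-normalized counts, and each real cell is
scored by the proportion of artificial doublets among its k nearest
neighbors.  The top ``expected_rate`` fraction of real cells by score
is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "QCThresholds",
    "compute_cell_metrics",
    "apply_qc_filters",
    "score_doublets",
    "run_qc",
    "REMOVAL_REASONS",
]

REMOVAL_REASONS = ("low_genes", "high_genes", "mito", "hemoglobin",
                   "doublet", "none")


@dataclass(frozen=True)
class QCThresholds:
    """Strict (exclusive) retention bounds for per-cell metrics."""

    min_genes: int = 200
    max_genes: int = 2500
    max_mito_pct: float = 30.0
    max_hb_pct: float = 10.0

    def __post_init__(self):
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0 < self.max_mito_pct <= 100:
            raise ValueError("max_mito_pct must be in (0, 100]")
        if not 0 < self.max_hb_pct <= 100:
            raise ValueError("max_hb_pct must be in (0, 100]")


def _counts(adata: AnnData) -> sparse.csr_matrix:
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    return X.tocsr()


def compute_cell_metrics(adata: AnnData, mito_genes=None, hb_genes=None) -> pd.DataFrame:
    """Per-cell QC metrics: n_genes, n_umi, mito_pct, hb_pct.

    ``mito_genes`` / ``hb_genes`` are gene-ID collections; if omitted,
    mitochondrial genes default to the ``mt-`` name prefix and
    hemoglobin genes to the ``.var['is_hb']`` flag when present (else
    empty).  Cells with zero total counts get 0% for both fractions and
    are later removed by the gene-count rule.
    """
    genes = adata.var_names
    if mito_genes is None:
        mito_genes = {g for g in genes if g.lower().startswith("mt-")}
    if hb_genes is None:
        if "is_hb" in adata.var:
            hb_genes = set(genes[adata.var["is_hb"]])
        else:  # zebrafish hemoglobin gene families: hbae*, hbba*, hbbe*, hbz
            hb_genes = {g for g in genes
                        if g.lower().startswith(("hba", "hbb", "hbz"))}
    mito_genes, hb_genes = set(mito_genes), set(hb_genes)
    unknown = (mito_genes | hb_genes) - set(genes)
    if unknown:
        raise ValueError(f"gene sets contain IDs absent from the matrix: "
                         f"{sorted(unknown)[:5]}...")

    X = _counts(adata)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes_per_cell = X.getnnz(axis=1)
    mito_mask = np.asarray([g in mito_genes for g in genes])
    hb_mask = np.asarray([g in hb_genes for g in genes])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito = (np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
                if mito_mask.any() else np.zeros(adata.n_obs))
        hb = (np.asarray(X[:, hb_mask].sum(axis=1)).ravel()
              if hb_mask.any() else np.zeros(adata.n_obs))
        mito_pct = np.where(n_umi > 0, 100.0 * mito / np.maximum(n_umi, 1), 0.0)
        hb_pct = np.where(n_umi > 0, 100.0 * hb / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame({
        "n_genes": n_genes_per_cell.astype(int),
        "n_umi": n_umi.astype(int),
        "mito_pct": mito_pct,
        "hb_pct": hb_pct,
    }, index=adata.obs_names)


def apply_qc_filters(report: pd.DataFrame,
                     thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Fill retention decisions from computed metrics.

    A cell is retained iff min_genes < n_genes < max_genes and
    mito_pct < max_mito_pct and hb_pct < max_hb_pct (all strict).
    ``removal_reason`` records the first violated rule in the fixed
    order low_genes, high_genes, mito, hemoglobin.
    """
    thr = thresholds or QCThresholds()
    out = report.copy()
    reason = np.full(len(out), "none", dtype=object)
    checks = [
        ("low_genes", out["n_genes"].to_numpy() <= thr.min_genes),
        ("high_genes", out["n_genes"].to_numpy() >= thr.max_genes),
        ("mito", out["mito_pct"].to_numpy() >= thr.max_mito_pct),
        ("hemoglobin", out["hb_pct"].to_numpy() >= thr.max_hb_pct),
    ]
    for name, violated in reversed(checks):  # earlier rules overwrite later
        reason[violated] = name
    out["retained"] = reason == "none"
    out["removal_reason"] = pd.Categorical(reason, categories=REMOVAL_REASONS)
    return out


def log_normalize_dense(X: sparse.spmatrix | np.ndarray,
                        target_sum: float = 1e4) -> np.ndarray:
    """log1p counts-per-``target_sum`` as a dense array."""
    if sparse.issparse(X):
        X = np.asarray(X.todense(), dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals),
                      where=totals > 0)
    return np.log1p(X * scale)


def score_doublets(adata: AnnData, expected_rate: float,
                   k: int | None = None, artificial_fraction: float = 0.25,
                   n_components: int = 30, seed: int = 0):
    """Artificial-nearest-neighbor doublet scores and flags.

    Returns ``(scores, flagged)`` aligned with ``adata.obs_names``:
    score = proportion of artificial doublets among the cell's k
    nearest neighbors in the top ``n_components`` principal components
    of log-normalized counts; the ``expected_rate`` quantile of real
    cells with the highest scores is flagged.
    """
    if not 0 <= expected_rate < 0.5:
        raise ValueError("expected_rate must be in [0, 0.5)")
    if not 0 < artificial_fraction <= 1:
        raise ValueError("artificial_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    X = _counts(adata)
    n_real = adata.n_obs
    n_art = max(1, int(round(artificial_fraction * n_real)))
    i1 = rng.integers(0, n_real, size=n_art)
    i2 = rng.integers(0, n_real, size=n_art)
    art = (X[i1].toarray() + X[i2].toarray()) / 2.0
    combined = np.vstack([np.asarray(X.todense(), dtype=float), art])
    n_total = n_real + n_art
    if k is None:
        k = max(10, int(round(0.01 * n_total)))
    if k >= n_total:
        raise ValueError(f"k={k} must be smaller than the {n_total} "
                         "co-embedded cells")
    logn = log_normalize_dense(combined)
    n_comp = min(n_components, min(logn.shape) - 1)
    emb = PCA(n_components=n_comp, random_state=0).fit_transform(logn)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n_real])
    idx = idx[:, 1:]  # drop self
    scores = (idx >= n_real).mean(axis=1)
    n_flag = int(round(expected_rate * n_real))
    flagged = np.zeros(n_real, dtype=bool)
    if n_flag > 0:
        order = np.argsort(-scores, kind="stable")
        flagged[order[:n_flag]] = True
    return scores, flagged


def run_qc(adata: AnnData, thresholds: QCThresholds | None = None,
           mito_genes=None, hb_genes=None, expected_doublet_rate: float = 0.0,
           seed: int = 0, **doublet_kwargs) -> pd.DataFrame:
    """Full QC report: metrics, threshold decisions, doublet removal.

    Doublet scoring runs only on cells that pass the metric filters
    (scores of metric-failed cells are NaN).  Metric-passing cells
    flagged as doublets get ``removal_reason='doublet'``.
    """
    report = apply_qc_filters(compute_cell_metrics(adata, mito_genes, hb_genes),
                              thresholds)
    report["doublet_score"] = np.nan
    if expected_doublet_rate > 0:
        passing = report.index[report["retained"]]
        if len(passing) > 1:
            scores, flagged = score_doublets(
                adata[passing], expected_doublet_rate, seed=seed,
                **doublet_kwargs)
            report.loc[passing, "doublet_score"] = scores
            doublet_cells = passing[flagged]
            report.loc[doublet_cells, "retained"] = False
            report.loc[doublet_cells, "removal_reason"] = "doublet"
    return report
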