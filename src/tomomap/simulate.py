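"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's inputs:

* a serial-section spatial reference (tomo-seq style): genes with
  Gaussian-bump expression along an anterior→posterior section axis,
  plus flat "housekeeping" genes and low-expressed genes that exercise
  the reference filter, with negative-binomial count noise;
* a droplet-style cell count matrix: discrete cell clusters whose
  expression programs are read off the section truth at a cluster
  anchor section, heterotypic doublets formed by summing two cells
  from different clusters, and injected mitochondrial / hemoglobin
  reads spanning the QC thresholds;
* two-group heart-rate tables with a stated bpm shift.

All randomness flows from ``SimulationConfig.seed`` through spawned
NumPy generators, so identical configs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats

__all__ = [
    "SectionTruth",
    "CellTruth",
    "SimulationConfig",
    "generate_section_reference",
    "generate_cell_matrix",
    "generate_heart_rate_table",
    "mean_profile",
    "nb_counts",
]

#: default mitochondrial gene names (``mt-`` prefix rule)
DEFAULT_MITO_GENES = (
    "mt-nd1", "mt-nd2", "mt-nd4", "mt-nd5", "mt-co1",
    "mt-co2", "mt-co3", "mt-atp6", "mt-cyb", "mt-nd6",
)
#: default hemoglobin gene names
DEFAULT_HB_GENES = ("hbae1.1", "hbae3", "hbae5", "hbba1", "hbbe1.1", "hbbe2")


@dataclass(frozen=True)
class SectionTruth:
    """Ground-truth spatial profile of one reference gene.

    The expected count at section x is
    ``baseline + amplitude * exp(-(x - anchor)^2 / (2 * width^2))``.
    Flat genes (housekeeping / low-expressed) carry amplitude 0 and are
    tagged by ``kind``; anchored genes must have a positive bump.
    """

    gene_id: str
    anchor_section: int
    bump_width: float
    amplitude: float
    baseline: float
    kind: str = "anchored"  # anchored | housekeeping | low

    def __post_init__(self):
        if self.kind == "anchored" and self.amplitude <= 0:
            raise ValueError("anchored genes need amplitude > 0")
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("amplitude and baseline must be non-negative")
        if self.bump_width <= 0:
            raise ValueError("bump_width must be positive")


@dataclass(frozen=True)
class CellTruth:
    """Ground-truth identity of one simulated droplet."""

    cell_id: str
    cluster_label: str | None
    is_doublet: bool
    stage: str
    replicate: str
    source_clusters: tuple[str, str] | None = None
    source_cells: tuple[str, str] | None = None

    def __post_init__(self):
        if self.is_doublet:
            if self.source_clusters is None or len(set(self.source_clusters)) != 2:
                raise ValueError("doublets must record two distinct source clusters")
        elif self.cluster_label is None:
            raise ValueError("singlets must carry exactly one cluster label")


@dataclass(frozen=True)
class SimulationConfig:
    """Sizes, rates and noise of one simulation run.

    ``count_noise`` is the negative-binomial dispersion theta
    (variance = mean + mean^2 / theta); ``numpy.inf`` gives the
    noise-free limit (counts = rounded means).  ``mito_fraction_range``
    and ``hb_fraction_range`` are the per-cell read-fraction intervals
    of ordinary cells; ``mito_violation_fraction`` / ``hb_violation_fraction``
    of cells are instead pushed just above the corresponding QC
    threshold (30% mito, 10% hemoglobin).
    """

    n_genes: int = 1500
    n_sections: int = 40
    n_cells: int = 2000
    n_clusters: int = 10
    doublet_rate: float = 0.0
    count_noise: float = 5.0
    housekeeping_fraction: float = 0.2
    low_expression_fraction: float = 0.1
    mito_fraction_range: tuple[float, float] = (0.0, 0.25)
    hb_fraction_range: tuple[float, float] = (0.0, 0.08)
    mito_violation_fraction: float = 0.05
    hb_violation_fraction: float = 0.03
    mito_threshold: float = 0.30
    hb_threshold: float = 0.10
    mean_library_size: float = 5000.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_sections", "n_cells", "n_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must be in [0, 1)")
        if not self.count_noise > 0:
            raise ValueError("count_noise (NB dispersion) must be positive")
        for name in ("housekeeping_fraction", "low_expression_fraction",
                     "mito_violation_fraction", "hb_violation_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for rng_name, thr in (("mito_fraction_range", self.mito_threshold),
                              ("hb_fraction_range", self.hb_threshold)):
            lo, hi = getattr(self, rng_name)
            if not (0 <= lo <= hi < thr):
                raise ValueError(
                    f"{rng_name} must satisfy 0 <= lo <= hi < {thr}")
        if self.mean_library_size <= 0:
            raise ValueError("mean_library_size must be positive")


def nb_counts(rng: np.random.Generator, mean: np.ndarray,
              dispersion: float) -> np.ndarray:
    """Negative-binomial counts with the given mean and dispersion theta.

    ``dispersion=inf`` is the noise-free limit: rounded means.
    """
    mean = np.asarray(mean, dtype=float)
    if np.isinf(dispersion):
        return np.rint(mean).astype(np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(np.int64)


def mean_profile(truth: SectionTruth, n_sections: int) -> np.ndarray:
    """Expected counts of a gene across sections 1..S."""
    x = np.arange(1, n_sections + 1, dtype=float)
    bump = np.exp(-((x - truth.anchor_section) ** 2)
                  / (2.0 * truth.bump_width**2))
    return truth.baseline + truth.amplitude * bump


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_section_reference(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[SectionTruth]]:
    """Simulate a gene x section count reference.

    Returns a DataFrame (index gene_id, integer columns 1..S,
    anterior→posterior) and the per-gene ground truth.  A
    ``housekeeping_fraction`` of genes are flat; a
    ``low_expression_fraction`` have expected maxima well below the
    reference filter's default cutoff of 20 reads.
    """
    rng = _spawn(config.seed, 3)[0]
    S, G = config.n_sections, config.n_genes
    n_low = int(round(config.low_expression_fraction * G))
    n_hk = int(round(config.housekeeping_fraction * G))
    n_anchored = G - n_low - n_hk
    if n_anchored < 0:
        raise ValueError("housekeeping + low fractions exceed 1")

    truths: list[SectionTruth] = []
    for i in range(G):
        gene_id = f"g{i:05d}"
        if i < n_anchored:
            truths.append(SectionTruth(
                gene_id=gene_id,
                anchor_section=int(rng.integers(1, S + 1)),
                bump_width=float(rng.uniform(1.5, 3.5)),
                amplitude=float(rng.uniform(50, 400)),
                baseline=float(rng.uniform(1, 10)),
            ))
        elif i < n_anchored + n_hk:
            truths.append(SectionTruth(
                gene_id=gene_id, anchor_section=1, bump_width=1.0,
                amplitude=0.0, baseline=float(rng.uniform(30, 300)),
                kind="housekeeping",
            ))
        else:
            truths.append(SectionTruth(
                gene_id=gene_id, anchor_section=1, bump_width=1.0,
                amplitude=0.0, baseline=float(rng.uniform(0.3, 2.0)),
                kind="low",
            ))

    means = np.vstack([mean_profile(t, S) for t in truths])
    counts = nb_counts(rng, means, config.count_noise)
    ref = pd.DataFrame(counts, index=[t.gene_id for t in truths],
                       columns=np.arange(1, S + 1))
    ref.index.name = "gene_id"
    return ref, truths


def cluster_anchor_sections(config: SimulationConfig) -> dict[str, int]:
    """Evenly spaced interior anchor sections, one per cluster."""
    S, C = config.n_sections, config.n_clusters
    lo, hi = max(2, round(0.08 * S)), min(S - 1, round(0.92 * S))
    anchors = np.rint(np.linspace(lo, hi, C)).astype(int)
    return {f"cluster{c:02d}": int(a) for c, a in enumerate(anchors)}


def _inject_fractions(rng, n_cells, violation_fraction, fraction_range, threshold):
    """Per-cell target read fractions; a Bernoulli(violation_fraction)
    subset is pushed just above the threshold."""
    violate = rng.random(n_cells) < violation_fraction
    frac = rng.uniform(*fraction_range, size=n_cells)
    hi = min(threshold + 0.15, 0.6)
    frac[violate] = rng.uniform(threshold + 0.005, hi, size=int(violate.sum()))
    return frac, violate


def generate_cell_matrix(
    config: SimulationConfig, truth: Sequence[SectionTruth],
) -> tuple[AnnData, list[CellTruth]]:
    """Simulate a droplet count matrix with clusters anchored in space.

    Each cluster's expected expression program is the section-truth mean
    profile evaluated at the cluster's anchor section, so genes bumping
    near that section are the cluster's planted markers.  Heterotypic
    doublets (``config.doublet_rate`` of all droplets) are exact sums of
    two singlet columns from distinct clusters.  Mitochondrial and
    hemoglobin reads are injected per cell at fractions spanning the QC
    thresholds.

    Returns an AnnData (cells x genes, raw counts; truth columns in
    ``.obs``; ``is_mito`` / ``is_hb`` flags in ``.var``) plus the cell
    truth records.
    """
    rng = _spawn(config.seed, 3)[1]
    S = config.n_sections
    anchors = cluster_anchor_sections(config)
    cluster_ids = list(anchors)
    gene_ids = [t.gene_id for t in truth]
    G = len(gene_ids)

    # expected relative expression of each gene in each cluster
    rel = np.empty((G, len(cluster_ids)))
    for j, cid in enumerate(cluster_ids):
        x = anchors[cid]
        for i, t in enumerate(truth):
            rel[i, j] = (t.baseline + t.amplitude
                         * np.exp(-((x - t.anchor_section) ** 2)
                                  / (2.0 * t.bump_width**2)))
    probs = rel / rel.sum(axis=0, keepdims=True)

    n_doublets = int(round(config.doublet_rate * config.n_cells))
    n_singlets = config.n_cells - n_doublets
    if n_doublets > 0 and config.n_clusters < 2:
        raise ValueError("heterotypic doublets need at least 2 clusters")
    if n_doublets > 0 and n_singlets < 2:
        raise ValueError("too few singlets to source doublets")

    labels = rng.integers(0, len(cluster_ids), size=n_singlets)
    libs = rng.lognormal(mean=np.log(config.mean_library_size), sigma=0.35,
                         size=n_singlets)
    counts = np.zeros((n_singlets, G), dtype=np.int64)
    for j in range(len(cluster_ids)):
        mask = labels == j
        if not mask.any():
            continue
        lam = np.outer(libs[mask], probs[:, j])
        counts[mask] = nb_counts(rng, lam, config.count_noise)

    # inject mitochondrial and hemoglobin reads
    mito_genes, hb_genes = list(DEFAULT_MITO_GENES), list(DEFAULT_HB_GENES)
    f_m, _ = _inject_fractions(rng, n_singlets, config.mito_violation_fraction,
                               config.mito_fraction_range, config.mito_threshold)
    f_h, _ = _inject_fractions(rng, n_singlets, config.hb_violation_fraction,
                               config.hb_fraction_range, config.hb_threshold)
    totals = counts.sum(axis=1).astype(float)
    denom = np.maximum(1.0 - f_m - f_h, 1e-6)
    m_tot = np.rint(f_m / denom * totals).astype(np.int64)
    h_tot = np.rint(f_h / denom * totals).astype(np.int64)
    mito_p = rng.dirichlet(np.ones(len(mito_genes)))
    hb_p = rng.dirichlet(np.ones(len(hb_genes)))
    mito_counts = np.vstack([rng.multinomial(m, mito_p) for m in m_tot])
    hb_counts = np.vstack([rng.multinomial(h, hb_p) for h in h_tot])
    counts = np.hstack([counts, mito_counts, hb_counts])
    all_genes = gene_ids + mito_genes + hb_genes

    stages = rng.choice(["48hpf", "72hpf"], size=config.n_cells)
    reps = rng.choice(["rep1", "rep2"], size=config.n_cells)
    cell_ids = [f"cell{i:05d}" for i in range(config.n_cells)]

    truths: list[CellTruth] = []
    for i in range(n_singlets):
        truths.append(CellTruth(
            cell_id=cell_ids[i], cluster_label=cluster_ids[labels[i]],
            is_doublet=False, stage=str(stages[i]), replicate=str(reps[i]),
        ))

    doublet_rows = []
    for d in range(n_doublets):
        c1, c2 = rng.choice(len(cluster_ids), size=2, replace=False)
        pool1 = np.flatnonzero(labels == c1)
        pool2 = np.flatnonzero(labels == c2)
        if pool1.size == 0 or pool2.size == 0:  # rare tiny-sim corner
            pool1, pool2 = np.arange(n_singlets), np.arange(n_singlets)
        i1 = int(rng.choice(pool1))
        i2 = int(rng.choice(pool2))
        doublet_rows.append(counts[i1] + counts[i2])
        idx = n_singlets + d
        truths.append(CellTruth(
            cell_id=cell_ids[idx], cluster_label=None, is_doublet=True,
            stage=str(stages[idx]), replicate=str(reps[idx]),
            source_clusters=(cluster_ids[labels[i1]], cluster_ids[labels[i2]]),
            source_cells=(cell_ids[i1], cell_ids[i2]),
        ))
    if doublet_rows:
        counts = np.vstack([counts, np.asarray(doublet_rows)])

    obs = pd.DataFrame({
        "cluster": [t.cluster_label if t.cluster_label else "doublet"
                    for t in truths],
        "is_doublet": [t.is_doublet for t in truths],
        "stage": [t.stage for t in truths],
        "replicate": [t.replicate for t in truths],
    }, index=cell_ids)
    var = pd.DataFrame({
        "is_mito": [g in mito_genes for g in all_genes],
        "is_hb": [g in hb_genes for g in all_genes],
    }, index=all_genes)
    adata = AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)
    adata.uns["cluster_anchor_sections"] = {k: int(v) for k, v in anchors.items()}
    return adata, truths


def generate_heart_rate_table(
    n_per_group: int,
    control_mean: float = 146.0,
    shift: float = -28.0,
    sd: float = 10.0,
    seed: int = 0,
    skew: float = 0.0,
    group_names: tuple[str, str] = ("control", "knockout"),
    stage: str = "48hpf",
) -> pd.DataFrame:
    """Two-group per-embryo heart-rate table (columns group, bpm, stage).

    The test group is the control distribution shifted by ``shift`` bpm.
    ``skew`` != 0 draws from a skew-normal with the same mean and scale,
    emulating the non-normal rate distributions that route the analysis
    down the nonparametric path.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    if skew == 0.0:
        draw = lambda loc: rng.normal(loc, sd, size=n_per_group)
    else:
        delta = skew / np.sqrt(1 + skew**2)
        offset = sd * delta * np.sqrt(2 / np.pi)  # keep the stated mean

        def draw(loc):
            return stats.skewnorm.rvs(skew, loc=loc - offset, scale=sd,
                                      size=n_per_group, random_state=rng)

    bpm = np.concatenate([draw(control_mean), draw(control_mean + shift)])
    bpm = np.maximum(bpm, 1.0)  # rates are positive
    group = np.repeat(group_names, n_per_group)
    return pd.DataFrame({"group": group, "bpm": bpm, "stage": stage})
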