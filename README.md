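# tomomap

Spatially anchoring single-cell clusters of the embryonic zebrafish
heart — and testing every step of that analysis on synthetic data with
known ground truth.

Single-cell RNA-seq of the developing heart (48–72 hpf) resolves
myocardial, endocardial, epicardial, neural and blood lineages as
expression clusters, but droplets carry no positional information.
A serial-section RNA-seq reference (tomo-seq) of the same organ gives,
for every gene, a 1-D expression profile along the anterior→posterior
axis of the heart tube. `tomomap` implements the computational chain
that connects the two, plus the surrounding statistics:

1. **Cell QC** — per-cell gene counts, UMI totals, mitochondrial and
   hemoglobin read fractions; the strict retention rule
   `200 < n_genes < 2500 & mito% < 30 & hb% < 10` (a permissive
   mitochondrial cutoff, because cardiomyocytes are
   mitochondria-rich); and an artificial-nearest-neighbor doublet
   score: simulated doublets (averaged random cell pairs) are
   co-embedded in PCA space and each cell is scored by the artificial
   fraction among its k nearest neighbors.
2. **Cluster profiles and markers** — counts-per-10k/log1p
   normalization, per-cluster pseudobulk profiles with one-vs-rest
   log₂ fold changes, and marker detection by two-sided Wilcoxon
   rank-sum tests with Bonferroni correction (exact permutation
   distribution for small groups, tie-corrected normal approximation
   otherwise), with top-100 upregulated marker extraction.
3. **Spatial mapping** (the core) — reference genes with a maximum
   read count below 20 are removed; each gene's section profile is
   LOESS-smoothed (tricube local linear fits, span α = 0.15) and
   converted to fold changes against the gene's cross-section average;
   cluster log₂FC values are converted to plain fold changes; genes
   are matched by ID with zero values dropped; and the Pearson
   correlation ρ(x) between each cluster and each section x is
   computed over the matched fold changes. Clusters are placed at
   argmax ρ(x); per-section compared-gene counts relative to their
   average flag thinly supported sections; main-vs-subcluster
   concordance (gene- and space-level correlations) flags
   heterogeneous clusters.
4. **Heart-rate statistics** — for CRISPR knockout phenotyping:
   Shapiro–Wilk normality gate, two-sided Wilcoxon rank-sum comparison
   of knockout vs each control arm, Holm–Bonferroni family-wise
   correction.

A first-class synthetic-data module generates all three inputs with
ground truth (Gaussian-bump section profiles with negative-binomial
noise, anchored cell clusters with heterotypic doublets and injected
mito/hb reads, shifted heart-rate cohorts), so recovery of anchors,
doublets, markers and rate shifts is testable end to end without any
download.

## Worked example

```python
import pandas as pd
from tomomap import (SimulationConfig, generate_section_reference,
                     generate_cell_matrix, generate_heart_rate_table,
                     pseudobulk_profile, map_clusters_to_sections,
                     heart_rate_comparisons)

cfg = SimulationConfig(n_genes=800, n_sections=40, n_cells=1000,
                       n_clusters=8, count_noise=5.0, seed=4)
ref, section_truth = generate_section_reference(cfg)
adata, cell_truth = generate_cell_matrix(cfg, section_truth)

profiles = pseudobulk_profile(adata, adata.obs["cluster"])
cmap = map_clusters_to_sections(ref, profiles.log2fc, span=0.15)

truth = adata.uns["cluster_anchor_sections"]
print(pd.DataFrame({"assigned": cmap.assigned_section,
                    "true_anchor": pd.Series(truth)}))
print(f"average compared genes per section: {cmap.avg_compared:.0f}")

rates = generate_heart_rate_table(60, control_mean=146, shift=-28,
                                  sd=10, seed=4)
print(heart_rate_comparisons(rates)[["comparison", "median_diff",
                                     "p_value", "p_holm"]])
```

prints

```
          assigned  true_anchor
cluster00        2            3
cluster01        8            8
cluster02       13           13
cluster03       18           18
cluster04       22           22
cluster05       27           27
cluster06       32           32
cluster07       38           37
average compared genes per section: 719
            comparison  median_diff       p_value        p_holm
0  knockout_vs_control   -26.533658  2.393871e-19  2.393871e-19
```

Every cluster is placed within one section of its true anchor; the
cluster×section matrix `cmap.rho` is the correlation map one would
draw as a heatmap, and `cmap.n_compared` / `cmap.low_support` carry the
per-section gene-support quality proxy. The heart-rate cohort was
simulated with a −28 bpm shift; the rank-sum test recovers a −26.5 bpm
median difference at a decisive Holm-adjusted p.

The same flow is available from the shell:

```sh
tomomap simulate --outdir sim
tomomap qc --counts sim/counts --hb sim/hb_genes.txt --out qc.tsv
tomomap profile --counts sim/counts --labels sim/labels.tsv --outdir prof
tomomap map --reference sim/reference.tsv --profiles prof/log2fc.tsv --outdir map
tomomap stats --table sim/heart_rates.tsv --out stats.tsv
```

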