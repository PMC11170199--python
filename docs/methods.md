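# Methods

## Scope and data model

`tomomap` covers the desk-side computations of a developing-heart
single-cell atlas analysis: quality control of a droplet count matrix,
cluster profile and marker construction, projection of clusters onto a
1-D serial-section spatial reference, and knockout heart-rate
statistics. Upstream steps (read mapping, normalization-model fitting,
graph clustering, embedding) and downstream annotation (ontology
enrichment, ligand–receptor maps) are out of scope; cluster labels are
inputs.

Cells live in an `AnnData` (cells × genes, raw integer counts);
the spatial reference is a pandas DataFrame (genes × sections, integer
section IDs 1..S ordered anterior→posterior); profiles, correlation
maps and statistics are DataFrames keyed by gene or cluster ID.

## Cell QC

Metrics per cell: `n_genes` (genes with count > 0), `n_umi` (total
counts), `mito_pct` and `hb_pct` (percent of counts on mitochondrial /
hemoglobin genes; 0 for cells with no counts, which the gene-count
rule removes anyway). Retention requires, with *strict* inequalities,

```
200 < n_genes < 2500,  mito_pct < 30,  hb_pct < 10
```

so boundary cells (exactly 200 genes, exactly 30% mito, exactly 10%
hb) are removed. The mitochondrial cutoff is deliberately permissive:
cardiomyocytes are energetically demanding and legitimately
mitochondria-rich, so the usual 5–10% cutoffs would discard the cell
type of interest. The hemoglobin rule removes erythrocyte-contaminated
droplets. `removal_reason` records the first violated rule in the
fixed order low_genes, high_genes, mito, hemoglobin; the retention
decision itself is a conjunction and order-independent. Mitochondrial
genes default to the `mt-` name prefix and hemoglobin genes to the
zebrafish `hba*`/`hbb*`/`hbz*` families; both sets can be supplied
explicitly instead.

### Doublet scoring

A simplified artificial-nearest-neighbor scheme. Artificial doublets
(default 0.25 × n cells) are averages of uniformly sampled real-cell
pairs; real and artificial cells are jointly normalized
(counts-per-10k, log1p) and embedded in the top 30 principal
components; each real cell's score is the proportion of artificial
doublets among its k nearest neighbors (k = round(0.01 × co-embedded
cells), floor 10); the top `expected_rate` fraction of real cells by
score is flagged. Defaults are explicit and testable rather than swept.
The scorer targets *heterotypic* doublets — chimeras of
transcriptionally distinct cells that sit between clusters in PCA
space; homotypic doublets are indistinguishable by construction and
not claimed. Scoring runs after the metric filters, on passing cells
only.

## Cluster profiles and markers

Normalization is counts-per-10k then log1p. Pseudobulk profiles hold,
per gene and cluster: mean log expression, expressing-cell fractions
inside/outside, and the one-vs-rest fold change computed on de-logged
means,

```
log2fc = log2((mean_cp10k_in + ε) / (mean_cp10k_out + ε)),  ε = 1e-9
```

The pseudocount only guards division by zero; it leaves large-effect
ordering intact, and a gene absent everywhere gets log2fc = 0.

Markers are two-sided Wilcoxon rank-sum tests on normalized log
expression, one gene at a time, cluster vs the entire rest of the
dataset (or an explicit second cluster for within-lineage contrasts,
e.g. among myocardial subclusters). The tested universe is all genes
expressed in at least one cell of either group — no min-pct or
fold-change prefilter, so the universe (and hence the Bonferroni
denominator) is permissive; Benjamini–Hochberg is available as an
option. Ranking is by adjusted p, then |log2fc|, then gene ID (ties
deterministic). `top_markers` returns the n highest-ranked genes with
log2fc > 0 and adjusted p < 0.05.

### Rank-sum implementation

One implementation backs markers and heart-rate comparisons. For
min(group) ≤ 6 the exact permutation distribution of the rank sum is
computed by a subset-sum dynamic program over doubled midranks —
exact under ties, and cheap even when the other group is large, where
naive enumeration of C(n+m, n) assignments would not be. Two-sided
p = min(1, 2·min(P(W ≤ w), P(W ≥ w))), the convention of the standard
exact tests. Larger groups use the normal approximation with the
usual tie correction and a 0.5 continuity correction; at the cohort
sizes used here (≥ 30 per group) the approximation is
indistinguishable from exact in the test suite's tolerance and keeps
the 2000-gene marker scans fast via a vectorized matrix path.

## Spatial mapping

Order of operations is fixed: **filter → smooth → fold change →
match → correlate → assign**.

* **Reference filter.** Genes whose maximum section count is below 20
  are removed ("less than 20" — a gene peaking exactly at 20 is
  retained). This drops profiles dominated by shot noise.
* **LOESS.** Per gene, a tricube-weighted local linear fit at each
  section over the q = max(degree + 2, ceil(α·S)) nearest sections,
  α = 0.15 (at S = 39, q = 6; at S = 40, q = 6). Distances are scaled
  by the q-th nearest distance, so the farthest neighbor carries zero
  weight — standard LOESS. Boundaries use the one-sided neighborhood;
  no padding or reflection. Robust reweighting iterations are not
  implemented (only the span is specified by the analysis this
  reproduces). Because sections form a fixed integer grid, the whole
  smoother is precomputed as an S × S linear operator and applied to
  the gene matrix in one product. Negative local-linear predictions
  are clamped to 0 so fold changes stay non-negative and the
  zero-drop rule handles them.
* **Fold changes.** Section side: fc(g, x) = smoothed(g, x) / mean over
  x; every retained gene's fc row therefore averages to exactly 1 (a
  tested invariant); all-zero rows stay zero and drop out at matching.
  Cluster side: fc(g) = 2^log2fc(g), strictly positive; missing
  log2fc values are skipped.
* **Matching and correlation.** For each cluster and section, genes in
  the ID intersection with non-zero values on both sides are paired;
  ρ(x) is the Pearson correlation of the paired fold changes (raw
  fold changes, not logs — the cluster values are explicitly
  converted before comparison). ρ is missing (not 0) when fewer than
  `min_matched` = 3 pairs remain or a vector is constant.
* **Quality proxy.** The average compared-gene count is the mean over
  clusters first, then over sections (the two orders differ only when
  cluster gene panels differ; the choice is exposed as
  `cluster_average_first`). Sections whose per-section mean falls
  below 0.5 of the average are flagged low-support; they are excluded
  from positional assignment but kept in the map rather than dropped.
* **Assignment.** Each cluster is placed at the non-flagged section
  maximizing ρ(x); ties break toward the lowest (most anterior)
  section; clusters with no defined ρ stay unassigned.
* **Subcluster concordance.** For fine-grained subclusters of a main
  cluster: gene_corr = Pearson of parent vs subcluster fold-change
  vectors over shared non-zero genes; spatial_corr = Pearson of the
  two ρ(x) vectors over sections where both are defined; a subcluster
  is homogeneous when both reach 0.6. Note an equal two-way split of
  a parent bounds these correlations near 1/√2 even for unrelated
  halves (the parent is their average), so the flag is most
  informative for minority subpopulations — the test suite
  demonstrates both a flagged distant minority and an unflagged
  random split.

## Heart-rate statistics

Rates are per-embryo beats per minute (30 s manual counts are doubled
before entry; fractional video-derived rates are accepted). The
Shapiro–Wilk gate (n ≥ 3; constant samples report p = 0 with a
warning) documents the departure from normality that motivates the
nonparametric path. Each knockout arm is compared with each control
arm (uninjected; scrambled-injected) by the two-sided rank-sum test;
the Holm–Bonferroni step-down adjustment (via statsmodels, checked
against the brute-force definition) spans the family of comparisons
in one run. Two-sided tests throughout — the conservative default for
two-group comparisons. Effect size is reported as the median
difference (test − control). No numerical reproduction of published
p-values is claimed: those depend on raw per-embryo measurements.

## Synthetic data: what it emulates, and what it does not

* **Section reference.** Gene g's expected profile is
  baseline + amplitude·exp(−(x − anchor)²/2w²): a Gaussian bump whose
  argmax is unambiguous truth. 20% of genes are flat "housekeeping"
  profiles and 10% are flat low-expressed genes whose maxima sit well
  below the count-20 filter, so the filter is exercised. Counts are
  negative binomial with mean m and dispersion θ (variance
  m + m²/θ) — tomo-seq and droplet counts are overdispersed;
  θ = 5 is the default noisy regime, large θ approaches Poisson, and
  θ = ∞ is the deterministic noise-free limit (counts = rounded
  means), which the examples use as the exact-identity case.
* **Cell matrix.** Each cluster is anchored at an evenly spaced
  interior section; its expected expression program is the section
  truth evaluated at that anchor, scaled to a lognormal library size
  (mean 5000). Genes bumping near a cluster's anchor are thereby its
  planted markers, and cluster fold-change vectors genuinely resemble
  the section fold changes near the anchor — the property the mapping
  exploits. Doublets are exact sums of two singlet columns from
  distinct clusters (heterotypic only), at a configurable rate of all
  droplets. Mito/hb reads are injected per cell: a configurable
  fraction of cells (defaults 5% mito, 3% hb) is pushed just above
  the respective QC threshold, the rest sampled below it, so both
  sides of each boundary occur.
* **Heart rates.** Two groups from a normal (or mean-matched
  skew-normal) distribution, control mean 146 bpm, sd 10 bpm, shift
  −28 bpm by default, n ≥ 2 per group.
* **Not emulated:** ambient RNA, batch effects beyond replicate
  labels, homotypic doublets, read-level data, cluster-assignment
  uncertainty (truth labels are exact), and 2-D/3-D anatomy (the
  reference is strictly 1-D). Passing tests therefore demonstrate
  correctness of the computations and recoverability under the stated
  noise model, not robustness to artifacts absent from the simulation.

All randomness descends from one integer seed through spawned NumPy
generators; identical configs give byte-identical tables.

## Numerical choices

* ε = 1e-9 pseudocount in fold changes; fc mean-of-one invariant held
  to 1e-9; LOESS checked against an independent per-point weighted
  least-squares solve to 1e-8; Pearson against the closed form to
  1e-12.
* Argmax ties (exactly equal ρ) break to the lowest section index;
  marker-rank ties break by gene ID; doublet-flag ties by score order
  then cell order — all deterministic.
* Degenerate inputs: zero-count cells get 0% fractions and are removed
  by the gene rule; constant genes get rank-sum p = 1; all-zero
  reference rows are filtered or drop out at matching; an empty
  post-filter reference raises with advice to review the threshold.

## Problem sizes

Default validation runs use 40 sections, 1500 genes, 10 clusters and
2000 cells (NB dispersion 5) for end-to-end recovery; 2000 genes or
replicates for calibration checks; 20 seeds × 3 dispersions for the
noise-degradation check. These sizes give stable statistics (binomial
99% CIs on rates, ≥ 9/10 recovery margins) while the whole suite runs
in about a minute and a half.

## Known limitations

* The doublet scorer makes no claim of matching any particular
  published tool's per-cell removals; only the mechanism and the
  separability it achieves on synthetic heterotypic doublets are
  specified.
* The marker gene universe is permissive (no expression prefilters),
  so adjusted p-values are conservative relative to toolkits that
  prefilter by detection fraction.
* ρ(x) pairs one fold-change value per gene per cluster against the
  per-section fold change; alternative pairings (e.g. correlating
  whole profiles across sections jointly) are not implemented.
* LOESS robustness iterations are unsupported; outlier sections
  influence fits with full tricube weight.
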