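# Methods

`invasig` implements a desk-scale version of the analysis chain used to
derive estrogen-receptor (ER)-regulated invasion gene signatures from
bulk RNA-seq contrasts, score them in single-cell populations, and
associate them with clinical outcome. Every stage runs on synthetic
inputs with planted ground truth, so the statistical behavior of the
chain — error calibration, recovery of planted effects, exact agreement
with textbook definitions — is verifiable without any external data.

## Bulk differential expression

Counts are modeled as negative binomial (NB) with mean μ and dispersion
φ, parameterized as `variance = μ + φμ²` (so φ = 0 is Poisson). The
chain is:

1. **TMM normalization.** Each sample is compared to the highest-depth
   column. Per-gene log2 ratios (M) and average log intensities (A) are
   computed over genes expressed in both samples, doubly trimmed (30%
   tails of M, 5% tails of A), and averaged with inverse delta-method
   precision weights. Factors are rescaled to geometric mean 1;
   effective library size = column total × factor.
2. **Common dispersion.** Counts are scaled to the geometric-mean
   effective library size and rounded ("equalized pseudo-counts"). A
   single φ is estimated by maximizing the conditional NB
   log-likelihood (conditioning on each gene's per-group total, which
   removes the unknown means) with a bounded 1-D search on [0, 10].
   Estimates below 1e-6, or no better than the φ = 0 boundary, snap
   to 0. Only a common dispersion is fitted — no tagwise or trended
   shrinkage — which is adequate at fixture scale and keeps the
   estimator fully specified.
3. **Conditional exact test.** Per gene, the group sums of the
   equalized pseudo-counts are conditioned on their total; the sum of n
   iid NB(μ, φ) variables with a shared mean is NB(nμ, φ/n), so every
   split of the total can be enumerated. The two-sided p-value sums the
   conditional probabilities of all outcomes no more likely than the
   observed one (ties within 1e-12 relative included). At φ = 0 and
   equal library sizes this reduces exactly to binomial conditioning,
   which is the independent oracle used in the tests.
4. **Fold change** uses the equalized group means with a pseudocount of
   0.125 added to each mean; positive log2FC = higher under ICI
   (fulvestrant). **FDR** is Benjamini–Hochberg step-up.

Under null simulation (2000 genes, φ = 0.1, 3 vs 3) the full chain
rejects at a rate consistent with the nominal 5% level, and the
dispersion estimator recovers the generating φ.

## Signature derivation

All genes with FDR ≤ 0.05 in a contrast form the "base" list for that
contrast. Signature 1 refilters the invaded-cell (INV+) contrast at
FDR < 0.001 and |log2FC| ≥ 0.5, then removes any gene whose id appears
in the noninvaded (INV−) base list — exclusivity is decided on gene
ids, so a gene regulated in opposite directions in the two contrasts is
still excluded. Signature 2 repeats the construction at FDR < 0.01 and
|log2FC| ≥ 0.25 after removing an externally supplied proliferation
gene set (in the original analysis this set came from pathway
enrichment of Signature 1; here it is an explicit input, recorded in
provenance). Exclusivity is judged against the base (FDR ≤ 0.05) INV−
list rather than the refiltered one, which makes "specifically
regulated in INV+ only" robust to near-threshold genes. Threshold
semantics: the base filter is inclusive (≤ 0.05, "0.05 or below");
refilters are strict on FDR and inclusive on |log2FC|.

## Single-cell processing

* **QC.** Barcodes with > 500 total counts are kept (strict
  inequality), then cells with ≥ 2000 detected genes and ≤ 15%
  mitochondrial counts (genes with the `MT-` name prefix). The
  mitochondrial threshold is applied to the UMI fraction.
* **Normalization.** Counts per cell are divided by the cell total,
  multiplied by 10⁴, and transformed with ln(1 + x). Summing
  exp(v) − 1 per cell returns exactly 10⁴, a conservation identity the
  tests check.
* **Covariate regression.** Per gene, an OLS fit on (intercept,
  mitochondrial fraction) replaces values by residuals. Cell-cycle
  scores are deliberately *not* regressed out by default: in this
  system the proliferative state is itself a cluster identity (one
  subpopulation is purely S/G2M), so removing it would erase the
  cluster, and because phase correlates with cluster membership the
  regression would also leak cluster-marker signal into unrelated
  cells.
* **PC selection.** A permutation (jackstraw-style) test: in each of
  100 permutations, 1% of genes have their values shuffled across
  cells and the PCA is recomputed; the shuffled genes' absolute
  loadings form a per-component null. Each gene receives an empirical
  p-value against that null, and the component's p-value is the
  binomial tail probability of the observed excess of genes with
  empirical p ≤ 0.01. The leading contiguous run of components with
  p < 0.05 is kept (falling back to one component, with a warning, if
  none is significant). The number of selected components is
  data-dependent; an explicit override is available.
* **Clustering.** K-nearest-neighbor graph in PC space (Euclidean),
  edges reweighted by the Jaccard overlap of the two neighbor sets
  (shared-nearest-neighbor weighting), then seeded Louvain modularity
  optimization. Labels are re-indexed in decreasing cluster-size order
  so downstream results do not depend on the partition's internal
  ordering. The default neighborhood is deliberately large
  (`k_neighbors = 90` at the ~500-cell reference scale): cell-cycle
  phase creates genuine subcommunities of ~50 cells inside each
  cluster, and a neighborhood wider than those subgroups absorbs them
  while leaving the (larger) clusters intact. At this setting the
  reference fixture is recovered exactly (5 clusters, ARI 1.0). For
  substantially larger datasets k should be scaled with cluster size.
* **Cell-cycle scoring.** Genes are ranked by mean expression and cut
  into 24 bins; each phase score is the mean expression of the phase
  gene set minus the mean of a pooled control set (up to 100 same-bin
  genes drawn per phase gene). Phase is the argmax of (S, G2M) when
  positive, else G1.

## Cluster enrichment (FEA)

Expression is z-scored per gene across the analyzed population (sample
SD; zero-variance genes contribute z = 0), and each cell's signature
score is the mean z over the signature genes present. Each cluster is
compared one-vs-rest with a two-sided Mann–Whitney rank-sum test (exact
null when n_in·n_out ≤ 400, tie/continuity-corrected normal
approximation otherwise); the AUC is U/(n_in·n_out) from the same
statistic. A cluster is called enriched when AUC > 0.6 **and** p < 0.01
jointly; raw p-values are reported without correction across clusters.
By default the ICI-downregulated subset of a signature is scored, since
ICI-upregulated genes (NFκB/EMT-related) are unlikely to mediate
ER-driven invasion.

## Cohort stratification and outcome

Patient expression is z-scored against the whole cohort (sample SD). A
patient is signature-positive when *any* signature gene exceeds z > 3
(strict; a `two_sided` option uses |z| > 3). The source text is
internally inconsistent about whether the negative group requires
z < −3 or merely the absence of a high outlier; the default takes the
"not positive" reading. Groups are tested against molecular subtype,
grade and vital status with Pearson's chi-squared (no continuity
correction, no multiplicity correction across variables) and against
overall and relapse-free survival with Kaplan–Meier curves and the
two-group log-rank test (both via `lifelines`, with hand-coded oracles
in the tests).

## Synthetic data

* **Bulk** (`gen_bulk`): four condition matrices (INV± × ±ICI).
  Per-gene baselines scatter log-normally (σ = 0.7) around a 200-count
  mean; library-size factors are uniform on [0.8, 1.2]; counts are
  Gamma–Poisson draws at dispersion φ = 0.1. Planted genes carry a
  log2FC (default ±2, a strong but realistic DE effect) applied only in
  the ICI samples of their contrast. The reference fixture plants 30
  INV+-exclusive genes (10 labeled proliferation) and 10 shared ones on
  a 2000-gene universe with 5 replicates per group.
* **Single cell** (`gen_sc`): 600 cells × 2500 genes, 5 equal
  clusters, each with 40 disjoint marker genes elevated 4-fold; one
  cluster additionally elevates a 50-gene set by 2^1.5. Ten
  mitochondrial genes receive a per-cell target fraction (2–10%).
  Phase structure: the enriched cluster is 53% S / 47% G2M; the others
  carry an actively-dividing-culture mix (60/25/15 G1/S/G2M) — a
  mostly-G1 background would make the expression-bin control matching
  too weak for the argmax phase rule, and a dividing breast-cancer
  culture is not mostly G1. Cells are multinomial draws at 8000–15000
  UMIs. Low-quality barcodes are planted explicitly (cycling through
  low total ≤ 500, low complexity < 2000 genes, high mito > 15%), so
  QC tests have exact truth. Depth and gene-count margins are chosen
  so that intact cells always clear the QC thresholds.
* **Cohort** (`gen_cohort`): gene z-scores are truncated standard
  normal on (−3, 3) except planted outliers (z ~ U[3.2, 6]), carried
  by a patient with probability 0.15; this makes the >3 SD rule exact
  against truth. Survival times are exponential (OS scale 120 months,
  RFS 90) with the hazard multiplied by 2.5 in the outlier-positive
  group; censoring is independent exponential, tuned so the reference
  group is censored at ~30%, which lets the hazard ratio shift the
  observed death fraction while keeping the groups exchangeable under
  a unit hazard ratio (so null log-rank p-values are exactly uniform).
  Subtype and grade frequencies shift toward LumB and grade 3 in the
  positive group.

What the generators do **not** model: doublets, ambient RNA, batch
effects, trended mean–variance relationships, read-level noise,
competing risks, or correlated gene–gene structure beyond the planted
blocks. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the stated models, not
robustness to those artifacts in real data.

## Problem sizes and numerics

Simulations run at fixture scale chosen for a single-CPU workstation:
2000-gene bulk matrices, 600-cell single-cell matrices, 1000-patient
cohorts, 50-seed enrichment calibrations, 200-seed log-rank null
calibrations. Ties in the exact test are matched within 1e-12 relative
probability; BH agreement with its oracle is exact to 1e-12; the
binomial-conditioning oracle agrees to 1e-9; chi-squared matches its
closed form to 1e-10. Degenerate inputs (all-zero columns, constant
covariates, zero-variance genes, single-category clinical variables,
clusters equal to the whole population) raise errors or warnings as
documented per function rather than propagating NaNs.

## Known limitations

* Common dispersion only; real data with gene-specific overdispersion
  would need tagwise shrinkage.
* The jackstraw permutation count (100) bounds per-gene empirical
  p-resolution; very weak components near the significance boundary
  are selected with seed-dependent variability.
* The SNN graph is dense at the default k; for datasets beyond a few
  thousand cells both the graph construction and the exact SVD should
  be replaced with approximate versions.
* The cohort generator plants at most one outlier gene per positive
  patient; co-occurrence structure across signature genes is absent.
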