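# invasig

Derivation and downstream analysis of estrogen-receptor (ER)-regulated
**invasion gene signatures** in breast cancer, as a tested, reusable
pipeline.

Most metastatic breast cancers arise from ER+ disease, yet ER's role in
invasion is unclear: in an ER+/IKKβ-driven invasion model, genes
regulated by the ER degrader fulvestrant (ICI) *specifically in
invaded cells* split into a proliferation-dominated signature and a
second, proliferation-depleted signature (vesicle/organelle biology)
that associates with aggressive disease. This package implements the
full analytical chain behind that kind of result:

1. **Bulk differential expression** on raw counts: TMM effective
   library sizes, common negative-binomial dispersion φ (variance
   = μ + φμ²) by conditional maximum likelihood, a per-gene
   conditional exact test, and Benjamini–Hochberg FDR.
2. **Signature derivation** by filter-and-set algebra: Signature 1 =
   genes at FDR < 0.001 and |log2FC| ≥ 0.5 in the invaded (INV+)
   contrast that are not ICI-regulated (FDR ≤ 0.05) in the noninvaded
   (INV−) contrast; Signature 2 = the same at (0.01, 0.25) after
   removing proliferation genes.
3. **Single-cell processing**: barcode/cell QC (> 500 counts, ≥ 2000
   genes, ≤ 15% mitochondrial), ln(1 + CP10K) normalization,
   mitochondrial-load regression, permutation-based PC selection,
   SNN/Louvain clustering, and binned-control cell-cycle scoring.
4. **Cluster enrichment (FEA)**: per-cell signature score = mean
   z-scored expression of the signature genes; per-cluster one-vs-rest
   Mann–Whitney test and ROC-AUC; enriched ⇔ AUC > 0.6 and p < 0.01.
5. **Cohort stratification**: patients are signature-positive when any
   signature gene exceeds z > 3 versus the cohort mean; groups are
   compared by chi-squared (subtype, grade, vital status) and
   Kaplan–Meier / log-rank (overall and relapse-free survival).

A synthetic-data module (`invasig.simulate`) generates bulk,
single-cell and cohort inputs with planted ground truth matching the
statistical assumptions of each stage, so the whole chain is verifiable
offline. See `docs/methods.md` for models, parameters and limitations.

## Worked example

The analysis is organized as numbered drivers over the library:

```bash
python analysis/01_simulate_inputs.py --seed 5      # write fixtures under results/data/
python analysis/02_differential_expression.py       # DE per contrast
python analysis/03_derive_signatures.py             # signature algebra
python analysis/04_single_cell_clustering.py --seed 5
python analysis/05_cluster_enrichment.py
python analysis/06_cohort_outcome.py
```

Output from a seed-5 run:

```
Signature 1: 30 genes (recovered 30/30 planted INV+-exclusive genes)
Signature 2: 20 genes = 20 overlapping Signature 1 + 0 distinct; 10 ICI-downregulated
QC: 600 barcodes -> 540 cells
6 significant PCs; 5 Louvain clusters
cluster ARI vs planted truth: 1.000; phase accuracy: 0.969
planted_enriched: scored 50 genes; enriched clusters [3]
stratification: 160 signature-positive / 840 negative patients
subtype: chi2=54.47 (df=3), p=8.93e-12
grade: chi2=25.14 (df=2), p=3.48e-06
vital_status: chi2=17.62 (df=1), p=2.7e-05
OS log-rank: statistic=80.20, p=3.39e-19
RFS log-rank: statistic=119.86, p=6.77e-28
```

Reading this: the DE + signature stage recovers exactly the 30 planted
invasion-specific genes (the 10 proliferation-labeled ones are removed
from Signature 2, whose remaining 20 genes all overlap Signature 1 —
at fixture scale no background gene clears the relaxed filter). QC
removes exactly the 60 planted low-quality barcodes; clustering finds
the 5 planted subpopulations perfectly; the planted 50-gene set is
enriched in exactly one cluster (AUC 1.0, the pure-S/G2M proliferative
subpopulation). In the cohort, the 16% of patients carrying a >3 SD
outlier in any signature gene skew toward Luminal B, higher grade, and
markedly worse survival — the planted 2.5× hazard.

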