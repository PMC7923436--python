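# cpgpairs

Batch-robust DNA-methylation subtyping of tumors from **immune CpG-pair
scores**, with cross-platform subtype transfer and downstream immune,
survival and genomic characterization.

## The problem

Methylation-array cohorts (e.g. TCGA kidney clear-cell carcinoma on the
Illumina 450K and 27K BeadChips) are assembled across platforms, batches and
centers, and absolute beta values are not comparable between them. A
classifier or clustering built on raw beta values therefore tends to learn
the batch, not the biology. This package implements a subtyping pipeline
whose core feature is *relative*: for two CpG probes measured in the same
sample, only their order matters.

## The method

For a sample *s* and a pair of differentially methylated CpG probes
*(i, j)* with *i < j* lexicographically, the **CpG-pair score** is

```
score(i, j; s) = 1  if beta_i(s) > beta_j(s)
                 0  otherwise (ties score 0)
```

Because the score depends only on the within-sample ordering of two values,
it is invariant to any strictly increasing per-sample distortion — exactly
the form batch and platform effects take. The pipeline is:

1. **Preprocess** — keep probes in strand-aware promoter windows
   (TSS − 2 kb upstream to TSS + 0.5 kb downstream) of immune-cell marker
   genes; drop probes missing in > 70 % of samples, on chromosomes X/Y, or
   cross-reactive; impute the rest by probe-wise KNN (k = 10).
2. **DMS detection** — per-probe two-sided Wilcoxon rank-sum test of tumor
   vs normal; a probe is a differentially methylated site (DMS) when
   BH-FDR < 0.05 and |Δβ| > 0.2 (Δβ = difference of group mean betas).
3. **Pair scoring** — all C(n, 2) unordered DMS pairs are binarized per
   sample by the rule above; pairs scoring constantly (same value in > 80 %
   of samples) are dropped.
4. **Subtype discovery** — complete-linkage hierarchical clustering of
   samples on Hamming distance between binary pair columns, cut at k = 3;
   validated by PCA. An optional resampled consensus wrapper is available.
5. **Transfer** — stratified 3:1 A/B split; RBF-kernel SVM tuned by
   stratified 5-fold cross-validated grid search on A, evaluated on B, and
   applied to new samples (e.g. a 27K-like platform) scored on the retained
   pairs.
6. **Characterization** — ssGSEA immune-cell enrichment (rank-weight
   exponent α = 0.25), ESTIMATE-style stromal/immune scores with tumor
   purity = cos(0.6049872018 + 0.0001467884 · ESTIMATE), Kaplan–Meier /
   log-rank survival comparisons, chi-square clinicopathology associations,
   per-cluster mutation frequencies, and gene-level copy-number gain/loss
   calls at the ±0.2 segment-mean thresholds with one-vs-rest contrasts.

A **synthetic cohort generator** (`cpgpairs.synthetic`) produces a fully
self-consistent cohort — methylation, expression, gene sets, clinical table,
MAF, SEG — with known planted subtypes, so the whole pipeline is testable
without any download.

## Worked example

```python
import cpgpairs as cp
from sklearn.metrics import adjusted_rand_score

cfg = cp.SimConfig(n_tumor=120, n_normal=60, n_probes=300,
                   n_dms_planted=40, n_genes=2000, seed=7)
tumor, normal, annotation, clinical, truth = cp.generate_cohort(cfg)

tumor = cp.knn_impute(cp.filter_probes(tumor, annotation))
normal = cp.filter_probes(normal, annotation).loc[tumor.index]

dms = cp.selected_probes(cp.wilcoxon_dms(tumor, normal))
scores = cp.filter_constant_pairs(cp.score_pairs(tumor, cp.build_pairs(dms)))
labels = cp.hierarchical_cluster(scores, k=3)
print(len(dms), len(scores), adjusted_rand_score(truth.sample_subtype[labels.index], labels))
```

prints

```
40 359 0.9614...
```

meaning: all 40 planted differentially methylated probes were recovered, the
780 candidate pairs reduced to 359 informative ones after the constancy
filter, and the discovered 3-subtype partition agrees with the planted truth
at an adjusted Rand index of 0.96. The `examples/` directory walks through
each capability (simulation, discovery, SVM platform transfer, immune/TME
scoring, survival and clinicopathology statistics, mutation/CNV contrasts)
as a short narrative script; run them with `python examples/02_discover_subtypes.py`
etc.

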