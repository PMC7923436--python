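# Methods

This note documents the models, parameter choices and numerical conventions
behind `cpgpairs`, and what the synthetic-data experiments do and do not
demonstrate about real cohorts.

## Pair-score representation

The unit of analysis is the unordered pair of differentially methylated CpG
probes. Within one sample the pair is binarized: 1 if the lexicographically
first probe's beta exceeds the second's, 0 otherwise, with ties scoring 0.
Pair orientation is a pure labeling convention: swapping the two probes
complements every bit (s → 1 − s), so any fixed orientation yields an
equivalent representation; lexicographic order makes it canonical and
reproducible. The representation's value is *monotone-transform invariance*:
any strictly increasing distortion of a sample's beta values — the usual
form of batch, scanner and platform effects — leaves that sample's scores
bit-identical. This is asserted as a property test and measured by the
acceptance script.

Pairs scoring constantly (the same value in strictly more than 80 % of the
training tumor samples) are removed: they cannot separate groups. The filter
is applied once, on tumor training samples only, and is idempotent.

## Preprocessing

* **Promoter windows.** A probe is promoter-associated when its position
  lies within 2 kb upstream to 0.5 kb downstream of a gene's transcription
  start site. "Upstream" is read strand-aware (5′ of the TSS): the window is
  [TSS − 2000, TSS + 500] on the + strand and [TSS − 500, TSS + 2000] on the
  − strand, 1-based inclusive.
* **Probe exclusion.** Probes missing in strictly more than 70 % of samples
  (boundary retained), probes on chromosomes X/Y, and probes on a
  user-supplied cross-reactive list are removed. The three predicates are
  independent per probe, hence commute. Missingness is computed jointly over
  all supplied samples.
* **KNN imputation.** A missing entry is replaced by the unweighted mean of
  the target sample's values at the k = 10 nearest probes, with distance the
  (unnormalized) squared Euclidean distance over the samples observed in
  both probes, and candidate donors restricted to probes observed in the
  target sample. Probe-wise neighbours are the convention of the methylation
  imputation literature; k = 10 is a common default, exposed as a parameter.
  Imputation is idempotent and never alters observed values.

## DMS detection

Per probe, a two-sided Mann–Whitney (unpaired Wilcoxon rank-sum) test of
tumor vs normal. The exact null distribution is used for small tie-free
comparisons (n₁·n₂ ≤ 400); otherwise the tie-corrected normal approximation.
Benjamini–Hochberg adjustment is applied across all tested probes. Δβ is the
difference of group *means* (the dominant convention for "delta beta";
medians would be the alternative). Selection requires FDR < 0.05 **and**
|Δβ| > 0.2, both strict: a probe sitting exactly on a threshold is excluded.
Both thresholds are exposed as arguments.

## Subtype discovery

Samples are clustered on the binary pair matrix with complete-linkage
agglomeration over pairwise Hamming distances, and the dendrogram is cut at
k (default 3). Hamming is the natural metric for 0/1 vectors and is monotone
in squared Euclidean distance on this domain, so the linkage order is
unaffected by the choice between them. Samples are sorted by identifier
before linkage, making the partition invariant to input order; cluster
labels are canonicalized to 1..k by decreasing size (ties broken by smallest
member sample ID) so partitions are comparable across runs. A resampled
consensus variant (default 100 draws of 80 % of samples, same linkage on
1 − co-assignment frequency) is available behind a flag; on clearly
separated data it reproduces the plain partition, and it is not the default
because the plain procedure is the fully specified one.

PCA validation mean-centers the pair features; components are ordered by
decreasing explained variance with each component's largest-magnitude
loading made positive (a deterministic sign convention).

## SVM transfer

The labeled training cohort is split 3:1 (stratified by cluster, seeded)
into groups A and B. An RBF-kernel SVM is selected by exhaustive grid search
over C ∈ {0.1, 1, 10, 100} and γ ∈ {scale, 0.01, 0.1, 1}, scored by mean
stratified 5-fold cross-validation accuracy on A, with ties broken toward
smaller C and then the earlier γ; the winner is refit on all of A. B serves
as the internal hold-out; new-platform samples are scored on the retained
pair universe (no re-filtering) and classified with the fitted model. A
hold-out accuracy within 10 points of the CV accuracy is asserted as a guard
against information leakage.

## Immune and microenvironment scoring

ssGSEA: per sample, genes are ranked by decreasing expression; the
enrichment score is the summed difference between the in-set ECDF weighted
by rank^α (α = 0.25, the customary exponent) and the uniform out-of-set
ECDF, accumulated over the whole ranked list. Scores depend only on
within-sample ranks, hence inherit monotone-transform invariance. Optional
normalization divides the whole score matrix by its global range; the
unnormalized scores are used for ESTIMATE because the purity transform
expects that scale.

ESTIMATE-style scores: stromal and immune signature ssGSEA scores, their
sum, and tumor purity = cos(0.6049872018 + 0.0001467884 · ESTIMATE) — the
published calibration of purity against the combined score, a strictly
decreasing function on the realistic score range. Note the calibration was
fitted on genome-wide array data, so on synthetic cohorts the *ordering* of
purity across subtypes is meaningful while its absolute level is not.

Group comparisons use the tie-corrected Kruskal–Wallis test (χ² reference on
k − 1 df); the degenerate all-equal case is defined as H = 0, p = 1. Across
the 28 immune-cell sets, raw p-values are reported (matching the usual
star-annotation practice) alongside a BH-adjusted column. Immune-checkpoint
genes (CD80, CD86, CD276, CD274, CTLA4, PDCD1LG2, PDCD1) are compared on raw
expression per gene, not as a set score.

## Survival and clinicopathology

Kaplan–Meier product-limit estimation and the k-group log-rank test (with
all pairwise contrasts) are delegated to `lifelines`. The cohort loader
implements the inclusion rules — follow-up strictly greater than 30 days,
known grade/stage/T/M — and reports how many samples each rule removed.
Categorical features are tested against subtype with Pearson chi-square
without continuity correction; expected counts are returned and a flag is
raised when any falls below 5. Age is dichotomized at a configurable cut
(default 65 years), since age enters the contingency analysis as a category.

## Genomic alterations

Mutation frequencies count, per cluster, the fraction of samples with at
least one non-silent variant per gene; the silent/non-coding class list
follows the maftools convention and is configurable. Top-N lists (default
30) break frequency ties alphabetically, and the union of the per-cluster
lists is reported. One-vs-rest contrasts use Pearson chi-square on the 2×2
table, substituting Fisher's exact test (flagged) when any expected count is
below 5.

Copy-number segments (1-based inclusive, validated non-overlapping per
sample and chromosome; on violation the first record is kept with a warning)
are reduced to one value per gene and sample as the overlap-length-weighted
mean of intersecting segment means, with the gene model in 0-based half-open
coordinates. Calls use the ±0.2 thresholds, strictly: gain > 0.2,
loss < −0.2, anything else (including the thresholds and missing values,
the latter flagged) neutral. Full GISTIC significance modeling (background
rates, G-scores, peak deconvolution) is out of scope; the threshold calling
is the operational rule used downstream.

## Synthetic cohort generator

The generator emulates the input data model of a two-platform TCGA-style
renal cohort. Design and defaults:

* **Cohort sizes** default to 323 tumors and 160 normals — the training-set
  scale of the motivating cohort — with three equally likely subtypes
  (discovered cluster sizes are an outcome, not a generator condition).
* **Beta values** are clipped Gaussians around probe/subtype means
  (noise SD 0.1). Gaussian means are easier to control than Beta-law shape
  parameters; clipping mildly distorts moments near 0/1, so planted probes
  keep their means in [0.08, 0.92].
* **Planted DMS probes** (default 40) shift tumor means by ±0.35 relative to
  normal; non-planted probes share identical means in both groups.
* **Pair-order structure**: each planted probe receives per-subtype mean
  offsets (evenly spaced in ±0.12, permuted per probe, centered so the
  tumor–normal shift is preserved in expectation). The pair templates follow
  from the subtype means, so the binarization path itself — not an injected
  binary matrix — is what recovers the structure. `pair_signal` ∈ [0.5, 1]
  maps linearly to the per-probe probability 2·f − 1 of following the own
  subtype's offsets (otherwise a uniformly random subtype's): f = 1 is
  perfect adherence, f = 0.5 removes all subtype structure, and the default
  f = 0.9 leaves pair orders matching their template roughly 85–90 % of the
  time once noise is included.
* **Missing values** are injected into the tumor matrix only (rate 0.02),
  with a 30 % quota of probes kept complete so KNN imputation always has
  donors; the normal matrix stays complete.
* **Immune level** per sample is subtype-determined (harsher-prognosis
  subtypes are more infiltrated, the pattern reported for methylation-low
  tumors), on a 0.2–0.8 scale with Gaussian jitter. Expression is log-normal
  with immune-set genes multiplied by exp(2.5·(level − 0.5)) and stromal
  signature genes following an independent uniform stromal level with a
  weaker exp(0.8·(level − 0.5)) coupling. The stromal coupling is weak and
  subtype-independent by design: the subtyping is immune-driven, so stromal
  scores should (and do) differ little across subtypes. With very small gene
  universes (≲500 genes) the immune boost covers a large fraction of the
  transcriptome and mechanically depresses the ranks — hence the ssGSEA
  scores — of everything else; TME-pattern experiments therefore use the
  default 2000-gene universe.
* **Survival** is exponential with per-subtype hazards (defaults
  8·10⁻⁴, 4·10⁻⁴, 1.6·10⁻³ per day, i.e. median survival ≈ 2.4, 4.7 and
  1.2 years) under independent uniform censoring on [60, 2500] days — the
  smallest model that makes the log-rank test discriminative. Staging
  categories (T/N/M/grade/stage) shift toward worse values with the
  subtype's hazard rank; sex and age are independent of subtype.
* **Alterations**: a renal-driver gene pool is mutated at a background rate
  of 0.05 per gene and sample, with one gene enriched (×10) in subtype 1 and
  one in the last subtype; `mut_enrichment = 1` is a null configuration.
  One genomic region gains (+0.3) in subtype 1 and one loses (−0.3) in
  subtype 2; other segment means are N(0, 0.05) noise. MAF/SEG coordinates
  are 1-based inclusive, the BED-like gene model 0-based half-open.
* **Second platform**: a probe subset retaining all planted DMS probes plus
  the distortion (x + 0.05)/1.05 — strictly increasing and [0, 1]-preserving
  — standing in for a 27K-like platform with a batch offset.
* **Determinism**: one seed drives independent child generators for the
  methylation, expression and alteration stages; equal seeds give
  byte-identical outputs.

### What the synthetic experiments show — and what they do not

Passing tests demonstrate that the pipeline's statistics and algorithms are
implemented correctly (against enumeration/closed-form oracles), that the
pair representation is exactly batch-invariant, and that under the planted
generative model the pipeline recovers subtypes, differential probes and
alteration contrasts at the expected operating characteristics. The
generator does **not** emulate probe–probe correlation (LD-like co-methylation
blocks), Beta-distributed heteroscedastic noise, platform-specific probe
chemistry, subclonal mutations or purity-confounded copy-number signal, and
it treats the normal group as homogeneous. Performance numbers on synthetic
cohorts are therefore upper bounds on, not estimates of, real-data
performance.

## Problem sizes used in tests and the acceptance script

Test cohorts use 60–160 tumor samples, 300–400 probes with 40 planted DMS
probes, and 500–2000 genes; the acceptance script sweeps ten cohorts of 160
tumors for subtype recovery and one 2000-gene cohort for the TME pattern.
These sizes were chosen so the full suite completes in well under a minute
while keeping every group large enough for the asymptotic tests to be valid.
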