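# Methods

## The problem and the overall model

Multi-platform tumor cohorts spanning several tissues of origin carry two
layers of structure: a dominant lineage (tissue-of-origin) signal and weaker
subtype signals that may be shared across lineages. Unsupervised analysis of
absolute molecular values recovers the first layer and hides the second.
The pipeline's working model is therefore additive on some latent scale:

    x[feature, sample] = mu(feature, lineage) + nu(feature, subtype) + noise

and its central operation is to estimate and remove `mu` nonparametrically,
feature by feature, inside each lineage, before any clustering or scoring.

## Within-lineage normalization

For each feature and each lineage the per-lineage median is subtracted and
(in `median_sd` mode) the result is divided by the per-lineage standard
deviation. Conventions:

* "Standard deviations from the median" is read literally as
  `(x − median) / SD`, with SD the usual sample standard deviation about the
  **mean** (n−1 denominator), not a median-based scale estimate. The
  centered values therefore have median exactly 0 and SD exactly 1 per
  (feature, lineage).
* Medians of even-sized groups use midpoint interpolation, for determinism.
* Features whose per-lineage SD falls below `sd_floor` (default 1e-8) are
  set to 0 in that lineage: a constant feature carries no signal and must
  not blow up under division.
* Missing values are ignored in the median/SD and remain missing.
* Methylation beta values are centered only (`median_only`), preserving
  their interpretation as shifts of a bounded quantity.
* `global_median_sd` (whole-cohort centering) is kept as the comparator
  that demonstrates the tissue effect.

Expression ranking may be done on `log2(x + pseudocount)` while clustering
runs on centered values; both are configurable, since the two choices serve
different purposes (variance stabilization for ranking vs. interpretability
of SD units for scoring).

`batch_adjust` is a per-feature moment-matching adjustment: each batch is
standardized to mean 0 / SD 1 and rescaled to the pooled feature moments.
It removes additive and multiplicative batch effects exactly but performs
no empirical-Bayes shrinkage across features; it is intended for the
generated data in this package, where batch effects are simple location and
scale shifts.

## Feature selection

A feature's score is the mean over lineages of its per-lineage SD
(optionally on logged values). Lineages where the feature has fewer than
two observed values are omitted from the mean. Ties break lexicographically
on the feature id. Platform conventions: top 2000 features for mRNA and
methylation, top 500 for miRNA, all protein features, and the full
(cytoband-style collapsed) matrix for copy number.

## Consensus clustering

Pearson distance between sample profiles, `d = 1 − r`, is computed over
features observed in both samples (pairwise-complete); a pair sharing fewer
than three features is an error, and a constant profile (undefined `r`) is
an error naming the sample. Because `d(i, j)` does not depend on which other
samples are present, the full distance matrix is computed once and sliced
per resampling iteration.

Each of `iterations` rounds (default 1000) draws `ceil(0.8 n)` samples
without replacement and cuts an agglomerative tree at every `k` in the
requested range. Ward linkage on a non-Euclidean dissimilarity is
convention-dependent; here the Pearson distances play the role of the
*squared* Euclidean distances in the Lance–Williams recurrence (the
classical "ward.D" convention, implemented by handing their square roots to
the Euclidean-form Ward update). Average linkage is plain UPGMA. Merge
order is deterministic for a given input.

The consensus entry `C(i, j)` is co-clustered count over co-sampled count; a
pair never co-sampled is reported as 0 with a warning (not an error). Final
labels at each `k` cut a tree built on `1 − C` with the same linkage, and
every cluster in the final cut is nonempty.

The per-`k` stability diagnostic is the area under the empirical CDF of the
off-diagonal consensus values, computed in closed form as `mean(1 − C)`,
with `delta_area(k)` the relative change from `k−1` (at the smallest `k` it
equals the area itself, by convention). Following the field's practice for
this cohort design, `k = 7` is the default reported solution per platform,
with the full diagnostic table always emitted; the synthetic configurations
in this package use the planted `k` instead.

## COCA

Per-platform subtype calls are encoded as binary indicator rows
(`platform|label`), columns sorted by sample id. A sample missing from a
platform receives zeros across that platform's rows — the indicator
semantics of the approach — rather than a masked value. Samples with no
call on any platform are excluded with a warning and listed. Indicator rows
constant across samples (a platform that assigned everyone one label) are
dropped before clustering: they carry no information, and dropping them
makes COCA exactly invariant to the addition of an uninformative platform.
The indicator matrix is then consensus-clustered with the same defaults as
the platforms (1000 iterations, 80% resampling, Ward, Pearson), and the
`k`-group cut (default `k = 9`) is reported with integrated subtypes named
`c1..ck` in decreasing size order.

## Subtype characterization

* **Differential features.** Welch (unequal-variance) two-sample *t*-test
  per feature, each subtype vs. the rest; the unequal-variance form is the
  robust default wherever a two-sample *t* is required in this package.
  Per subtype the `top_n = 100` features with smallest *p* are kept (ties:
  larger |t| first, then feature id). The classifier gene list concatenates
  the per-subtype lists and removes duplicates keeping first occurrence, so
  with 9 subtypes it holds *up to* 900 genes; the realized count is logged.
  A feature identical inside and outside a subtype is assigned t = 0, p = 1.
* **Signature scores.** `mean` mode averages the normalized values of the
  signature's genes; `tscore` mode computes, within each sample, the Welch
  *t*-statistic of up-gene values against down-gene values (0 with a
  warning when both groups are constant, keeping scores bounded); `sumdiff`
  is the EMT convention — the sum over 14 mesenchymal markers (ZEB1, CDH2,
  FN1, FOXC2, GSC, ITGB6, MMP2, MMP3, MMP9, SNAI1, SNAI2, SOX10, TWIST1,
  VIM) minus the sum over 3 epithelial markers (CDH1, DSP, OCLN). The
  proteomic MAPK signature is the mean over nine phospho-proteins (pSHC,
  pRAF, pMEK, pERK, pSRK, pYB1, pP38, pJNK, pJUN). Gene coverage (fraction
  of signature genes present) is recorded with every score. Pathway
  "summary scores" normalize each component score vector to SDs from the
  median across samples and average them; constant vectors contribute zero.
* **Methylation summaries.** The per-sample methylation index is the
  fraction of non-missing probes with beta strictly greater than 0.3; the
  epigenetic-silencing call for a single probe is beta at or **above** 0.2
  (inclusive). The two boundary conventions differ deliberately, following
  the respective definitions ("> 0.3" vs. "0.2 or above").
* **Reference similarity.** Reference cell/tissue profiles are
  median-centered per gene across all reference samples; each reference
  profile in a group is correlated (Pearson) with each tumor profile in a
  subtype, and the cell value is the one-sample *t*-statistic of those
  correlations against zero. Cells with fewer than two correlations are
  missing. Note the centering is across the whole reference panel, so a
  group's signature is measured relative to the other groups.
* **Pathway alterations.** A gene is altered in a sample if: oncogene — a
  hotspot-flagged nonsilent variant or a +2 (high-level) amplification;
  tumor suppressor — any nonsilent variant or a −2 (deep) deletion;
  `always_nonsilent` (the receptor-kinase exception, e.g. FGFR/KIT/MET) —
  any nonsilent variant. A pathway is altered if any member gene is;
  fractions are over the samples with mutation data.

## Association statistics

Overlap between two label sets is scored per label pair by the one-sided
Fisher exact test in the enrichment direction — the upper hypergeometric
tail including the observed count — computed on the samples shared by both
label sets. Raw p-values are reported (a Benjamini–Hochberg helper exists
but is off by default). Survival uses the Kaplan–Meier product-limit
estimator and the multi-group log-rank test (df = groups − 1), both via
lifelines; at tied times events are processed before censorings. The
Mann–Whitney U test uses midrank ties, exact enumeration when the combined
sample is ≤ 12 without ties, and otherwise the normal approximation with
tie-corrected variance and continuity correction.

## Centroid classification

Subtype centroids are per-gene means of the centered training values over
the classifier genes. External profiles are standardized per profile
(across genes) and then centered per gene to SDs from the median across
external samples — within each lineage by default, or across the whole
cohort for single-lineage sets. The per-profile standardization comes
first so that the full procedure is *exactly* invariant to positive affine
transforms of any individual profile (scanner gain/offset differences);
the final Pearson correlation alone would be invariant only if the
cross-sample gene statistics were unaffected. Each profile is assigned the
candidate subtype (per-lineage candidate lists restrict the choice) with
the highest correlation over the shared genes; ties go to the first
candidate in declared order and are flagged, and assignments with best
correlation below 0.1 can be flagged low-confidence. Every profile is
assigned — there is no rejection threshold by default.

## Synthetic cohorts

The generator emulates the structure the pipeline is designed for, with
defaults chosen as a regime where the tissue effect clearly dominates yet
the subtype effect is recoverable after normalization: 3 lineages × 60
samples sharing 3 subtypes (planted cyclically, so every subtype appears in
every lineage), lineage shifts of ±3 SD on 50% of features, subtype shifts
of ±1.5 SD on 10%, unit Gaussian noise, 10% per-platform sample dropout.
Effect signs are fixed per (feature, group) by the seeded generator — not
resampled per sample — so groups form coherent clusters. Per-platform
emissions: continuous platforms emit the latent value; methylation emits
`logistic(x)`, strictly inside (0, 1) and monotone in the signal (simpler
and more clusterable than Beta sampling); copy number discretizes at latent
cutpoints −2.5, −1, 1, 2.5 into {−2..2}, keeping high-level events sparse;
mutation emits Bernoulli draws with rate `logistic(x − 3)` (≈ 5% baseline).
Survival is exponential with hazard proportional to the subtype's hazard
multiplier (defaults 1.0/1.8/3.0 over a 1/1000-per-day baseline, i.e.
median survival roughly 2 years for the best group) under independent
exponential censoring tuned to a 30% censoring fraction. Each platform has
its own RNG stream keyed off the master seed, so adding a platform never
perturbs the others; a sample dropped by chance from every platform is
deterministically rescued into the first.

What the generator does **not** emulate: real marginal distributions,
gene–gene correlation structure, mutation spectra or signatures, platform-
specific technical artifacts, or gene identities. Passing tests therefore
demonstrate that the algorithms recover planted additive structure under
Gaussian noise — not that they would resolve any particular real cohort.

Noisy per-platform calls for COCA testing report the true subtype with
probability `1 − flip`, otherwise a uniformly random other label, and are
missing with a configurable probability.

## Problem sizes, tolerances, and degenerate inputs

The shipped tests and the acceptance script run the pipeline at the
generator defaults (180 samples, 500 mRNA features) with 100–250 consensus
iterations — enough for the consensus matrices to stabilize at these sizes
while keeping the whole suite fast; production runs would use the 1000-
iteration default. Exact-arithmetic claims (round-trips, score formulas,
the methylation index) are tested to 1e-12; statistics against independent
direct-formula oracles to 1e-9 (Welch *t*), 1e-12 (hypergeometric tail,
exhaustively for all 2×2 tables with totals up to 50), and 1e-6 (log-rank).
Degenerate inputs are decided, not left to chance: constant features
normalize to zero, constant profiles are errors in correlation distance,
degenerate *t*-scores are 0 with a warning, never-co-sampled pairs get
consensus 0 with a warning, and samples with no platform call are excluded
from COCA with a warning.

## Known limitations

* Ward on Pearson distance is one of several defensible conventions; trees
  from other conventions (e.g. ward.D2) can differ near ties.
* The moment-matching batch adjustment does not shrink and can overfit
  small batches; it is not a substitute for empirical-Bayes methods on
  real data.
* The per-subtype *t*-tests treat features independently; no multiplicity
  correction is applied to the differential tables (the top-N cut is a
  ranking device, not an inference).
* COCA weighs every platform equally; a platform with many clusters
  contributes more indicator rows and hence more weight in the correlation.
* Survival comparisons are plain multi-group log-rank tests with no
  stratification or covariate adjustment.
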