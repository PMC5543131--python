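# transtype

Pan-lineage molecular subtyping for multi-platform cancer cohorts.

When tumors from several tissues of origin are profiled together (mRNA,
miRNA, protein, DNA methylation, copy number, mutations), unsupervised
clustering almost always returns the tissue labels: lineage-specific
expression dominates every other signal. `transtype` implements the analytic
strategy that works around this — remove the tissue effect, cluster each
platform, then reconcile the platforms — so that molecular subtypes shared
*across* cancer types can surface:

1. **Within-lineage normalization.** Per feature, values are centered to the
   median computed separately inside each lineage and scaled to that
   lineage's standard deviation: `x ↦ (x − median_L) / sd_L`. Methylation
   beta values are median-centered only.
2. **Feature selection** by average within-lineage SD, so a feature must
   vary inside several tissues to be kept (top 2000 for mRNA/methylation,
   top 500 for miRNA, all protein features, by convention).
3. **Consensus clustering** per platform: repeated hierarchical clustering
   (Ward or average linkage, Pearson distance `d = 1 − r`) of random 80%
   sample subsets; the consensus matrix entry `C(i,j)` is the fraction of
   co-sampled iterations in which samples *i* and *j* co-clustered, and the
   area under the consensus CDF diagnoses the number of clusters *k*.
4. **COCA (cluster-of-clusters analysis).** Each platform's subtype calls
   become binary indicator rows; consensus clustering of the 0/1 indicator
   matrix defines the integrated, pan-lineage subtypes `c1..ck`.
5. **Characterization.** One-vs-rest Welch *t*-tests per feature (top 100
   per subtype form the classifier gene list), per-sample methylation index
   (fraction of probes with beta > 0.3), signature scores (mean, *t*-score
   contrasting up- vs down-genes, EMT sum-difference), pathway-level
   mutation/copy-number alteration calls, and reference-profile similarity
   (mean Pearson correlation expressed as a *t*-statistic).
6. **Association and classification.** One-sided Fisher enrichment between
   label sets, Kaplan–Meier curves and multi-group log-rank tests for
   survival, and nearest-centroid (highest Pearson correlation)
   classification of external expression profiles into the subtypes.

A synthetic-cohort generator plants a dominant lineage effect and a weaker
cross-lineage subtype effect with known ground truth (plus subtype-dependent
exponential survival and noisy per-platform calls), so every stage of the
pipeline is testable without any external data.

## Worked example

```python
import pandas as pd
from sklearn.metrics import adjusted_rand_score
import transtype as tt

cfg = tt.SimConfig(seed=1, missing_platform_prob=0.0,
                   features_per_platform={"mrna": 500})
matrices, annotation, truth = tt.simulate_cohort(cfg)
mrna = matrices["mrna"]

lineage = [truth.lineage[s] for s in mrna.sample_ids]
subtype = [truth.subtype[s] for s in mrna.sample_ids]

raw = tt.hier_cluster(tt.pearson_distance(mrna.data), "ward", k=3)
print("raw clustering vs lineage ARI:   %.3f" % adjusted_rand_score(lineage, raw))
print("raw clustering vs subtype ARI:   %.3f" % adjusted_rand_score(subtype, raw))

norm = tt.center_within_lineage(mrna)
unmasked = tt.hier_cluster(tt.pearson_distance(norm.data), "ward", k=3)
print("normalized vs subtype ARI:       %.3f" % adjusted_rand_score(subtype, unmasked))

calls = tt.simulate_platform_calls(truth, n_platforms=5, call_flip_prob=0.1,
                                   missing_call_prob=0.2, seed=7)
res = tt.coca_cluster(tt.encode_indicators(calls), k=3,
                      params=tt.ClusterParams(k_min=3, k_max=3, iterations=250, seed=7))
named = tt.assign_subtype_names(res.labels)
true = [truth.subtype[s] for s in named.index]
print("COCA vs planted subtype ARI:     %.3f" % adjusted_rand_score(true, named))
print(named.value_counts().to_dict())
```

Output:

```
raw clustering vs lineage ARI:   1.000
raw clustering vs subtype ARI:   -0.011
normalized vs subtype ARI:       0.983
COCA vs planted subtype ARI:     0.967
{'c1': 61, 'c2': 60, 'c3': 59}
```

Clustering the raw matrix reproduces the three tissue lineages exactly
(ARI 1.0) and is blind to the planted subtypes (ARI ≈ 0); after
within-lineage normalization the same clustering recovers the cross-lineage
subtypes (ARI 0.98), and COCA reconciles five noisy platform-level call sets
into integrated subtypes that match the planted truth (ARI 0.97) with
near-equal subtype sizes, as planted.

The same stages are available from a shell via the `transtype` command
(`simulate`, `normalize`, `select`, `cluster`, `coca`, `characterize`,
`associate`, `classify`, and `run` for a seeded end-to-end pipeline from a
YAML config).

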