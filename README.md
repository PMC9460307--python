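# tdpatterns

Discovery and validation of **temporal dietary patterns (TDPs)** — clusters of
people who eat similar amounts of energy at similar times of day — from
event-level 24-hour dietary recall data, and assessment of how those patterns
relate to BMI and waist circumference (WC) under a complex survey design.

The package is aimed at nutrition epidemiologists working with recall data of
the NHANES type: one row per eating occasion (participant, clock time, kcal),
plus per-participant covariates, survey weights, strata and PSUs, and measured
anthropometry.

## What it implements

**Modified dynamic time warping (MDTW).** Two recalls are compared by
optimally aligning their eating-event sequences under the monotone DTW step
set and summing local costs

```
cost(a, b) = ((e_a − e_b)/s_E)² + β·((t_a − t_b)/s_T)²
```

where `e` is event energy, `t` event time, and β (default 40) penalises time
mismatches relative to energy mismatches so that, e.g., breakfast does not
align with a midnight snack. Defaults measure time in hours and energy in
100-kcal units.

**Kernel k-means.** The pairwise MDTW matrix is mapped to a Gaussian kernel
(median-heuristic bandwidth, optional PSD repair by diagonal shift) and
partitioned into K mutually exclusive clusters with the kernel trick; the
silhouette and Dunn indices computed on the original distances guide the
choice of K.

**Energy/time cut-off classifier.** A descriptive rule validated against the
data-driven clusters: all events < 800 kcal → cluster 1; otherwise the unique
maximum-energy event labels the participant by its time window
(05:00–15:00 → 4, 15:00–19:00 → 2, after 19:00 → 3; ties → 1).

**Overlap validation.** Cut-off and data-driven labelings are aligned by
optimal assignment on their crosstab; per-cluster overlap percentages, total
agreement and the adjusted Rand index quantify concurrence.

**Survey-weighted association models.** BMI and WC are regressed on cluster
membership adjusting for survey year, age group, sex, race/ethnicity, income
(PIR) category, and energy misreporting (intake over the IOM estimated energy
requirement). Variance is by stratum/PSU Taylor linearization with
leverage-adjusted residuals; cluster least-squares means and all pairwise
differences carry Tukey–Kramer adjusted p-values.

**Synthetic cohorts.** `tdpatterns.synthetic` generates full cohorts with
planted archetypes, covariates, survey design and outcome effects at three
separability levels, so the entire pipeline is testable without any data
download.

## Worked example

```python
import tdpatterns as tdp
from tdpatterns.synthetic import CohortConfig, generate_cohort, generate_separability_variants

cfg = generate_separability_variants(CohortConfig(n_participants=800, seed=3), "well_separated")
recalls, participants, truth = generate_cohort(cfg)

D = tdp.pairwise_distance_matrix(recalls)            # MDTW, β = 40
K = tdp.distance_to_kernel(D.values)
clusters = tdp.kernel_kmeans(K, k=4, seed=3)         # data-driven TDPs
cut_labels, _ = tdp.classify_cohort(recalls)         # cut-off TDPs

report = tdp.overlap_percentages(cut_labels, clusters.labels)
print({c: round(p, 1) for c, p in report.per_cluster_overlap_pct.items()})

participants["cluster"] = cut_labels
fit = tdp.fit_adjusted_model(participants, "bmi")
print(fit.pairwise[["cluster_a", "cluster_b", "estimate", "se", "p_adj"]].head(3))
```

Output:

```
{1: 99.7, 2: 100.0, 3: 100.0, 4: 100.0}
   cluster_a  cluster_b  estimate        se     p_adj
0          1          2 -3.880731  1.074022  0.012181
1          1          3 -5.125153  0.901737  0.000228
2          1          4 -4.071507  1.086471  0.009355
```

Nearly every cut-off cluster coincides with its matched data-driven cluster
on this well-separated cohort, and the adjusted models detect the planted
≈3 kg/m² BMI disadvantage of the single-peak patterns relative to the
three-moderate-meals pattern (the single-cohort estimates scatter around the
planted values within about two standard errors), with all three cluster-1
contrasts Tukey–Kramer significant.

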