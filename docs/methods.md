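# Methods

This note documents the models, conventions and numerical choices behind
`tdpatterns`, and what the synthetic-cohort experiments do and do not
demonstrate about real recall data.

## Recall representation

A 24-h recall is an ordered list of eating events, each a minute-of-day
`t ∈ [0, 1440)` and an energy `e > 0` kcal. Recall instruments report one row
per food, so items sharing a clock time are merged into one event by summing
energy before any analysis; this is the package's convention for forming
"eating events" (instruments do not define occasion grouping themselves).
When a recall is expanded to a 1440-minute series, each event spreads `e/15`
kcal/min over the half-open window `[t, t+15)` — occasion duration is not
recorded, so a fixed 15-minute occasion is assumed. Windows are truncated at
minute 1439 rather than wrapped: the recall describes a single day, and
wrapping would fabricate early-morning intake. Energy is therefore conserved
exactly unless an event starts after 23:45.

## MDTW distance

The distance between two recalls is the minimum, over monotone alignments in
which every event of either sequence matches at least one event of the other
(steps: diagonal, repeat-left, repeat-right), of the summed local costs

    cost(a, b) = ((e_a − e_b)/s_E)² + β ((t_a − t_b)/s_T)².

Parameters:

* **β = 40** (default) — the weight penalising time mismatches relative to
  energy mismatches. β = 0 ignores timing entirely; large β forbids, in
  effect, aligning morning with late-night intake.
* **s_T = 60 min, s_E = 100 kcal** — unit scales. These place typical
  squared energy differences (a few hundred kcal → Δe² of 1–10) and weighted
  squared time differences (an hour or two → βΔt² of 40–160) on comparable
  footing near β = 40, so the weight genuinely trades the two terms. The
  scales are configurable; distances are not comparable across scale choices.

No window constraint, step weights, or path-length normalisation is applied:
the quantity is a minimised weighted sum, and pathological matchings are
discouraged by β, not by a hard band. The measure is symmetric, nonnegative
and zero iff the scaled sequences coincide, but — like all DTW-type
measures — it can violate the triangle inequality, so nothing downstream
assumes metricity. The `pairwise_distance_matrix` engine evaluates the DP
row-vectorised over participants; it is cross-checked in the tests against
the plain per-pair DP and against exhaustive alignment enumeration.

## Kernel and clustering

The distance matrix D is mapped to a similarity kernel
`K_ij = exp(−d_ij²/(2σ²))` with σ the median off-diagonal distance (the
parameter-free median heuristic); a `gaussian` variant treats the MDTW value,
itself a sum of squares, as already squared. Because MDTW is not guaranteed
PSD-embeddable, the kernel's minimum eigenvalue is checked and, if negative,
|λ_min| + 1e−10 is added to the diagonal. The diagonal shift preserves all
off-diagonal structure and the kernel-trick algebra; eigenvalue clipping
would not.

Kernel k-means minimises Σ_c Σ_{i∈c} ‖φ(i) − μ_c‖² using only kernel sums.
Initialisation picks k distinct medoids at random and assigns points to the
nearest; 20 restarts by default (the algorithm is initialisation-sensitive),
best objective kept, fully deterministic given a seed. The recorded
per-iteration objective is nonincreasing within a run. An emptied cluster is
reseeded from the point farthest from its current centroid — a rare event
that is the one step not covered by the monotonicity argument.

Cluster-count selection reports silhouette and Dunn on the original
distances. Silhouette uses the standard (b − a)/max(a, b) with singleton
clusters contributing 0; Dunn is minimum between-cluster distance over
maximum within-cluster diameter and is reported as NaN when all diameters
are zero (duplicated points). Both are validated against definition-level
brute-force computation on all small labelings.

## Cut-off classification

The descriptive rule: (1) every merged event < 800 kcal → cluster 1;
(2) otherwise, a unique maximum-energy event labels the participant by its
window — [05:00, 15:00) → 4, [15:00, 19:00) → 2, 19:00 onward → 3;
(3) a tied maximum → cluster 1. Two corners are genuinely ambiguous and are
config-exposed rather than silently fixed:

* **Threshold boundary** — the rule is stated both as "no more than" and
  "less than" 800 kcal; the operative strict reading is the default (an
  event of exactly 800 kcal leaves cluster 1), with an inclusive option.
* **Pre-05:00 maxima** — unaddressed by the published windows; assigned to
  cluster 3 as the overnight continuation of late-night eating.

Window edges are half-open with 05:00 → 4, 15:00 → 2, 19:00 → 3 exactly.
Energy ties are compared with exact float equality after merging: recall
energies are sums of coded food energies, so exact ties are meaningful and
no epsilon is warranted.

## Overlap validation

Cluster labels from the two methods are nominal, so they are aligned by the
bijection maximising the matched count (optimal assignment on the crosstab;
ties broken lexicographically by source label). Per-cluster overlap divides
matched counts by the **cut-off** cluster size by default; the transposed
convention is available because the verbal definition of "percent overlap"
does not determine the denominator. Total agreement is the size-weighted
mean of per-cluster overlaps; the adjusted Rand index is attached as a
symmetric diagnostic.

## Association models

Outcomes (BMI kg/m², WC cm) are fit by weighted least squares on cluster
dummies, categorical covariates (survey cycle, age group, sex,
race/ethnicity, PIR category) and the continuous misreporting ratio EI/EER.
EER uses the IOM adult equations (PA = 1.0, sedentary, since recalls carry
no activity measure); misreporting enters continuously as the simplest
faithful reading of an "energy misreporting" confounder.

Design-based variance is Taylor linearization: per-PSU totals of the
estimating scores `w_i x_i e_i`, centred within stratum, with the
with-replacement first-stage approximation and design df = #PSUs − #strata.
Two small-sample conventions matter:

* **Leverage-adjusted residuals (default `hc3`).** Fitted residuals are
  shrunk by their own leverage, which biases the raw linearized variance low
  — noticeably so when weights are variable or a covariate (here,
  misreporting) is strongly collinear with cluster membership. Dividing each
  residual by (1 − h_ii) approximates the delete-one jackknife and restores
  near-nominal calibration; `hc2` and `none` are available.
* **Lonely PSUs** are an error by default; `lonely_psu="center"` computes
  that stratum's deviation from the grand mean instead.

Least-squares means evaluate the fit at the weighted covariate means, so
cluster differences equal the corresponding coefficient contrasts. All
pairwise differences receive Tukey–Kramer adjusted p-values,
`p = P(Q_{k, df} ≥ √2 |Δ|/SE)` with Q the studentized range on the design
df; with two groups this reduces exactly to the two-sided t-test. Multiplying
all weights by a constant changes neither coefficients nor SEs.

## Synthetic cohorts

The generator plants the structure the analysis is designed to find:

* **Archetype 1** (mixing weight 0.481): three occasions near 08:00, 13:00,
  18:00, energies Normal(500, 100) truncated to (50, 799) — every event
  strictly under the 800-kcal cut-off.
* **Archetypes 2/3/4** (0.178/0.168/0.173): one dominant occasion,
  Normal(1500, 300) truncated to (801, 4000), timed within the afternoon
  [15:00, 19:00), night [19:00, 24:00) and midday [05:00, 15:00) windows
  (centres 18:00, 20:00, 13:00), plus 1–2 minor occasions under 500 kcal.
  Construction guarantees a unique dominant event inside the window.

Mixing weights and outcome anchors (BMI baseline 29.1, WC 97.7; single-peak
archetype shifts +3.0/+3.3/+3.3 kg/m² and +7.4/+8.2/+8.2 cm) reproduce the
effect magnitudes the pipeline should detect. Within-archetype dispersions
are package choices — no published dispersion exists to copy — exposed
through three separability regimes: `well_separated` (time SD 25 min, fixed
three events, dominant ≥ 2× any minor), `moderate` (time SD 60 min, 2–3
events) and `overlapping` (time SD 150 min, energies blurring the 800-kcal
boundary). Event-count variability is treated as part of dispersion: an
unmatched extra occasion costs as much under MDTW as a between-archetype
peak shift, so the well-separated regime pins the count.

Covariates follow plausible US-adult marginal frequencies; the survey design
is 15 strata × 2 PSUs with round-robin assignment (guaranteeing no lonely
PSUs) and lognormal weights normalised to sum to n. Outcomes are drawn from
the additive linear model directly. Body weight and height are drawn
independently of the BMI outcome and used only for EER: deriving weight from
the simulated BMI would make misreporting a descendant of the outcome noise,
and adjusting for it would then bias the planted cluster contrasts — a
collider structure absent from the measurement process being emulated.

**What passing tests show — and don't.** Synthetic cohorts have clean
archetypes, no measurement error in times or energies, no correlation
between covariates and eating patterns, and outcome noise that is exactly
Gaussian and homoskedastic. Recovery and overlap results therefore
demonstrate the correctness and calibration of the machinery, not the
separability of patterns in any real population; published index values and
overlap percentages for survey microdata are not reproducible from synthetic
cohorts and are not asserted anywhere.

## Problem sizes

The verification experiments use cohorts of n = 2000 (pipeline, overlap and
planted-effect recovery, 10 seeds), n = 400 planted-block kernels for
clustering recovery, and 500 null replicates of n = 500 for family-wise
error calibration — sizes at which every Monte-Carlo criterion is stable
across seed batches while the full suite runs in a couple of minutes.

## Known limitations

* MDTW scaling (hours, 100-kcal units) is a package convention; other unit
  choices change distances and possibly cluster boundaries.
* Kernel bandwidth σ has no published counterpart; the median heuristic is a
  default, not a tuned value.
* The cut-off rule's pre-05:00 and exact-800 conventions are package
  decisions on genuinely ambiguous cases (both configurable).
* Survey inference assumes with-replacement first-stage sampling and many
  PSUs per stratum would be needed for exact studentized-range calibration;
  the HC3 adjustment is an approximation, calibrated here only under the
  synthetic design.
* β is exposed as configuration; no automatic tuning of β against health
  outcomes is attempted.
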