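# Methods

This note documents the models, defaults and numerical choices behind
`hfclust`, and what the synthetic study conditions do and do not establish
about real cohorts.

## Synthetic cohort model

The generator emulates a multimorbid heart-failure cohort at the level of
structure, not of any specific hospital's statistics.

**Comorbidities.** Each patient belongs to one of K latent clusters (default
K = 4, mixing 0.21/0.23/0.33/0.23). Binary flags for 11 tracked diseases
(ICM, CM, HT, Diabetes, AF, TIA, VD, CKD, Anaemia, COPD, Obesity) are drawn
from a Gaussian copula per cluster: a latent multivariate normal with unit
diagonal correlation R_c is thresholded at each disease's marginal quantile,
giving exact Bernoulli marginals with controllable pairwise co-occurrence.
The default R_c is exchangeable with ρ = 0.03; ρ is the lever for
disease-network co-occurrence structure beyond what the marginals imply.

**Default archetypes.** The four default prevalence vectors follow the
qualitative pattern of published HF subgroups — a high-burden cardio-renal
cluster (CKD/Anaemia/HT/ICM), an HT/AF/Obesity cluster, an anaemia-dominant
cluster, and a low-burden cluster — with deliberately strong separation:
pairwise prevalence contrasts on the discriminating diseases are ≥ 0.6 (most
0.8-0.9) and key laboratory means shift ≥ 2 within-cluster sd (NT-proBNP,
haemoglobin, urea, creatinine, age). Two deliberate design constraints
shaped the exact numbers:

1. *Recoverability.* The separation level is a precondition for the
   advertised planted-structure recovery (Gower + Ward ARI ≥ 0.8); weaker,
   more literally "realistic" archetypes overlap enough that no equal-weight
   mixed-type clustering can recover them reliably.
2. *Equidistance.* The archetypes are roughly equidistant in both the Gower
   geometry and the scaled-Euclidean geometry used by the centroid-based
   indices. When one cluster is a lone outlier (e.g. a single dominant
   high-burden group), all three validity indices prefer k = 2 — the
   top-level dendrogram split — and the majority vote can never choose k = 4.
   Real cohorts frequently have exactly this pathology, which is why the
   size floor and clinical judgement matter in practice; the synthetic
   default is constructed so the vote itself is decisive.

**Labs and demographics.** Labs are cluster-shifted normals with MCAR
missingness at 10-40% per lab (NT-proBNP highest at 35%); an optional MAR
switch makes the missingness probability logistic in standardised age,
rescaled to preserve the average rate. Age is normal per cluster (clipped to
18-105); gender is Bernoulli (female = 1).

**Events.** First unplanned-admission times per outcome (hospitalisation,
emergency) are exponential with rate `baseline_rate × hazard_multiplier[c]`
(defaults 0.12/y and 0.35/y; multipliers 4.0/2.5/2.0/1.0 and
2.6/2.0/1.3/1.0). Constant hazards make proportional hazards hold exactly,
so Cox hazard-ratio recovery is a well-posed check. Patients whose first
event exceeds the censoring horizon (default 5 years after diagnosis)
produce no event row. Each patient carries an `observation_end` column
(diagnosis + horizon); the survival builder accepts either this per-patient
series or one administrative censor date.

**Prescriptions.** Per pharmacological group, per-patient counts are Poisson
with cluster multipliers (2.2/1.6/1.0/0.7) so the high-burden cluster shows
the highest utilisation of every group; drug identifiers are concrete
exemplars (e.g. "furosemide") resolved through the editable
`data/drug_groups.csv` map.

**What the generator does not emulate:** longitudinal lab trajectories,
informative (MNAR) missingness, disease-onset ordering, recurrent events,
competing mortality, coding noise. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under a known model, not
performance on real EHR extracts.

## Preprocessing

* Cohort identification: a patient qualifies if any diagnosis record's
  ICD-9 code, dots stripped, starts with one of the HF prefixes (428,
  398.91, 402.x1, 404.x1/x3, 425.4-425.9) or its free text contains an HF
  keyword. Keyword matching is case- and diacritic-insensitive and
  word-bounded — bare substring matching of the abbreviation "IC" would fire
  inside ordinary Portuguese words (e.g. *microcitose*).
* Aggregation: labs/BMI are averaged over all observations; age is taken at
  the final observation; comorbidity flags are ever-present by default, with
  a last-year window option.
* Filters, in order and both strict: binary features with prevalence < 2%
  are dropped, then any feature with missingness > 40%; features exactly at
  a boundary are kept. Every drop is recorded in an audit table.
* Imputation: chained equations with linear ridge regressors
  (α = 10⁻⁵, 10 sweeps, stop when the largest change < 10⁻³). Observed
  cells are restored bit-identically after fitting. A column that is
  entirely missing is an error (it should have been filtered), as is a
  zero-variance continuous column at scaling time — degenerate inputs fail
  loudly rather than silently.
* Scaling: continuous columns are z-scored with the population sd; binary
  columns map {0,1} → {−0.5, +0.5}.

## Clustering pathways

* **Gower** is computed on the aggregated, imputed but *unscaled* features:
  the per-feature range normalisation inside the formula makes prior
  z-scoring redundant. Binary features are treated as categorical
  (match/mismatch). Zero feature range or all-zero weights are errors.
* **Ward on Gower** feeds the distance matrix directly into the
  Lance-Williams recursion. Ward's variance objective is exact only for
  Euclidean distances; Gower is of negative type but not Euclidean, so this
  pairing is a pragmatic heuristic. A square-root transform (which makes the
  metric Euclidean-embeddable) was evaluated and gave no consistent recovery
  gain, so the raw distances are used.
* **FAMD** z-scores quantitative columns, divides each categorical level
  indicator by √(level proportion) and centres it, then truncates the SVD.
  With only quantitative columns this is exactly PCA; with only qualitative
  columns the row coordinates are proportional to MCA's. Components kept:
  smallest number explaining ≥ 80% of inertia (flag-overridable). Component
  signs follow the largest-loading-positive convention.
* **K-means** uses k-means++ with 10 restarts, 300 iterations, seeded.

## Model selection

Silhouette is computed on each pathway's native representation (the Gower
matrix, or Euclidean embedding distances). Calinski-Harabasz and
Davies-Bouldin require centroids, which a raw distance matrix does not
define; for the Gower pathway they are computed on the scaled feature matrix.
This is a genuine design choice — the alternative (silhouette-only voting)
would abandon the three-index vote.

Admissibility: every cluster must exceed max(375, 10% of n) patients (an
absolute count or a fraction can be supplied). Per index the best admissible
row wins (ties break toward smaller k, then method name, making the vote
row-order invariant); two of three indices decide. A three-way split raises
an error carrying the tally — the package never resolves a tie silently; a
`prefer_k` override exists for judgement calls outside the formal vote.

## Disease networks

Edge weight is the fraction of subset patients with both diseases, computed
against the subset's own denominator (the cluster for per-cluster networks,
the cohort for the global network). The "below 2% discarded" rule is strict,
so a weight of exactly 0.02 is retained. Zero-prevalence diseases are
omitted as nodes. The clustering coefficient is computed on the unweighted
retained-edge topology (nodes with fewer than two neighbours contribute 0);
weights affect only export and visualisation. Networks export to GraphML
plus node/edge CSVs and round-trip losslessly through the package's reader.

## Profiles

Continuous characteristics are reported as median (IQR) with
linear-interpolation (type-7) quantiles; binary ones as percentages.
Chi-square tests are Pearson without continuity correction; Kruskal-Wallis
is tie-corrected. Significance is per-row at 0.05 with no multiplicity
correction by default (a Benjamini-Hochberg switch exists). Prescription
prevalence is at-least-one-prescription per group; prescriptions/year is the
mean of per-patient rates (not pooled counts). Person-years for admission
rates run from HF diagnosis to the end of observation. Events dated before
diagnosis are excluded with a warning.

## Survival

Durations run from HF diagnosis to the first qualifying event, else to the
censor date; same-day events are floored at one day to keep durations
positive. Kaplan-Meier estimation, Greenwood-based confidence bands, the
K-group log-rank test and Cox fits are delegated to lifelines; Cox tie
handling is Efron. The reference cluster is the one with the lowest observed
event percentage, resolved per outcome (a log message notes when outcomes
disagree). Covariates that are identically constant are dropped with a
warning rather than fitted. Model 1 uses cluster indicators only; Model 2
adds age and gender (female = 1); Model 3 adds NT-proBNP.

## Problem sizes and reproducibility

Default study conditions: n = 2000 patients, k ∈ [2, 12], 20 seeded
replicates for selection-stability checks, 200 replicates for log-rank
type-I calibration, n = 5000 for marginal-calibration checks. One global
seed derives fixed per-stage seeds, so any stage rerun in isolation sees the
randomness of a full run; identical config + seed reproduces byte-identical
CSVs and manifest digests.

## Known limitations

* Ward-on-Gower lacks the Euclidean geometry its objective assumes (above).
* The centroid-based indices score a different representation than the
  Gower pathway clusters, so their votes are not perfectly aligned with the
  clustered geometry.
* MCAR/MAR missingness only; imputation quality under MNAR is untested.
* The synthetic separation level is favourable by construction; real-cohort
  performance of the full pipeline depends on signal strength that cannot be
  asserted from these tests.
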