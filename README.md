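# hfclust

Multimorbidity subgroup discovery in heart-failure (HF) cohorts from
EHR-like tabular data: mixed-type preprocessing, Gower/FAMD clustering with
majority-vote model selection, phenotypic disease networks (PDNs), per-cluster
clinical profiling, and survival stratification by unplanned hospital
admissions.

HF patients rarely suffer from HF alone — hypertension, atrial fibrillation,
chronic kidney disease, anaemia and other chronic conditions co-occur in
patterns that shape prognosis. `hfclust` implements a complete workflow for
finding such subgroups in a patient-level table of demographics, binary
comorbidity flags, laboratory values (with missingness), prescriptions and
admission dates, and for characterising each subgroup clinically and
prognostically. Because real hospital EHR extracts are access-restricted, the
package ships a first-class synthetic-cohort generator with planted cluster
structure, so every stage runs, and can be validated, end to end.

## The method

**Mixed-type distance.** Patients mix continuous labs with binary
comorbidities. The Gower dissimilarity between patients *x* and *y* over *m*
features is

d_G(x, y) = Σⱼ wⱼ·fⱼ(xⱼ, yⱼ) / Σⱼ wⱼ,
  fⱼ = |xⱼ − yⱼ| / rⱼ  (interval features, rⱼ = cohort range),
  fⱼ = 1[xⱼ ≠ yⱼ]   (categorical features),

with unit weights wⱼ = 1, so d_G ∈ [0, 1]. Three clustering pathways are
provided: Ward agglomeration on the Gower matrix, and Ward or K-means on a
factor-analysis-of-mixed-data (FAMD) embedding (PCA on quantitative columns,
MCA-style scaling of qualitative indicators).

**Model selection.** Every (pathway, k) candidate for k ∈ [2, 12] is scored
with the Silhouette score, Calinski-Harabasz index and Davies-Bouldin index;
configurations whose smallest cluster does not exceed a stability floor
(default max(375, 10% of n)) are inadmissible; the configuration winning at
least two of the three indices is selected.

**Phenotypic disease networks.** Per cluster, diseases are nodes and an edge
joins two diseases with weight equal to their co-occurrence prevalence in the
cluster; edges below 2% are discarded. Average degree and the average
clustering coefficient summarise multimorbidity complexity — a cluster where
all 11 tracked comorbidities pairwise co-occur yields the complete graph:
55 edges, average degree 10, clustering coefficient 1.

**Profiles and survival.** Clusters are compared with chi-square (binary) and
Kruskal-Wallis (continuous) tests at p < 0.05, plus prescription-group and
admission summaries. Time from HF diagnosis to first hospitalisation or
emergency admission is analysed with Kaplan-Meier curves, the K-group
log-rank test, and three nested Cox models (unadjusted; + age, gender;
+ NT-proBNP), with hazard ratios against the lowest-risk cluster.

## Worked example

Run the whole pipeline on the default synthetic four-cluster cohort
(n = 2000):

```bash
hfclust run-all --out-dir demo --seed 1
```

`demo/chosen.json` records the majority-vote winner — all three indices agree
on k = 4:

```json
{"method": "famd_kmeans", "k": 4,
 "winners": {"silhouette": ["gower_ward", 4],
             "calinski_harabasz": ["famd_kmeans", 4],
             "davies_bouldin": ["famd_kmeans", 4]}}
```

`demo/network_metrics.csv` contrasts the clusters' comorbidity networks: the
high-burden cluster is near-complete (49 of 55 possible edges, average degree
8.9, clustering coefficient 0.92), while the low-burden cluster retains no
edge above the 2% co-occurrence rule:

```
subset,n_patients,nodes,edges,average_degree,average_clustering
cohort,2000,11,54,9.82,0.98
cluster2,461,11,0,0.00,0.00
cluster3,437,11,49,8.91,0.92
```

`demo/cox_hospitalisation.csv` quantifies prognosis: relative to the
lowest-risk cluster, the high-burden cluster's unadjusted hospitalisation
hazard ratio is 3.90 (95% CI 3.30-4.61), and the log-rank test across
clusters gives χ² = 289.7, p < 10⁻⁶⁰ — the planted cluster-dependent hazards
are recovered.

Every stage can also be run individually (`simulate`, `preprocess`,
`cluster`, `select`, `network`, `profile`, `survival`) from the previous
stage's on-disk outputs; `manifest.json` records seeds, versions and artifact
digests for reproducibility. The same functionality is available as a
library (`import hfclust`).

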