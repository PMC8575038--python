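# Methods

## Scope and model

`subtypebench` benchmarks patient-stratification workflows on bulk
expression cohorts. Two feature-space families feed a shared
clustering and evaluation layer: data-driven embeddings (PCA, t-SNE,
UMAP) and a knowledge-driven pathway embedding built from network
diffusion and gene set enrichment. Everything downstream —
clustering, the five evaluation criteria, aggregation and Pareto
selection — treats the two families identically, so their merits can
be compared on equal terms.

## The RWR-FGSEA feature extractor

Per patient, the extractor proceeds in four steps.

1. **Seed selection.** Disease gene lists are supplied split by
   fold-change sign. Genes are z-scored across samples and, per
   sample, the `top_n` (default 50) up-list genes with the highest z
   and `top_n` down-list genes with the lowest z become seeds. The
   z-score (rather than raw within-sample expression) is used because
   raw ranking would be dominated by constitutively abundant genes
   rather than patient-specific dysregulation; ties break by
   lexicographic gene ID so the selection is deterministic.
2. **Random walk with restart.** Affinities solve
   `p = (1−r) W p + r p0` with restart `r = 0.75`, `p0` uniform over
   the seeds, and `W` the symmetrically normalized adjacency
   `D^{-1/2} A D^{-1/2}` of the network's largest connected component
   (a row-stochastic transition operator is available; it conserves
   total probability exactly). The fixed point is found by iteration
   to an L1 tolerance of 1e-10 (cap 10⁴ iterations); with `r = 0.75`
   the map contracts by 0.25 per step, so a few dozen iterations
   suffice and the iterate matches a dense linear solve to 1e-8.
3. **Pre-ranked GSEA.** The affinity vector itself (not its rank) is
   the ranking statistic. The running sum gains
   `|score|^w / Σ_set |score|^w` (default exponent `w = 1`) at set
   members and loses `1/(N − |set|)` elsewhere; ES is the signed
   maximum deviation. The null is built from gene-label permutations
   (default 1000), shared across samples via one precomputed
   permutation matrix — the null depends only on set size and the
   score vector, and sharing permutations is standard practice that
   makes whole-cohort extraction roughly 50× cheaper. NES divides ES
   by the mean |null ES| of matching sign; p is the one-sided
   permutation tail `(1 + #more extreme) / (1 + #matching sign)`. Sets
   outside [5, 500] members after filtering are skipped.
4. **Embedding assembly.** The default adjusted score is
   `NES · (−log10 p)`, which preserves the enrichment direction and
   vanishes for unenriched pathways (p ≈ 1), giving the sparse
   feature matrix; the literal `NES · ln p` variant (which flips the
   sign) is selectable. Up- and down-seeded runs are computed
   separately and combined as up-score minus down-score, so positive
   features follow up-regulated disease biology. Entries above an
   optional significance floor can be zeroed; by default no floor is
   applied.

Numerical detail: when both running-sum deviations are exact multiples
of the miss decrement the positive and negative extremes can tie
structurally; the positive deviation wins, with a 1e-12 tolerance so
float accumulation order cannot flip the choice.

## Co-expression modules and the module score

The module machinery follows the WGCNA recipe on Spearman
correlations: adjacency is either hard (`|ρ| ≥ τ`, unweighted; the
benchmark config exposes 0.475 and 0.525 as reference thresholds) or
soft (`|ρ|^β`, default power 6, alternative 4). Thresholds and powers
are tuned by the scale-free topology criterion: log10 p(k) is
regressed on log10 k over 10 logarithmic connectivity bins, a
negative slope reports R², a positive slope reports 0, and the
smallest grid value reaching the target R² (default 0.8) wins; if
none does, the argmax is returned with a warning flag.

Topological overlap is
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`, and
modules come from average-linkage clustering of `1 − TOM` with a
static cut at a fraction of the maximum merge height, followed by
dropping clusters below `min_module_size` (default 10, relabelled 0 =
unassigned) and renumbering by decreasing size. The static cut (in
place of dynamic tree cutting) keeps detection deterministic and
dependency-free; its default height is 0.9 because with `1 − TOM`
dissimilarities between-module merges concentrate in the top 1–2% of
the dendrogram — on planted-partition networks (p_in 0.9, p_out 0.02,
four 25-gene modules) a 0.9 cut recovers the partition with ARI 1.0
across seeds, whereas cutting at 0.99 of the root height merges
modules.

Each module is summarized by its eigen-gene: the unit-norm first left
singular vector of the gene-standardized samples × genes submatrix,
sign-aligned to correlate non-negatively with the module's mean
profile, with the first eigenvalue's share reported as explained
variance.

The module relevance of a clustering is
`E[(min(1,S⁺)+min(1,S⁻)) / (S⁺+S⁻)]` over modules, where `S±` counts
clusters whose one-hot indicator has Spearman correlation ≥ α
(respectively ≤ −α) with the eigen-gene; a module associated with no
cluster contributes the fallback β. Defaults α = 0.5 (operationalizing
"strongly correlated"; reported in output metadata) and β = 0, which
penalizes clusterings that ignore a module. The expectation is an
unweighted mean over modules.

## Clustering layer

Correlation distance `d = 1 − cor(x, y)` is the convention for
pathway-feature spaces; Euclidean geometry for data-driven embeddings
(overridable per clusterer). DIANA is implemented in full
(Kaufman–Rousseeuw): repeatedly split the largest-diameter cluster by
seeding a splinter group with the object of maximal average
dissimilarity and moving objects whose average dissimilarity to the
splinter group is lower than to the remainder (largest positive
difference first); k clusters are materialized after k − 1 splits,
equivalent to cutting the divisive banner at the k-cluster level. All
ties break by lowest sample index, so labels are bit-identical across
runs. k-means uses 100 k-means++ restarts; the Gaussian mixture uses
full covariances with `reg_covar = 1e-6` and a mean-shrinkage prior of
strength 0.01 toward the global mean (applied in the M-step as a MAP
update), mirroring the common mclust regularization; agglomerative
trees (average, complete, Ward) are cut at k. Labels are canonicalized
by first occurrence and every result must use all k labels (empty
clusters trigger up to five reseeded refits).

## Evaluation protocol

* **Silhouette** on the workflow's own dissimilarity; singleton
  clusters and coincident points contribute 0.
* **NMI** with square-root normalization (`I/√(H·H')`; 0 when either
  entropy is 0), **ARI** with the permutation-model adjustment.
* **cNMI** = NMI(clusters, subtype) − NMI(clusters, batch), the plain
  difference; missing reference labels are dropped pairwise.
* **Stability**: the pipeline (feature extraction included) is rerun
  on the retained 4/5 of each fold across 20 repeats of shuffled
  5-fold CV (100 resamples) and compared to the full-data reference
  restricted to the retained samples via co-clustering Jaccard and
  ARI. Failures are recorded as missing; more than 50% failing aborts.
* **Survival**: likelihood-ratio χ² between a covariate-only Cox
  proportional-hazards model and one adding k − 1 cluster indicators
  (df = k − 1), hazard ratios reported against the first cluster.
  Covariates are config inputs; an optional follow-up cap excludes
  long-followup outliers. Singular designs (e.g. cluster indicators
  collinear with a covariate) are refit with a 1e-8 ridge so the test
  degrades to its correct ≈0 statistic instead of failing.
* **Informative pathways**: per-pathway Kruskal–Wallis across
  clusters with Benjamini–Hochberg correction; constant rows are
  skipped and recorded.

Aggregation takes means and SDs per combination, except survival
p-values, which aggregate as the median of −log10 p (a monotone
transform that makes the criterion commensurable with the others
after scaling). Best-by-sum min-max scales each selected criterion to
[0, 1] across combinations, flips minimized ones (batch NMI enters
effectively as 1 − NMI), sums, and picks the best clusterer per
feature space averaged over k, breaking ties by stability, then
silhouette, then name. The Pareto front contains the combinations not
dominated (≥ on all criteria, > on one) after direction alignment.

All grid seeds derive from the master seed through indexed
`SeedSequence` streams (component, embedding, clusterer, k, resample),
so a run is bit-reproducible while stochastic embedders stay pinned
per combination.

## Synthetic cohort generator

Expression follows a module latent-factor model: each of `n_modules`
(default 6) modules has one latent activity per sample
(`f ~ N(0,1)`); genes load on their module with positive weights
`U(0.5, 1.5)`; 80% of genes belong to modules, the rest are noise.
Modules are partitioned among the `k_subtypes` (default 3) subtypes
and each subtype shifts its block's activities by ±`subtype_effect`
(default 4 SD) with alternating signs, so every subtype carries a
distinct multi-module signature — the realistic situation for cancer
subtypes, and the design under which the disease gene lists (the
genes of positively / negatively shifted modules, emulating a
DEG-by-disease-association intersection) are informative for every
subtype. Batch variables add a batch-level constant (scaled by
`batch_effect`, default 1 SD) to a random half of the genes;
i.i.d. Gaussian noise (default SD 1) is added everywhere. Subtype and
batch labels are balanced to within one sample. Survival is
exponential with per-subtype hazard ratios (default `3^(t/(k−1))`,
i.e. 1…3) on a baseline of 10⁻³ events/day with independent
exponential censoring at 5·10⁻⁴/day (≈ 25–33% censoring, a typical
cohort rate). Cohort defaults (200 genes × 120 samples) keep a full
benchmark grid in minutes on one CPU while leaving all recovery
properties comfortably testable.

Knowledge inputs are aligned with the truth: gene sets draw ≥ 80% of
their members from one module (modules cycled; the rest uniform
random), and the network is a planted-partition graph (within-module
edge probability `p_in` = 0.9, between `p_out` = 0.02).

All randomness flows through named integer-tagged `SeedSequence`
streams, so outputs are identical across platforms given a seed.

What the generator does **not** emulate: count-level technical noise
and library-size effects (inputs are already log-scale), heavy-tailed
or non-Gaussian expression, overlapping or hierarchically nested
modules, unbalanced subtype prevalences, covariate-dependent hazards,
informative censoring, and missing clinical data. Tests passing on
these cohorts therefore demonstrate correctness of the algorithms and
the recoverability of clean planted structure — not performance on
real tumor cohorts, where signal-to-noise is far lower and module
structure murkier.

## Problem sizes used by the test suite

Unit tests run on small fixtures (tens of genes/samples; brute-force
oracles up to n = 50). The end-to-end recovery check uses 100 default
cohorts (200 genes × 120 samples); survival calibration uses 400
null cohorts of n = 300 and 100 powered ones; the acceptance script
runs one default cohort through both workflows plus a 12-combination
benchmark grid with 10 stability resamples per combination. These
sizes were chosen so the full suite and the script each complete in a
few minutes on a single CPU.

## Known limitations

* GSVA/DiffRank-style per-sample enrichment scorers are not
  implemented; external scores can be injected as a
  `PathwayEmbedding`.
* FGSEA's adaptive multilevel p-value refinement is not implemented;
  plain permutation p-values bound significance at `1/(n_perm+1)`.
* Module detection uses a static cut, not dynamic tree cutting, and
  no module merging by eigen-gene correlation.
* The VAE embedding family and signed co-expression networks are out
  of scope; the adapter contract admits them later.
* Proportional-hazards diagnostics are reported but never gate
  results.
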