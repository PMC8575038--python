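# subtypebench

Benchmarking framework for molecular disease-subtype discovery from
bulk transcriptomics. It implements and compares two families of
patient-stratification workflows on the same footing:

* **DR-CL** (data-driven): reduce the expression matrix with
  PCA/t-SNE/UMAP and cluster the embedding with Euclidean-geometry
  methods (k-means, Gaussian mixtures, Ward).
* **BK-CL** (biological-knowledge-driven): turn each patient's profile
  into pathway activities via network diffusion and enrichment, then
  cluster with correlation-distance methods (DIANA, agglomerative HC).

The core of the BK-CL workflow is an **RWR-FGSEA** feature extractor.
For each patient, disease gene lists split by fold-change sign are
ranked by per-gene z-score and the top *n* (default 50) genes seed a
random walk with restart on a gene network,

```
p_{t+1} = (1 − r) W p_t + r p_0,      r = 0.75,
```

with `W` the symmetrically normalized adjacency `D^{-1/2} A D^{-1/2}`.
The stationary affinity vector is scored against a gene set collection
with pre-ranked GSEA (weighted Kolmogorov–Smirnov running sum;
permutation null), and each pathway enters the embedding as the
adjusted score `NES · (−log10 p)` — sparse because unenriched pathways
(p ≈ 1) score ≈ 0. Up- and down-seeded walks run separately; the down
run enters with flipped sign so positive values track up-regulated
biology.

Every (feature space × clusterer × k) combination is evaluated on five
criteria:

1. **separability** — average silhouette width;
2. **stability** — co-clustering Jaccard/ARI between the full-data
   clustering and reruns on 20 repeats of 5-fold cross-validation
   subsets;
3. **batch-aware concordance** — NMI against known subtypes, NMI
   against batch variables, and their difference (cNMI);
4. **gene-module relevance** — WGCNA-style modules (soft-thresholded
   Spearman network → TOM → average-linkage clustering → eigen-genes)
   scored by `E[(min(1,S⁺) + min(1,S⁻)) / (S⁺ + S⁻)]`, where `S±`
   counts clusters whose indicator correlates with a module eigen-gene
   beyond ±α;
5. **clinical relevance** — likelihood-ratio χ² test (df = k−1) of
   cluster membership added to a covariate-only Cox proportional-
   hazards model.

Model selection reports the best clusterer per feature space by the
min-max-scaled sum of criteria and the first Pareto frontier of
non-dominated combinations.

A seeded synthetic-cohort generator (`simulate_cohort`,
`simulate_knowledge`, `simulate_survival`) plants subtypes, correlated
gene modules, batch effects, module-aligned gene sets and networks,
and cluster-dependent survival, so the whole framework runs end to end
without any external data.

## Worked example

```bash
python examples/02_rwr_fgsea_embedding.py
```

```
pathway embedding: 15 pathways x 120 samples
first sample's top pathway scores (NES * -log10 p, signed by direction):
pathway
SET002    2.88
SET014    1.31
SET004    0.53
SET008    0.49
Name: s0000, dtype: float64

DIANA k=3 on correlation distance:
  NMI vs planted subtypes: 1.000   (1.0 = perfect recovery)
  average silhouette:      0.904   (cluster compactness, in [-1, 1])
  informative pathways:    14 of 15 (BH-adjusted Kruskal-Wallis p < 0.05)
```

The per-sample pathway scores are positive where up-regulated disease
biology is enriched along the network around that patient's seed genes
and negative for down-regulated biology; clustering those profiles
recovers the three planted subtypes exactly (NMI 1.0), and 14 of the
15 pathways differ significantly between the resulting clusters.

The other examples cover cohort simulation (`01`), module detection
and the module score (`03`), and the full benchmark grid with Pareto
selection (`04`). The same functionality is exposed on the command
line via `subtype-bench simulate|run|rwr-fgsea|score-modules`.

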