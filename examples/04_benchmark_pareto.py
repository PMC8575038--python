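"""Run the benchmark grid and select models on the Pareto frontier.

Compares a data-driven feature space (PCA) with the knowledge-driven
RWR-FGSEA embedding across clusterers and cluster counts, evaluating
every combination on separability, stability, batch association,
module relevance and survival relevance, then reports the best
combination per feature space (scaled criteria sum) and the first
Pareto frontier.
"""

import warnings

import subtypebench as sb

expr, clinical, truth = sb.simulate_cohort(seed=1)
sets, net = sb.simulate_knowledge(truth, seed=1)
spec = sb.SeedSpec(truth.up_genes, truth.down_genes)

config = sb.BenchmarkConfig(
    embeddings=[{"method": "pca", "n_dims": 2}, {"method": "rwr_fgsea"}],
    clusterers=[{"method": "kmeans"}, {"method": "diana"}],
    k_values=[2, 3, 4],
    seed=1,
    stability_folds=5,
    stability_repeats=2,  # 10 resamples per combination keeps this quick
    survival_covariates=["age"],
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table = sb.run_benchmark(config, expr, clinical, knowledge=(sets, net, spec))

aggregated = sb.aggregate_metrics(table)
matrix = sb.aggregated_matrix(aggregated)
print("criteria means per combination (rows = embedding/clusterer/k):")
cols = ["silhouette", "stability_jaccard", "nmi_batch", "module_score",
        "survival_neglog10p"]
print(matrix[cols].round(3).to_string())

best = sb.best_by_sum(aggregated)
print("\nbest clusterer per feature space (min-max scaled criteria sum):")
print(best.to_string(index=False))

front = sb.pareto_front(matrix, table.directions)
print(f"\nfirst Pareto frontier ({len(front.indices)} of {matrix.shape[0]} "
      "combinations are non-dominated):")
for e, c, k in front.indices:
    print(f"  {e} + {c} at k={k}")
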