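"""Benchmark orchestration: the grid, aggregation and model selection.

Runs every configured (feature space x clusterer x k) combination,
records the five evaluation criteria (separability, stability,
batch-aware concordance, module relevance, survival relevance) in a
long-format table, aggregates over resamples, picks a best combination
per feature space by the min-max-scaled sum of criteria, and computes
the first Pareto frontier over all combinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    METRIC_COLUMNS,
    BenchmarkConfig,
    ClinicalTable,
    ExpressionMatrix,
    GeneNetwork,
    GeneSetCollection,
)
from .errors import ConfigError
from .embed import Embedding, reduce_dimensionality
from .rwr_fgsea import PathwayEmbedding, SeedSpec, rwr_fgsea_embedding
from .clusterers import (
    correlation_dissimilarity,
    diana_cluster,
    euclidean_dissimilarity,
    run_partitioner,
)
from .netops import (
    EigengeneMatrix,
    build_adjacency,
    compute_eigengenes,
    detect_modules,
    tom_similarity,
)
from .evalmetrics import (
    ModuleScoreParams,
    cnmi,
    cox_lrt,
    label_agreement,
    module_score,
    silhouette,
    stability_resample,
)

__all__ = [
    "MetricTable",
    "ParetoFront",
    "DEFAULT_DIRECTIONS",
    "run_benchmark",
    "aggregate_metrics",
    "aggregated_matrix",
    "best_by_sum",
    "pareto_front",
]

# direction of preference for each recorded / aggregated metric
DEFAULT_DIRECTIONS: dict[str, str] = {
    "silhouette": "maximize",
    "stability_jaccard": "maximize",
    "stability_ari": "maximize",
    "nmi_subtype": "maximize",
    "ari_subtype": "maximize",
    "nmi_batch": "minimize",
    "cnmi": "maximize",
    "module_score": "maximize",
    "survival_lrt_p": "minimize",
    "survival_neglog10p": "maximize",
}

FULL_DATA_RESAMPLE_ID = "full"


@dataclass
class MetricTable:
    """Long-format metric records plus per-metric directions."""

    records: pd.DataFrame  # METRIC_COLUMNS
    directions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))

    def __post_init__(self) -> None:
        missing = set(METRIC_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"metric records lack columns: {sorted(missing)}")
        keys = self.records[METRIC_COLUMNS[:5]]
        if keys.duplicated().any():
            raise ValueError("duplicate (embedding, clusterer, k, resample, metric)")
        unknown = set(self.records["metric"]) - set(self.directions)
        if unknown:
            raise ValueError(f"metrics without a direction: {sorted(unknown)}")


@dataclass
class ParetoFront:
    """First Pareto frontier of the aggregated criteria matrix."""

    indices: list  # row labels of non-dominated combinations
    criteria: pd.DataFrame  # the (direction-aligned) matrix used


def _derive_seed(master: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(master), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


def _embedding_id(spec: dict) -> str:
    method = spec["method"]
    extras = [f"{k}={v}" for k, v in sorted(spec.items()) if k != "method"]
    return method if not extras else f"{method}({','.join(extras)})"


def _make_feature_fn(
    spec: dict,
    config: BenchmarkConfig,
    knowledge: tuple[GeneSetCollection, GeneNetwork, SeedSpec] | None,
    e_idx: int,
):
    spec = dict(spec)
    method = spec.pop("method")
    seed = _derive_seed(config.seed, 1, e_idx)
    if method == "rwr_fgsea":
        if knowledge is None:
            raise ConfigError("rwr_fgsea embedding requires knowledge inputs")
        sets, net, seed_spec = knowledge

        def feature_fn(ex: ExpressionMatrix) -> PathwayEmbedding:
            return rwr_fgsea_embedding(
                ex,
                seed_spec,
                net,
                sets,
                top_n=spec.get("top_n", config.seed_top_n),
                restart=spec.get("restart", config.rwr_restart),
                n_perm=spec.get("n_perm", config.gsea_n_perm),
                min_size=spec.get("min_size", config.gsea_min_size),
                max_size=spec.get("max_size", config.gsea_max_size),
                seed=seed,
            )

        return feature_fn
    if method in ("pca", "tsne", "umap", "identity"):
        n_dims = spec.pop("n_dims", 2)

        def feature_fn(ex: ExpressionMatrix):
            return reduce_dimensionality(
                ex, method=method, n_dims=n_dims, params=dict(spec), seed=seed
            )

        return feature_fn
    raise ConfigError(f"unknown embedding method {method!r}")


def _distance_policy(features, override: str | None = None) -> str:
    if override:
        return override
    if isinstance(features, PathwayEmbedding):
        return "correlation"
    if isinstance(features, Embedding):
        return features.distance
    return "euclidean"


def _dissimilarity(features, metric: str):
    if metric == "correlation":
        return correlation_dissimilarity(features)
    return euclidean_dissimilarity(features)


def _cluster(features, method: str, k: int, seed: int, distance: str | None = None):
    policy = _distance_policy(features, distance)
    if method == "diana":
        return diana_cluster(_dissimilarity(features, policy), k)
    if method in ("hc_average", "hc_complete"):
        return run_partitioner(_dissimilarity(features, policy), method, k, seed=seed)
    if isinstance(features, PathwayEmbedding):
        features = reduce_dimensionality(features, "identity")
    return run_partitioner(features, method, k, seed=seed)


def _module_eigengenes(expr: ExpressionMatrix, config: BenchmarkConfig) -> EigengeneMatrix | None:
    try:
        net = build_adjacency(expr, "soft", config.soft_power)
        tom = tom_similarity(net)
        modules = detect_modules(
            tom,
            genes=expr.gene_ids,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
        )
        if not modules.module_ids:
            warnings.warn("no gene modules detected; module score unavailable")
            return None
        return compute_eigengenes(expr, modules)
    except Exception as exc:
        warnings.warn(f"module detection failed: {exc}")
        return None


def run_benchmark(
    config: BenchmarkConfig,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    knowledge: tuple[GeneSetCollection, GeneNetwork, SeedSpec] | None = None,
) -> MetricTable:
    """Run the full benchmark grid and collect metric records.

    For every (embedding, clusterer, k): full-data records of
    silhouette, NMI/ARI against the known subtype, NMI against each
    batch variable, cNMI, module score and the survival LRT p-value,
    plus one stability record (co-clustering Jaccard and ARI vs. the
    full-data reference) per cross-validation resample. All seeds
    derive from ``config.seed`` by indexed SeedSequence spawning.
    """
    config.validate(n_samples=expr.n_samples)
    for spec in config.clusterers:
        if spec["method"] not in (
            "diana", "kmeans", "gmm", "hc_average", "hc_complete", "hc_ward",
        ):
            raise ConfigError(f"unknown clustering method {spec['method']!r}")

    if list(clinical.sample_ids) != list(expr.sample_ids):
        raise ConfigError("clinical table and expression matrix sample IDs differ")

    eigengenes = _module_eigengenes(expr, config)
    ms_params = ModuleScoreParams(config.module_score_alpha, config.module_score_beta)
    subtype = clinical.subtype
    batch_cols = clinical.batch_columns

    directions = dict(DEFAULT_DIRECTIONS)
    for b, col in enumerate(batch_cols):
        directions[f"nmi_batch_{col}"] = "minimize"

    rows: list[tuple] = []
    for e_idx, e_spec in enumerate(config.embeddings):
        e_id = _embedding_id(e_spec)
        feature_fn = _make_feature_fn(e_spec, config, knowledge, e_idx)
        try:
            features_full = feature_fn(expr)
        except Exception as exc:
            warnings.warn(f"embedding {e_id} failed on the full data: {exc}")
            continue
        for c_idx, c_spec in enumerate(config.clusterers):
            method = c_spec["method"]
            distance = c_spec.get("distance")
            for k in config.k_values:
                cluster_seed = _derive_seed(config.seed, 2, e_idx, c_idx, k)
                try:
                    result = _cluster(
                        features_full, method, k, cluster_seed, distance
                    )
                except Exception as exc:
                    warnings.warn(
                        f"{e_id}/{method}/k={k} failed on the full data: {exc}"
                    )
                    continue
                labels = result.labels

                def record(metric: str, value: float, rid=FULL_DATA_RESAMPLE_ID):
                    rows.append((e_id, method, k, rid, metric, value))

                policy = _distance_policy(features_full, distance)
                try:
                    record(
                        "silhouette",
                        silhouette(_dissimilarity(features_full, policy), labels),
                    )
                except Exception as exc:
                    warnings.warn(f"silhouette failed for {e_id}/{method}/{k}: {exc}")
                    record("silhouette", np.nan)

                if subtype is not None:
                    s = subtype.to_numpy()
                    record("nmi_subtype", label_agreement(labels, s, "nmi"))
                    record("ari_subtype", label_agreement(labels, s, "ari"))
                    if batch_cols:
                        record(
                            "cnmi",
                            cnmi(labels, s, clinical.data[batch_cols[0]].to_numpy()),
                        )
                for col in batch_cols:
                    b = clinical.data[col].to_numpy()
                    record(f"nmi_batch_{col}", label_agreement(labels, b, "nmi"))
                    if col == batch_cols[0]:
                        record("nmi_batch", label_agreement(labels, b, "nmi"))

                if eigengenes is not None:
                    try:
                        record(
                            "module_score",
                            module_score(eigengenes, labels, ms_params),
                        )
                    except Exception as exc:
                        warnings.warn(f"module score failed: {exc}")
                        record("module_score", np.nan)

                try:
                    surv = cox_lrt(
                        clinical,
                        labels,
                        covariates=tuple(config.survival_covariates),
                        followup_cap=config.followup_cap,
                    )
                    record("survival_lrt_p", surv.p_value)
                except Exception as exc:
                    warnings.warn(f"survival LRT failed: {exc}")
                    record("survival_lrt_p", np.nan)

                def pipeline(sub_expr):
                    feats = feature_fn(sub_expr)
                    return _cluster(feats, method, k, cluster_seed, distance).labels

                try:
                    report = stability_resample(
                        pipeline,
                        expr,
                        folds=config.stability_folds,
                        repeats=config.stability_repeats,
                        seed=_derive_seed(config.seed, 3, e_idx, c_idx, k),
                    )
                    for rid, rec in enumerate(report.records.itertuples()):
                        record("stability_jaccard", rec.jaccard, rid)
                        record("stability_ari", rec.ari, rid)
                except Exception as exc:
                    warnings.warn(f"stability failed for {e_id}/{method}/{k}: {exc}")

    records = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    return MetricTable(records, directions)


def aggregate_metrics(table: MetricTable) -> pd.DataFrame:
    """Mean and SD per (embedding, clusterer, k, metric).

    Survival LRT p-values are aggregated on the -log10 scale (median,
    reported as metric ``survival_neglog10p``); all other metrics as
    arithmetic mean with SD.
    """
    df = table.records.copy()
    out_rows = []
    grouped = df.groupby(["embedding", "clusterer", "k", "metric"], sort=True)
    for (e, c, k, metric), grp in grouped:
        vals = grp["value"].astype(float)
        if metric == "survival_lrt_p":
            neglog = -np.log10(vals.clip(lower=np.finfo(float).tiny))
            out_rows.append(
                (e, c, k, "survival_neglog10p", float(neglog.median()),
                 float(neglog.std(ddof=0)) if len(neglog) > 1 else 0.0)
            )
        else:
            out_rows.append(
                (e, c, k, metric, float(vals.mean()),
                 float(vals.std(ddof=0)) if len(vals) > 1 else 0.0)
            )
    return pd.DataFrame(
        out_rows, columns=["embedding", "clusterer", "k", "metric", "mean", "sd"]
    )


def aggregated_matrix(
    aggregated: pd.DataFrame, metrics: list[str] | None = None
) -> pd.DataFrame:
    """Pivot aggregated means to a combinations x metrics matrix."""
    pivot = aggregated.pivot_table(
        index=["embedding", "clusterer", "k"], columns="metric", values="mean"
    )
    if metrics is not None:
        pivot = pivot.loc[:, metrics]
    return pivot


def _minmax_scaled(matrix: pd.DataFrame, directions: dict[str, str]) -> pd.DataFrame:
    scaled = pd.DataFrame(index=matrix.index)
    for col in matrix.columns:
        x = matrix[col].astype(float)
        lo, hi = x.min(), x.max()
        if not np.isfinite(lo) or hi == lo:
            warnings.warn(f"metric {col!r} constant across combinations; contributes 0")
            scaled[col] = 0.0
            continue
        s = (x - lo) / (hi - lo)
        if directions.get(col, "maximize") == "minimize":
            s = 1.0 - s
        scaled[col] = s
    return scaled


DEFAULT_SELECTION_METRICS = [
    "silhouette",
    "stability_jaccard",
    "nmi_batch",
    "module_score",
    "survival_neglog10p",
]


def best_by_sum(
    aggregated: pd.DataFrame,
    metrics: list[str] | None = None,
    directions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Best clusterer per embedding by the scaled criteria sum.

    Each selected metric is min-max scaled to [0, 1] across all
    combinations (minimized metrics flipped); per embedding the
    clusterer with the highest sum averaged over k wins, ties broken by
    stability, then silhouette, then lexicographic clusterer name.
    """
    directions = directions or DEFAULT_DIRECTIONS
    matrix = aggregated_matrix(aggregated)
    if metrics is None:
        metrics = [m for m in DEFAULT_SELECTION_METRICS if m in matrix.columns]
    missing = [m for m in metrics if m not in matrix.columns]
    if missing:
        raise ValueError(f"metrics absent from the table: {missing}")
    scaled = _minmax_scaled(matrix[metrics], directions)
    sums = scaled.sum(axis=1).rename("sum_score").reset_index()

    per_clusterer = (
        sums.groupby(["embedding", "clusterer"])["sum_score"].mean().reset_index()
    )

    def tiebreak(embedding: str, cands: pd.DataFrame) -> tuple[str, bool]:
        top = cands[cands["sum_score"] >= cands["sum_score"].max() - 1e-12]
        tie = len(top) > 1
        if tie:
            for metric in ("stability_jaccard", "silhouette"):
                if metric in matrix.columns:
                    by = (
                        matrix.loc[embedding][metric]
                        .groupby(level="clusterer")
                        .mean()
                    )
                    vals = top["clusterer"].map(by)
                    top = top[vals >= vals.max() - 1e-12]
                    if len(top) == 1:
                        break
        return sorted(top["clusterer"])[0], tie

    rows = []
    for embedding, cands in per_clusterer.groupby("embedding"):
        best, tie = tiebreak(embedding, cands)
        score = float(
            cands.loc[cands["clusterer"] == best, "sum_score"].iloc[0]
        )
        if tie:
            warnings.warn(f"tie for embedding {embedding!r}; broken deterministically")
        rows.append((embedding, best, score, tie))
    return pd.DataFrame(rows, columns=["embedding", "clusterer", "sum_score", "tie"])


def pareto_front(
    criteria: pd.DataFrame, directions: dict[str, str] | None = None
) -> ParetoFront:
    """First Pareto frontier of a combinations x criteria matrix.

    After aligning directions (minimized criteria negated), a row is on
    the front iff no other row is >= on every criterion and > on at
    least one. Front order follows the input row order.
    """
    if criteria.shape[0] < 1 or criteria.shape[1] < 2:
        raise ValueError("need >= 1 combination and >= 2 criteria")
    directions = directions or DEFAULT_DIRECTIONS
    aligned = criteria.astype(float).copy()
    for col in aligned.columns:
        if directions.get(col, "maximize") == "minimize":
            aligned[col] = -aligned[col]
    x = aligned.to_numpy()
    n = x.shape[0]
    on_front = np.ones(n, dtype=bool)
    for i in range(n):
        if not on_front[i]:
            continue
        ge = np.all(x >= x[i], axis=1)
        gt = np.any(x > x[i], axis=1)
        if np.any(ge & gt & (np.arange(n) != i)):
            on_front[i] = False
    indices = [criteria.index[i] for i in range(n) if on_front[i]]
    return ParetoFront(indices, aligned)
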