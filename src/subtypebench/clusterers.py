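"""Clustering layer: correlation distance, DIANA, and partitioner adapters.

DIANA (DIvisive ANAlysis, Kaufman & Rousseeuw) is implemented in full:
starting from one cluster, the largest-diameter cluster is repeatedly
split by seeding a splinter group with the most dissimilar object and
moving objects that sit closer to the splinter group; cutting after
k - 1 splits yields exactly k clusters. The algorithm is fully
deterministic with ties broken by lowest sample index.

k-means, Gaussian mixtures and agglomerative hierarchical clustering
are adapters over scikit-learn/scipy with the conventions fixed here
(100 k-means++ restarts; GMM with full covariance and mean shrinkage
toward the global mean; trees cut at k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .errors import ContractError
from .embed import Embedding
from .rwr_fgsea import PathwayEmbedding

__all__ = [
    "DissimilarityMatrix",
    "ClusteringResult",
    "correlation_dissimilarity",
    "euclidean_dissimilarity",
    "diana_cluster",
    "run_partitioner",
    "canonicalize_labels",
]

GMM_MEAN_SHRINKAGE = 0.01
KMEANS_RESTARTS = 100


@dataclass
class DissimilarityMatrix:
    """Symmetric samples x samples dissimilarity with zero diagonal."""

    data: np.ndarray
    metric: str
    sample_ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.all(np.isfinite(d)):
            raise ValueError("dissimilarity matrix contains non-finite values")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any(d < -1e-12):
            raise ValueError("dissimilarity values must be non-negative")
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        np.fill_diagonal(d, 0.0)
        self.data = d

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


@dataclass
class ClusteringResult:
    """Per-sample cluster labels in 1..k, canonicalized by first occurrence."""

    labels: np.ndarray
    k: int
    method: str
    sample_ids: list[str]
    params: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        used = set(self.labels)
        if used != set(range(1, self.k + 1)):
            raise ContractError(
                f"labels must use every value in 1..{self.k}; got {sorted(used)}"
            )

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")


def canonicalize_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first occurrence."""
    raw = np.asarray(raw)
    mapping: dict = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def _feature_frame(features) -> pd.DataFrame:
    if isinstance(features, Embedding):
        return features.data
    if isinstance(features, PathwayEmbedding):
        return features.data.T
    if isinstance(features, pd.DataFrame):
        return features
    raise TypeError(f"unsupported feature container: {type(features).__name__}")


def correlation_dissimilarity(features) -> DissimilarityMatrix:
    """d(x, y) = 1 - Pearson correlation of two samples' feature vectors."""
    frame = _feature_frame(features)
    if frame.shape[1] < 2:
        raise ValueError("correlation distance needs >= 2 features per sample")
    values = frame.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = [str(s) for s, z in zip(frame.index, sd == 0) if z]
        raise ValueError(
            f"correlation undefined for constant feature vector(s): {bad}"
        )
    d = 1.0 - np.corrcoef(values)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d, "correlation", [str(s) for s in frame.index])


def euclidean_dissimilarity(features) -> DissimilarityMatrix:
    frame = _feature_frame(features)
    d = squareform(pdist(frame.to_numpy(dtype=float)))
    return DissimilarityMatrix(d, "euclidean", [str(s) for s in frame.index])


# ---------------------------------------------------------------------------
# DIANA
# ---------------------------------------------------------------------------


def _diana_split(d: np.ndarray, cluster: list[int]) -> tuple[list[int], list[int]]:
    """One DIANA split of ``cluster`` into (remainder, splinter)."""
    members = list(cluster)
    # splinter seed: object with maximal average dissimilarity to the
    # rest; members are scanned in ascending index order, so on ties the
    # lowest index wins
    best_i, best_avg = None, -np.inf
    for i in members:
        others = [j for j in members if j != i]
        avg = float(np.mean(d[i, others])) if others else 0.0
        if avg > best_avg + 1e-15:
            best_i, best_avg = i, avg
    splinter = [best_i]
    remainder = [j for j in members if j != best_i]

    while len(remainder) > 1:
        best_j, best_diff = None, 0.0
        for j in remainder:
            others = [i for i in remainder if i != j]
            d_rem = float(np.mean(d[j, others]))
            d_spl = float(np.mean(d[j, splinter]))
            diff = d_rem - d_spl
            if diff > best_diff + 1e-15:
                best_j, best_diff = j, diff
        if best_j is None or best_diff <= 0:
            break
        remainder.remove(best_j)
        splinter.append(best_j)
    return sorted(remainder), sorted(splinter)


def diana_split_sequence(d: np.ndarray, k: int) -> list[list[list[int]]]:
    """Cluster compositions after each of the k - 1 DIANA splits.

    Returns a list whose t-th entry is the partition (list of sorted
    index lists) after t splits; entry 0 is the single starting cluster.
    At each step the cluster with the largest diameter is split (ties:
    lowest first index).
    """
    n = d.shape[0]
    partitions = [[list(range(n))]]
    clusters = [list(range(n))]
    for _ in range(k - 1):
        diameters = []
        for c in clusters:
            diam = max((d[i, j] for i in c for j in c if i < j), default=0.0)
            diameters.append(diam)
        order = sorted(
            range(len(clusters)),
            key=lambda idx: (-diameters[idx], clusters[idx][0]),
        )
        target = next(
            (idx for idx in order if len(clusters[idx]) > 1),
            None,
        )
        if target is None:
            raise ValueError("cannot split further: all clusters are singletons")
        remainder, splinter = _diana_split(d, clusters[target])
        clusters = (
            clusters[:target] + [remainder, splinter] + clusters[target + 1 :]
        )
        partitions.append([sorted(c) for c in clusters])
    return partitions


def diana_cluster(d: DissimilarityMatrix, k: int) -> ClusteringResult:
    """Divisive hierarchical clustering cut at exactly k clusters."""
    n = d.n_samples
    if not (2 <= k <= n):
        raise ValueError(f"k={k} must lie in [2, n={n}]")
    partitions = diana_split_sequence(d.data, k)
    final = partitions[-1]
    raw = np.empty(n, dtype=int)
    for c_idx, members in enumerate(final):
        raw[members] = c_idx
    labels = canonicalize_labels(raw)
    return ClusteringResult(
        labels,
        k,
        "diana",
        list(d.sample_ids),
        params={"metric": d.metric},
        diagnostics={"n_splits": k - 1},
    )


# ---------------------------------------------------------------------------
# partitioner adapters
# ---------------------------------------------------------------------------


class _ShrunkMeanGMM(GaussianMixture):
    """Gaussian mixture whose M-step shrinks component means toward the
    global data mean (MAP with a normal prior of strength ``shrinkage``)."""

    def __init__(self, shrinkage: float = GMM_MEAN_SHRINKAGE, **kwargs):
        super().__init__(**kwargs)
        self.shrinkage = shrinkage

    def _m_step(self, X, log_resp, **kwargs):
        super()._m_step(X, log_resp, **kwargs)
        nk = np.exp(log_resp).sum(axis=0) + 10 * np.finfo(float).eps
        global_mean = X.mean(axis=0)
        lam = self.shrinkage
        self.means_ = (nk[:, None] * self.means_ + lam * global_mean[None, :]) / (
            nk[:, None] + lam
        )


def run_partitioner(
    features_or_d,
    method: str,
    k: int,
    seed: int = 0,
) -> ClusteringResult:
    """Run a named clustering method at a fixed k.

    ``kmeans``, ``gmm`` and ``hc_ward`` require coordinate features
    (Euclidean geometry); ``hc_average`` and ``hc_complete`` accept a
    precomputed :class:`DissimilarityMatrix` as well. Runs are seeded
    and deterministic given the seed; an empty cluster triggers up to
    five reseeded refits.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    is_dissim = isinstance(features_or_d, DissimilarityMatrix)
    if method in ("kmeans", "gmm", "hc_ward") and is_dissim:
        raise ContractError(f"{method} requires coordinate features, not a "
                            "dissimilarity matrix")

    if is_dissim:
        sample_ids = list(features_or_d.sample_ids)
        n = features_or_d.n_samples
    else:
        frame = _feature_frame(features_or_d)
        sample_ids = [str(s) for s in frame.index]
        n = frame.shape[0]
        x = frame.to_numpy(dtype=float)
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")

    if method in ("hc_average", "hc_complete", "hc_ward"):
        linkage_method = method.split("_")[1]
        if is_dissim:
            condensed = squareform(features_or_d.data, checks=False)
        else:
            condensed = pdist(x)
        z = linkage(condensed, method=linkage_method)
        raw = fcluster(z, t=k, criterion="maxclust")
        labels = canonicalize_labels(raw)
        return ClusteringResult(labels, k, method, sample_ids, params={"seed": seed})

    if method == "kmeans":
        model = KMeans(
            n_clusters=k, n_init=KMEANS_RESTARTS, init="k-means++", random_state=seed
        )
        raw = model.fit_predict(x)
        labels = canonicalize_labels(raw)
        return ClusteringResult(
            labels,
            k,
            "kmeans",
            sample_ids,
            params={"seed": seed, "n_init": KMEANS_RESTARTS},
            diagnostics={"inertia": float(model.inertia_)},
        )

    if method == "gmm":
        last_error: Exception | None = None
        for attempt in range(5):
            model = _ShrunkMeanGMM(
                shrinkage=GMM_MEAN_SHRINKAGE,
                n_components=k,
                covariance_type="full",
                reg_covar=1e-6,
                random_state=seed + attempt,
                n_init=5,
            )
            try:
                raw = model.fit_predict(x)
            except ValueError as exc:  # numerical failure
                last_error = exc
                continue
            if len(set(raw)) == k:
                labels = canonicalize_labels(raw)
                return ClusteringResult(
                    labels,
                    k,
                    "gmm",
                    sample_ids,
                    params={"seed": seed + attempt, "shrinkage": GMM_MEAN_SHRINKAGE},
                    diagnostics={"log_likelihood": float(model.lower_bound_)},
                )
        raise ContractError(
            f"gmm produced an empty cluster in 5 attempts: {last_error}"
        )

    raise ValueError(f"unknown clustering method {method!r}")
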