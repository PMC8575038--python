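"""Uniform adapter over dimensionality-reduction methods.

Data-driven feature spaces (PCA/t-SNE/UMAP of expression) and
knowledge-driven pathway embeddings are made interchangeable
downstream: every method yields an :class:`Embedding` carrying the
samples x dimensions matrix plus the distance convention clustering
should use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ExpressionMatrix
from .rwr_fgsea import PathwayEmbedding

__all__ = ["Embedding", "reduce_dimensionality"]

DEFAULT_TSNE_PERPLEXITY = 45.0
DEFAULT_UMAP_NEIGHBORS = 20


@dataclass
class Embedding:
    """Samples x dimensions feature matrix with its distance convention."""

    data: pd.DataFrame  # samples x dimensions
    method: str
    params: dict = field(default_factory=dict)
    distance: str = "euclidean"  # convention for downstream clustering

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValueError("embedding contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "Embedding":
        return Embedding(
            self.data.loc[list(sample_ids)], self.method, self.params, self.distance
        )


def _sample_matrix(features) -> pd.DataFrame:
    """Coerce supported containers to a samples x features frame."""
    if isinstance(features, ExpressionMatrix):
        return features.data.T
    if isinstance(features, PathwayEmbedding):
        return features.data.T
    if isinstance(features, Embedding):
        return features.data
    if isinstance(features, pd.DataFrame):
        return features
    raise TypeError(f"unsupported feature container: {type(features).__name__}")


def _pca_sign_fix(scores: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Deterministic PCA orientation: the largest-magnitude loading of
    each component is made non-negative."""
    for j in range(components.shape[0]):
        i = int(np.argmax(np.abs(components[j])))
        if components[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def reduce_dimensionality(
    features,
    method: str = "pca",
    n_dims: int = 2,
    params: dict | None = None,
    seed: int = 0,
) -> Embedding:
    """Project samples into a low-dimensional embedding.

    ``method`` is one of ``pca`` (deterministic, sign-fixed), ``tsne``
    (perplexity defaults to 45, n_dims limited to 2 or 3), ``umap``
    (n_neighbors defaults to 20) or ``identity`` (features passed
    through as samples x features with correlation distance).
    """
    params = dict(params or {})
    x = _sample_matrix(features)
    n_samples = x.shape[0]

    if method == "identity":
        return Embedding(x.copy(), "identity", params, distance="correlation")

    if n_dims >= n_samples:
        raise ValueError(f"n_dims={n_dims} must be < n_samples={n_samples}")
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")

    values = x.to_numpy(dtype=float)
    if method == "pca":
        model = PCA(n_components=n_dims, svd_solver="full")
        scores = model.fit_transform(values)
        scores = _pca_sign_fix(scores, model.components_)
        used = {"n_dims": n_dims}
    elif method == "tsne":
        if n_dims not in (2, 3):
            raise ValueError("tsne supports only 2 or 3 dimensions")
        from sklearn.manifold import TSNE

        perplexity = float(params.pop("perplexity", DEFAULT_TSNE_PERPLEXITY))
        perplexity = min(perplexity, (n_samples - 1) / 3.0)
        model = TSNE(
            n_components=n_dims,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
            **params,
        )
        scores = model.fit_transform(values)
        used = {"n_dims": n_dims, "perplexity": perplexity, "seed": seed}
    elif method == "umap":
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            from umap import UMAP

            n_neighbors = int(params.pop("n_neighbors", DEFAULT_UMAP_NEIGHBORS))
            n_neighbors = min(n_neighbors, n_samples - 1)
            model = UMAP(
                n_components=n_dims,
                n_neighbors=n_neighbors,
                random_state=seed,
                **params,
            )
            scores = model.fit_transform(values)
        used = {"n_dims": n_dims, "n_neighbors": n_neighbors, "seed": seed}
    else:
        raise ValueError(f"unknown dimensionality-reduction method {method!r}")

    df = pd.DataFrame(
        np.asarray(scores, dtype=float),
        index=x.index,
        columns=[f"dim{j + 1}" for j in range(n_dims)],
    )
    return Embedding(df, method, used, distance="euclidean")
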