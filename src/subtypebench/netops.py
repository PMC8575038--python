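"""Co-expression network construction and module detection.

Implements the WGCNA-style pipeline on Spearman correlations: hard- or
soft-thresholded adjacency, scale-free topology fit, topological-overlap
similarity, module detection by average-linkage clustering of 1 - TOM,
and module eigen-genes (first principal component per module).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .errors import DegenerateInputError
from .io import ExpressionMatrix, GeneNetwork

__all__ = [
    "ModuleAssignment",
    "EigengeneMatrix",
    "spearman_correlation",
    "build_adjacency",
    "scale_free_r2",
    "tune_threshold",
    "tom_similarity",
    "detect_modules",
    "compute_eigengenes",
]


@dataclass
class ModuleAssignment:
    """Gene-to-module map; module 0 means unassigned."""

    genes: list[str]
    labels: np.ndarray  # int per gene, 0 = unassigned

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.genes) != len(self.labels):
            raise ValueError("genes and labels length mismatch")
        present = sorted(set(self.labels) - {0})
        if present and present != list(range(1, len(present) + 1)):
            raise ValueError("module labels must be contiguous positive integers")

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    @property
    def sizes(self) -> dict[int, int]:
        return {m: int(np.sum(self.labels == m)) for m in self.module_ids}

    def module_genes(self, module: int) -> list[str]:
        return [g for g, lab in zip(self.genes, self.labels) if lab == module]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "module": self.labels})


@dataclass
class EigengeneMatrix:
    """Samples x modules eigen-gene matrix with explained variance."""

    data: pd.DataFrame  # samples x modules, columns "ME1", "ME2", ...
    explained_variance: dict[int, float]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def module_ids(self) -> list[int]:
        return [int(c[2:]) for c in self.data.columns]

    def subset_samples(self, sample_ids) -> "EigengeneMatrix":
        return EigengeneMatrix(self.data.loc[list(sample_ids)], self.explained_variance)


def spearman_correlation(values: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation matrix (genes x genes)."""
    ranks = np.apply_along_axis(rankdata, 1, values)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    return np.nan_to_num(rho, nan=0.0)


def build_adjacency(
    expr: ExpressionMatrix, mode: str, param: float
) -> GeneNetwork:
    """Adjacency from absolute Spearman correlations between genes.

    ``hard``: unweighted edge where ``|rho| >= param`` (param in (0,1));
    ``soft``: weight ``|rho| ** param`` (param an integer power >= 1).
    The diagonal is excluded.
    """
    if expr.n_samples < 3:
        raise DegenerateInputError("correlation needs at least 3 samples")
    if mode == "hard":
        if not (0 < param < 1):
            raise ValueError("hard threshold must lie in (0, 1)")
    elif mode == "soft":
        if param < 1 or int(param) != param:
            raise ValueError("soft power must be an integer >= 1")
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")

    rho = np.abs(spearman_correlation(expr.values))
    np.fill_diagonal(rho, 0.0)
    if mode == "hard":
        adj = (rho >= param).astype(float)
    else:
        adj = rho ** param
    return GeneNetwork(expr.gene_ids, adj)


def scale_free_r2(degrees: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a degree distribution.

    Degrees (or weighted connectivities) are binned into ``n_bins``
    logarithmic bins; R-squared of the regression of log10 p(k) on
    log10 k over non-empty bins is returned when the slope is negative
    (a decreasing p(k), as scale-free topology requires) and 0.0 when
    the slope is positive.
    """
    degrees = np.asarray(degrees, dtype=float)
    degrees = degrees[degrees > 0]
    if degrees.size == 0 or np.unique(degrees).size < 2:
        raise DegenerateInputError("degenerate degree distribution (all equal)")
    log_k = np.log10(degrees)
    edges = np.linspace(log_k.min(), log_k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(log_k, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    sums = np.bincount(which, weights=degrees, minlength=n_bins)
    occupied = counts > 0
    if occupied.sum() < 2:
        raise DegenerateInputError("fewer than 2 occupied degree bins")
    p_k = counts[occupied] / counts.sum()
    mean_k = sums[occupied] / counts[occupied]
    x = np.log10(mean_k)
    y = np.log10(p_k)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise DegenerateInputError("degree distribution has a single occupied level")
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return float(r2) if slope < 0 else 0.0


@dataclass
class ThresholdDiagnostics:
    param: float
    r2: float
    mean_degree: float


def tune_threshold(
    expr: ExpressionMatrix,
    mode: str,
    grid: list[float],
    r2_target: float = 0.8,
) -> tuple[float, bool, list[ThresholdDiagnostics]]:
    """Pick the smallest threshold/power meeting the scale-free criterion.

    Returns ``(param, reached_target, diagnostics)``. When no grid value
    reaches ``r2_target`` the argmax-R2 value is returned with
    ``reached_target`` False and a warning.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    grid = sorted(grid)
    diagnostics: list[ThresholdDiagnostics] = []
    for param in grid:
        net = build_adjacency(expr, mode, param)
        deg = net.degrees()
        try:
            r2 = scale_free_r2(deg)
        except DegenerateInputError:
            r2 = np.nan
        diagnostics.append(ThresholdDiagnostics(param, r2, float(deg.mean())))
    valid = [d for d in diagnostics if np.isfinite(d.r2)]
    if not valid:
        raise DegenerateInputError("degenerate degree distribution at every grid value")
    for d in diagnostics:
        if np.isfinite(d.r2) and d.r2 >= r2_target:
            return d.param, True, diagnostics
    best = max(valid, key=lambda d: d.r2)
    warnings.warn(
        f"no grid value reached R2 target {r2_target}; "
        f"returning argmax R2={best.r2:.3f} at {best.param}"
    )
    return best.param, False, diagnostics


def tom_similarity(net: GeneNetwork) -> np.ndarray:
    """Topological overlap similarity of an adjacency with weights in [0,1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j and 1 on the diagonal; shared neighbours increase similarity
    beyond the direct connection.
    """
    a = net.adjacency
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("TOM requires adjacency weights in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    genes: list[str] | None = None,
    min_module_size: int = 10,
    cut_height: float = 0.9,
) -> ModuleAssignment:
    """Modules by average-linkage clustering of the 1 - TOM dissimilarity.

    The dendrogram is cut at ``cut_height`` times the maximum merge
    height; clusters smaller than ``min_module_size`` are relabelled 0
    (unassigned). Remaining modules are renumbered 1..M by decreasing
    size (ties by first gene index).
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if genes is None:
        genes = [f"g{i}" for i in range(n)]
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size; all unassigned")
        return ModuleAssignment(list(genes), np.zeros(n, dtype=int))
    if not np.allclose(tom, tom.T):
        raise ValueError("TOM must be symmetric")
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    max_height = z[:, 2].max() if len(z) else 0.0
    raw = fcluster(z, t=cut_height * max_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    # order surviving clusters by size desc, then first occurrence
    clusters = []
    for c in np.unique(raw):
        idx = np.nonzero(raw == c)[0]
        if len(idx) >= min_module_size:
            clusters.append((len(idx), idx[0], c))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for new_label, (_, _, c) in enumerate(clusters, start=1):
        labels[raw == c] = new_label
    return ModuleAssignment(list(genes), labels)


def compute_eigengenes(
    expr: ExpressionMatrix, modules: ModuleAssignment
) -> EigengeneMatrix:
    """First-principal-component eigen-gene of each module.

    Genes are standardized across samples; the eigen-gene is the
    unit-norm first left singular vector of the samples x genes module
    submatrix, sign-aligned so it correlates non-negatively with the
    module's mean expression profile. Explained variance is the first
    eigenvalue's share.
    """
    values = expr.data
    columns: dict[str, np.ndarray] = {}
    explained: dict[int, float] = {}
    for module in modules.module_ids:
        genes = [g for g in modules.module_genes(module) if g in values.index]
        if not genes:
            warnings.warn(f"module {module} has no genes in the expression matrix")
            continue
        sub = values.loc[genes].to_numpy(dtype=float)  # genes x samples
        sd = sub.std(axis=1, ddof=0)
        keep = sd > 0
        if not np.any(keep):
            warnings.warn(f"module {module} is constant; skipped")
            continue
        sub = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        x = sub.T  # samples x genes, column-standardized
        if x.shape[1] == 1:
            warnings.warn(f"module {module} reduced to a single gene")
            eg = x[:, 0]
            explained[module] = 1.0
        else:
            u, s, _ = np.linalg.svd(x, full_matrices=False)
            eg = u[:, 0]
            explained[module] = float(s[0] ** 2 / np.sum(s**2))
        eg = eg / np.linalg.norm(eg)
        mean_profile = x.mean(axis=1)
        if np.dot(eg, mean_profile - mean_profile.mean()) < 0:
            eg = -eg
        columns[f"ME{module}"] = eg
    df = pd.DataFrame(columns, index=pd.Index(expr.sample_ids, name="sample_id"))
    return EigengeneMatrix(df, explained)
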