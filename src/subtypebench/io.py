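"""Domain containers and readers/writers for the standard formats.

Expression matrices, clinical tables and edge lists are plain TSV/CSV;
gene set collections use the GMT convention (one tab-separated set per
line: name, description, members...). All containers are thin, validated
wrappers around pandas/numpy objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    DuplicateIDError,
    FormatError,
    ParseError,
)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "GeneNetwork",
    "ClinicalTable",
    "BenchmarkConfig",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
    "read_clinical",
    "write_metrics",
    "read_metrics",
    "load_config",
    "filter_low_variance_genes",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values."""

    data: pd.DataFrame  # rows = genes, columns = samples

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DuplicateIDError(f"duplicate gene IDs: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise DuplicateIDError(f"duplicate sample IDs: {dupes}")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValueError(
                f"expression matrix needs >= 2 genes and >= 2 samples, got {df.shape}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ParseError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids), :])


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways); order of sets and members is preserved."""

    sets: dict[str, list[str]]  # insertion-ordered
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def filter_by_size(self, min_size: int, max_size: int) -> "GeneSetCollection":
        kept = {
            n: m for n, m in self.sets.items() if min_size <= len(m) <= max_size
        }
        return GeneSetCollection(
            kept, {n: d for n, d in self.descriptions.items() if n in kept}
        )


class GeneNetwork:
    """Undirected gene network held as a dense symmetric adjacency matrix.

    Weights are non-negative and finite; the diagonal is zero. Unweighted
    networks use 0/1 weights.
    """

    def __init__(self, nodes: Sequence[str], adjacency: np.ndarray):
        nodes = [str(n) for n in nodes]
        if len(set(nodes)) != len(nodes):
            raise DuplicateIDError("duplicate node IDs in network")
        adjacency = np.asarray(adjacency, dtype=float)
        if adjacency.shape != (len(nodes), len(nodes)):
            raise ValueError("adjacency shape does not match node list")
        if not np.all(np.isfinite(adjacency)):
            raise ValueError("adjacency contains non-finite weights")
        if np.any(adjacency < 0):
            raise ValueError("adjacency contains negative weights")
        if not np.allclose(adjacency, adjacency.T):
            raise ValueError("adjacency must be symmetric (undirected network)")
        adjacency = (adjacency + adjacency.T) / 2.0
        np.fill_diagonal(adjacency, 0.0)
        self.nodes: list[str] = nodes
        self.adjacency: np.ndarray = adjacency
        self._index = {n: i for i, n in enumerate(nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def degrees(self) -> np.ndarray:
        """Weighted connectivity per node (plain degree when unweighted)."""
        return self.adjacency.sum(axis=1)

    def edges(self) -> Iterable[tuple[str, str, float]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        for i, j in zip(ii, jj):
            yield self.nodes[i], self.nodes[j], float(self.adjacency[i, j])

    def has_node(self, node: str) -> bool:
        return node in self._index

    def largest_component(self) -> list[str]:
        """Node IDs of the largest connected component."""
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        n_comp, labels = connected_components(
            csr_matrix(self.adjacency > 0), directed=False
        )
        sizes = np.bincount(labels)
        keep = int(np.argmax(sizes))
        return [n for n, lab in zip(self.nodes, labels) if lab == keep]

    def subnetwork(self, nodes: Sequence[str]) -> "GeneNetwork":
        idx = [self._index[n] for n in nodes]
        return GeneNetwork(list(nodes), self.adjacency[np.ix_(idx, idx)])

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Sequence[str] | None = None,
    ) -> "GeneNetwork":
        """Build a network from an undirected edge list.

        Duplicate edges (either orientation) are collapsed keeping the
        maximum weight; self-loops are dropped with a warning.
        """
        weights: dict[tuple[str, str], float] = {}
        seen_nodes: list[str] = list(nodes) if nodes is not None else []
        seen_set = set(seen_nodes)
        for edge in edges:
            a, b = str(edge[0]), str(edge[1])
            w = float(edge[2]) if len(edge) > 2 else 1.0
            if w < 0:
                raise ValueError(f"negative edge weight on ({a}, {b}): {w}")
            if not np.isfinite(w):
                raise ValueError(f"non-finite edge weight on ({a}, {b})")
            for n in (a, b):
                if n not in seen_set:
                    seen_set.add(n)
                    seen_nodes.append(n)
            if a == b:
                warnings.warn(f"dropping self-loop on {a!r}")
                continue
            key = (a, b) if a <= b else (b, a)
            weights[key] = max(weights.get(key, 0.0), w)
        adj = np.zeros((len(seen_nodes), len(seen_nodes)))
        index = {n: i for i, n in enumerate(seen_nodes)}
        for (a, b), w in weights.items():
            adj[index[a], index[b]] = w
            adj[index[b], index[a]] = w
        return cls(seen_nodes, adj)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations: survival, covariates, labels.

    `data` is indexed by sample ID with canonical columns ``time`` and
    ``event`` (may contain NaN for samples without follow-up, flagged in
    ``has_survival``) plus optional ``subtype``, batch columns and
    covariate columns.
    """

    data: pd.DataFrame
    covariate_columns: list[str] = field(default_factory=list)
    batch_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise DuplicateIDError("duplicate sample IDs in clinical table")
        for col in ["time", "event"] + self.covariate_columns + self.batch_columns:
            if col in ("time", "event"):
                continue
            if col not in self.data.columns:
                raise ConfigError(f"clinical table is missing column {col!r}")
        if "time" in self.data.columns and "event" in self.data.columns:
            ev = self.data["event"].dropna()
            bad = ~ev.isin([0, 1, 0.0, 1.0, True, False])
            if bad.any():
                raise ValueError(
                    f"event values outside {{0,1}}: {ev[bad].unique().tolist()}"
                )
            tt = self.data.loc[ev.index, "time"]
            if (tt.dropna() <= 0).any():
                raise ValueError("follow-up times must be > 0 where event is defined")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def has_survival(self) -> pd.Series:
        if "time" not in self.data.columns or "event" not in self.data.columns:
            return pd.Series(False, index=self.data.index)
        return self.data["time"].notna() & self.data["event"].notna()

    @property
    def subtype(self) -> pd.Series | None:
        return self.data["subtype"] if "subtype" in self.data.columns else None

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(
            self.data.loc[list(sample_ids)],
            list(self.covariate_columns),
            list(self.batch_columns),
        )


@dataclass
class BenchmarkConfig:
    """Configuration of a full benchmark run.

    ``embeddings`` and ``clusterers`` are lists of ``{"method": ..., **params}``
    mappings; ``k_values`` is the grid of cluster counts.
    """

    embeddings: list[dict]
    clusterers: list[dict]
    k_values: list[int]
    seed: int = 0
    stability_folds: int = 5
    stability_repeats: int = 20
    module_score_alpha: float = 0.5
    module_score_beta: float = 0.0
    survival_covariates: list[str] = field(default_factory=list)
    followup_cap: float | None = None
    soft_power: int = 6
    min_module_size: int = 10
    cut_height: float = 0.9
    rwr_restart: float = 0.75
    seed_top_n: int = 50
    gsea_n_perm: int = 1000
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    paths: dict = field(default_factory=dict)

    def validate(self, n_samples: int | None = None) -> None:
        if not self.embeddings or not self.clusterers or not self.k_values:
            raise ConfigError("embeddings, clusterers and k_values must be non-empty")
        if self.stability_folds < 2:
            raise ConfigError("stability_folds must be >= 2")
        if self.stability_repeats < 1:
            raise ConfigError("stability_repeats must be >= 1")
        for k in self.k_values:
            if k < 2:
                raise ConfigError(f"k={k} invalid: need k >= 2")
            if n_samples is not None and k > n_samples - 1:
                raise ConfigError(f"k={k} exceeds n_samples-1={n_samples - 1}")
        if not (0 < self.module_score_alpha < 1):
            raise ConfigError("module_score_alpha must lie in (0, 1)")
        if not (0 <= self.module_score_beta <= 1):
            raise ConfigError("module_score_beta must lie in [0, 1]")
        if not (0 < self.rwr_restart <= 1):
            raise ConfigError("rwr_restart must lie in (0, 1]")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from TSV/CSV.

    First column holds gene IDs, header row holds sample IDs.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty expression file: {path}") from exc
    if df.empty:
        raise ParseError(f"expression file has no data rows: {path}")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-numeric expression value in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    expr.data.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m != ""]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise DuplicateIDError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                warnings.warn(f"set {name!r}: duplicate members removed")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.set_names:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + list(collection[name])) + "\n")


def read_network(path: str | Path, symmetrize: bool = True) -> GeneNetwork:
    """Read a 2- or 3-column edge list into an undirected network.

    With ``symmetrize`` each directed edge contributes one undirected
    edge (duplicates collapsed keeping the maximum weight).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#", dtype=str)
    if df.shape[1] == 2:
        edges = [(a, b) for a, b in df.itertuples(index=False)]
    elif df.shape[1] == 3:
        edges = [(a, b, float(w)) for a, b, w in df.itertuples(index=False)]
    else:
        raise FormatError(f"edge list must have 2 or 3 columns, got {df.shape[1]}")
    if not symmetrize:
        # keep API symmetry: without symmetrization the file must already
        # list both orientations consistently; construction symmetrizes
        # anyway since the container is undirected.
        pass
    return GeneNetwork.from_edges(edges)


def write_network(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def read_clinical(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    covariates: Sequence[str] = (),
    batch_columns: Sequence[str] = (),
) -> ClinicalTable:
    """Read a clinical table from CSV/TSV.

    ``column_map`` maps canonical names (sample_id, time, event, subtype,
    batch columns) to file column names. Unmapped canonical names default
    to identically named columns when present.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    column_map = dict(column_map or {})

    def resolve(canonical: str, required: bool = False) -> str | None:
        name = column_map.get(canonical, canonical)
        if name in df.columns:
            return name
        if canonical in column_map or required:
            raise ConfigError(f"clinical file {path} lacks mapped column {name!r}")
        return None

    id_col = resolve("sample_id", required=True)
    out = pd.DataFrame(index=df[id_col].astype(str))
    out.index.name = "sample_id"
    for canonical in ("time", "event", "subtype"):
        col = resolve(canonical)
        if col is not None:
            out[canonical] = df[col].to_numpy()
    for col in list(covariates) + list(batch_columns):
        src = column_map.get(col, col)
        if src not in df.columns:
            raise ConfigError(f"clinical file {path} lacks mapped column {src!r}")
        out[col] = df[src].to_numpy()
    missing = pd.Series(False, index=out.index)
    if "time" in out.columns and "event" in out.columns:
        missing = out["time"].isna() | out["event"].isna()
        if missing.any():
            warnings.warn(f"{int(missing.sum())} samples lack survival data; flagged")
    return ClinicalTable(out, list(covariates), list(batch_columns))


METRIC_COLUMNS = ["embedding", "clusterer", "k", "resample_id", "metric", "value"]


def write_metrics(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format metric table (one row per record) as CSV."""
    df = table.loc[:, METRIC_COLUMNS].copy()
    df = df.sort_values(METRIC_COLUMNS[:5], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"metric file lacks columns: {sorted(missing)}")
    return df


def load_config(path: str | Path) -> BenchmarkConfig:
    """Load a BenchmarkConfig from a YAML document."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    known = {f for f in BenchmarkConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        cfg = BenchmarkConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def filter_low_variance_genes(
    expr: ExpressionMatrix,
    variance_floor: float = 1e-8,
    max_mode_fraction: float = 0.95,
) -> ExpressionMatrix:
    """Drop near-zero-variance genes.

    A gene is removed when its variance falls below ``variance_floor`` or
    its most frequent value covers more than ``max_mode_fraction`` of
    samples.
    """
    values = expr.values
    keep = values.var(axis=1, ddof=0) >= variance_floor
    n = expr.n_samples
    for i in np.nonzero(keep)[0]:
        _, counts = np.unique(values[i], return_counts=True)
        if counts.max() / n > max_mode_fraction:
            keep[i] = False
    kept_genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    if len(kept_genes) < expr.n_genes:
        warnings.warn(
            f"removed {expr.n_genes - len(kept_genes)} near-zero-variance genes"
        )
    return expr.subset_genes(kept_genes)
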