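"""Network-diffusion pathway enrichment features for patient stratification.

The pipeline turns one expression profile per patient into a sparse
vector of pathway activities:

1. per-patient seed genes — the top-ranked members of up- and
   down-regulated disease gene lists (ranked by per-gene z-score);
2. random walk with restart (RWR) from the seeds over a gene network,
   yielding a per-gene affinity profile;
3. pre-ranked GSEA on the affinity profile against a gene set
   collection, giving per-pathway ES/NES and permutation p-values;
4. assembly of an adjusted-score embedding, NES * (-log10 p) by
   default, which is sparse because pathways with p ~ 1 score ~ 0.

Up- and down-seeded walks are run separately; the down run's scores
enter the embedding with flipped sign so positive embedding values
track up-regulated biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DegenerateInputError, SeedGeneError
from .io import ExpressionMatrix, GeneNetwork, GeneSetCollection

__all__ = [
    "SeedSpec",
    "SampleSeedSets",
    "EnrichmentResult",
    "PathwayEmbedding",
    "select_seed_genes",
    "rwr_propagate",
    "preranked_gsea",
    "build_pathway_embedding",
    "rwr_fgsea_embedding",
]


@dataclass
class SeedSpec:
    """Disease gene lists split by fold-change sign."""

    up_genes: list[str]
    down_genes: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"up/down gene lists overlap: {sorted(overlap)[:5]}")


@dataclass
class SampleSeedSets:
    """Per-sample selected seed genes, split by direction."""

    up: dict[str, list[str]]  # sample -> genes
    down: dict[str, list[str]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.up)


@dataclass
class EnrichmentResult:
    """Per-gene-set enrichment statistics for one sample.

    ``table`` is indexed by set name with columns ``es``, ``nes``,
    ``p``, ``n_more_extreme``, ``size_used`` and boolean ``skipped``
    (set outside the size window after filtering to scored genes).
    """

    table: pd.DataFrame

    @property
    def set_names(self) -> list[str]:
        return list(self.table.index)


@dataclass
class PathwayEmbedding:
    """Pathways x samples matrix of adjusted enrichment scores."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def pathway_ids(self) -> list[str]:
        return [str(p) for p in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "PathwayEmbedding":
        return PathwayEmbedding(self.data.loc[:, list(sample_ids)], self.provenance)


def select_seed_genes(
    expr: ExpressionMatrix,
    spec: SeedSpec,
    top_n: int = 50,
    standardize: bool = True,
) -> SampleSeedSets:
    """Select per-sample seed genes from signed disease gene lists.

    Genes are z-scored across samples (so ranking reflects relative
    dysregulation rather than constitutive abundance); per sample the
    ``top_n`` up-list genes with the highest z and the ``top_n``
    down-list genes with the lowest z are selected. Ties break by
    lexicographic gene ID.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    present = set(expr.gene_ids)
    up = [g for g in spec.up_genes if g in present]
    down = [g for g in spec.down_genes if g in present]
    if len(up) < len(spec.up_genes) or len(down) < len(spec.down_genes):
        warnings.warn("seed-list genes absent from the expression matrix were dropped")
    if not up or not down:
        raise SeedGeneError("up and down gene lists must be non-empty after filtering")
    if top_n > len(up) and top_n > len(down):
        warnings.warn(f"top_n={top_n} exceeds both list lengths; full lists used")

    data = expr.data
    if standardize:
        mu = data.mean(axis=1)
        sd = data.std(axis=1, ddof=0).replace(0.0, 1.0)
        data = data.sub(mu, axis=0).div(sd, axis=0)

    up_sets: dict[str, list[str]] = {}
    down_sets: dict[str, list[str]] = {}
    up_frame = data.loc[up]
    down_frame = data.loc[down]
    for sample in expr.sample_ids:
        z_up = up_frame[sample]
        order_up = sorted(up, key=lambda g: (-z_up[g], g))
        up_sets[sample] = order_up[: min(top_n, len(up))]
        z_dn = down_frame[sample]
        order_dn = sorted(down, key=lambda g: (z_dn[g], g))
        down_sets[sample] = order_dn[: min(top_n, len(down))]
    return SampleSeedSets(up_sets, down_sets)


def _normalized_operator(net: GeneNetwork, normalization: str) -> np.ndarray:
    a = net.adjacency
    k = a.sum(axis=1)
    if np.any(k == 0):
        raise ValueError("normalization undefined for isolated nodes")
    if normalization == "symmetric":
        d = 1.0 / np.sqrt(k)
        return a * d[:, None] * d[None, :]
    if normalization == "row-stochastic":
        # column-normalized operator: applying it to a probability
        # vector implements one step of the row-stochastic random walk
        # and conserves total probability
        return a / k[None, :]
    raise ValueError(f"unknown normalization {normalization!r}")


def rwr_propagate(
    net: GeneNetwork,
    seeds,
    restart: float = 0.75,
    normalization: str = "symmetric",
    tol: float = 1e-10,
    max_iter: int = 10_000,
    _operator: np.ndarray | None = None,
    _component: list[str] | None = None,
) -> pd.Series:
    """Random walk with restart from a seed gene set.

    Iterates ``p <- (1 - r) W p + r p0`` with ``p0`` uniform over the
    seeds and ``W`` the normalized adjacency of the network's largest
    connected component, until the L1 change falls below ``tol``.
    Returns per-gene affinities over all network nodes (zero outside
    the component).
    """
    if not (0 < restart <= 1):
        raise ValueError("restart probability must lie in (0, 1]")
    component = _component if _component is not None else net.largest_component()
    comp_index = {g: i for i, g in enumerate(component)}
    seeds = list(seeds)
    kept = [g for g in seeds if g in comp_index]
    if len(kept) < len(seeds):
        warnings.warn(
            f"{len(seeds) - len(kept)} seed genes outside the largest "
            "connected component were dropped"
        )
    if not kept:
        raise SeedGeneError("no seed gene lies in the network's largest component")

    if _operator is None:
        sub = net.subnetwork(component)
        w = _normalized_operator(sub, normalization)
    else:
        w = _operator
    n = len(component)
    p0 = np.zeros(n)
    p0[[comp_index[g] for g in kept]] = 1.0 / len(kept)

    p = p0.copy()
    r = restart
    for _ in range(max_iter):
        p_next = (1.0 - r) * (w @ p) + r * p0
        if np.abs(p_next - p).sum() < tol:
            p = p_next
            break
        p = p_next
    else:
        raise ConvergenceError(
            f"RWR did not converge within {max_iter} iterations",
            residual=float(np.abs(p_next - p).sum()),
        )
    out = pd.Series(0.0, index=pd.Index(net.nodes, name="gene"))
    out.iloc[[net._index[g] for g in component]] = p
    return out


def _es_from_positions(
    pos: np.ndarray, w_sorted: np.ndarray, n_genes: int
) -> np.ndarray:
    """Enrichment scores for hit-position matrices (rows = instances).

    ``pos`` is (n_instances, m) of sorted 0-based hit positions in the
    ranked gene list, ``w_sorted`` the per-position weights
    ``|score| ** exponent``. Returns the signed maximum deviation of the
    weighted running sum for each row.
    """
    pos = np.atleast_2d(pos)
    n_inst, m = pos.shape
    miss_rate = 1.0 / (n_genes - m)
    hit_w = w_sorted[pos]
    cum = np.cumsum(hit_w, axis=1)
    total = cum[:, -1].copy()
    zero = total <= 0
    if np.any(zero):
        # all-hit weights zero: fall back to unweighted (classic KS) hits
        cum[zero] = np.arange(1, m + 1)[None, :]
        total[zero] = m
    cum_hit = cum / total[:, None]
    idx = np.arange(m)[None, :]
    misses_before = pos - idx
    after = cum_hit - misses_before * miss_rate
    before = np.concatenate([np.zeros((n_inst, 1)), cum_hit[:, :-1]], axis=1)
    before = before - misses_before * miss_rate
    es_pos = after.max(axis=1)
    es_neg = before.min(axis=1)
    # the positive deviation wins ties; the tolerance keeps structural
    # ties (both deviations an exact multiple of the miss rate) from
    # being broken by float accumulation order
    return np.where(es_pos >= -es_neg - 1e-12, es_pos, es_neg)


def preranked_gsea(
    scores: pd.Series,
    sets: GeneSetCollection,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
    perm_matrix: np.ndarray | None = None,
) -> EnrichmentResult:
    """Pre-ranked GSEA of one score profile against a gene set collection.

    Genes are ranked by descending score (ties lexicographic); the
    running sum gains ``|score|**exponent`` (normalized) at set members
    and loses ``1/(N - set size)`` elsewhere; ES is the signed maximum
    deviation. The null distribution comes from ``n_perm`` random
    gene-label permutations: NES = ES / mean |null ES| of matching
    sign, p = (1 + #{more extreme, matching sign}) / (1 + #matching).

    ``perm_matrix`` (n_perm x n_genes, each row a permutation of
    0..n_genes-1) may be supplied to share one permutation null across
    samples.
    """
    scores = scores.astype(float)
    if not np.all(np.isfinite(scores.to_numpy())):
        raise ValueError("scores must be finite")
    if scores.nunique() == 1:
        raise DegenerateInputError("all ranking scores equal; ranking undefined")
    genes = list(scores.index)
    n_genes = len(genes)
    universe_index = {g: i for i, g in enumerate(genes)}

    # rank: descending score, ties by gene ID
    order = sorted(range(n_genes), key=lambda i: (-scores.iloc[i], genes[i]))
    rank_of = np.empty(n_genes, dtype=int)
    rank_of[order] = np.arange(n_genes)
    w_sorted = np.abs(scores.to_numpy()[order]) ** weight_exponent

    if perm_matrix is None:
        rng = np.random.default_rng(seed)
        perm_matrix = np.argsort(rng.random((n_perm, n_genes)), axis=1)
    else:
        n_perm = perm_matrix.shape[0]
        if perm_matrix.shape[1] != n_genes:
            raise ValueError("perm_matrix width does not match the gene universe")

    rows = []
    for name in sets.set_names:
        members = [g for g in sets[name] if g in universe_index]
        m = len(members)
        if not (min_size <= m <= max_size) or m >= n_genes:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, m, True))
            continue
        slots = np.array([universe_index[g] for g in members])
        pos = np.sort(rank_of[slots])
        es = float(_es_from_positions(pos[None, :], w_sorted, n_genes)[0])

        null_pos = np.sort(perm_matrix[:, slots], axis=1)
        null_es = _es_from_positions(null_pos, w_sorted, n_genes)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_matching = int(same_sign.sum())
        if n_matching == 0:
            nes, p, n_more = 0.0, 1.0, 0
        else:
            matching = np.abs(null_es[same_sign])
            mean_null = matching.mean()
            nes = es / mean_null if mean_null > 0 else 0.0
            n_more = int((matching >= abs(es)).sum())
            p = (1 + n_more) / (1 + n_matching)
        rows.append((name, es, nes, p, n_more, m, False))

    table = pd.DataFrame(
        rows,
        columns=["set", "es", "nes", "p", "n_more_extreme", "size_used", "skipped"],
    ).set_index("set")
    return EnrichmentResult(table)


def build_pathway_embedding(
    results: dict[str, EnrichmentResult],
    transform: str = "nes_times_neglog10p",
    significance_floor: float = 1.0,
) -> PathwayEmbedding:
    """Assemble per-sample enrichment results into a pathway embedding.

    Default adjusted score is ``NES * (-log10 p)``; the literal variant
    ``nes_times_logp`` uses ``NES * ln(p)`` (which flips the sign).
    Entries with p above ``significance_floor`` and pathways skipped in
    a sample are set to 0, giving the sparse embedding.
    """
    if not results:
        raise ValueError("no enrichment results supplied")
    samples = list(results)
    universe = results[samples[0]].set_names
    columns = {}
    for sample in samples:
        res = results[sample]
        if res.set_names != universe:
            raise ValueError(f"inconsistent pathway universe for sample {sample!r}")
        nes = res.table["nes"].to_numpy(dtype=float)
        p = res.table["p"].to_numpy(dtype=float)
        if transform == "nes_times_neglog10p":
            adj = nes * (-np.log10(p))
        elif transform == "nes_times_logp":
            adj = nes * np.log(p)
        else:
            raise ValueError(f"unknown transform {transform!r}")
        adj = np.where(np.isnan(adj) | (p > significance_floor), 0.0, adj)
        columns[sample] = adj
    data = pd.DataFrame(columns, index=pd.Index(universe, name="pathway"))
    return PathwayEmbedding(
        data, provenance={"transform": transform, "significance_floor": significance_floor}
    )


def rwr_fgsea_embedding(
    expr: ExpressionMatrix,
    spec: SeedSpec,
    net: GeneNetwork,
    sets: GeneSetCollection,
    top_n: int = 50,
    restart: float = 0.75,
    normalization: str = "symmetric",
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    transform: str = "nes_times_neglog10p",
    significance_floor: float = 1.0,
    combine: str = "signed_difference",
    seed: int = 0,
) -> PathwayEmbedding:
    """Full RWR-FGSEA pipeline: expression profile to pathway embedding.

    ``combine='signed_difference'`` runs separate up- and down-seeded
    walks and stores up-score minus down-score, so positive embedding
    values follow up-regulated disease biology; ``combine='single'``
    runs one walk from the union of seeds.
    """
    seeds = select_seed_genes(expr, spec, top_n=top_n)
    component = net.largest_component()
    sub = net.subnetwork(component)
    operator = _normalized_operator(sub, normalization)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    n_genes = net.n_nodes
    perm_matrix = np.argsort(rng.random((n_perm, n_genes)), axis=1)

    def run(seed_genes: list[str]) -> EnrichmentResult:
        affinity = rwr_propagate(
            net,
            seed_genes,
            restart=restart,
            normalization=normalization,
            _operator=operator,
            _component=component,
        )
        return preranked_gsea(
            affinity,
            sets,
            weight_exponent=weight_exponent,
            n_perm=n_perm,
            min_size=min_size,
            max_size=max_size,
            perm_matrix=perm_matrix,
        )

    if combine == "signed_difference":
        up_results, down_results = {}, {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for sample in expr.sample_ids:
                up_results[sample] = run(seeds.up[sample])
                down_results[sample] = run(seeds.down[sample])
        emb_up = build_pathway_embedding(up_results, transform, significance_floor)
        emb_down = build_pathway_embedding(down_results, transform, significance_floor)
        data = emb_up.data - emb_down.data
    elif combine == "single":
        results = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for sample in expr.sample_ids:
                results[sample] = run(seeds.up[sample] + seeds.down[sample])
        data = build_pathway_embedding(results, transform, significance_floor).data
    else:
        raise ValueError(f"unknown combine mode {combine!r}")

    provenance = {
        "method": "rwr_fgsea",
        "top_n": top_n,
        "restart": restart,
        "normalization": normalization,
        "weight_exponent": weight_exponent,
        "n_perm": n_perm,
        "transform": transform,
        "combine": combine,
        "seed": seed,
    }
    return PathwayEmbedding(data, provenance)
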