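"""The five-criterion evaluation protocol for subtyping results.

Separability (average silhouette width), agreement with known labels
(NMI/ARI), batch awareness (cNMI = subtype NMI minus batch NMI),
resampled clustering stability (co-clustering Jaccard / ARI against the
full-data reference), survival relevance (Cox proportional-hazards
likelihood ratio test), the gene-module score, and the informative-
pathway filter (BH-adjusted Kruskal-Wallis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, kruskal, spearmanr
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_samples,
)
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, StabilityError
from .clusterers import ClusteringResult, DissimilarityMatrix
from .netops import EigengeneMatrix
from .io import ClinicalTable
from .rwr_fgsea import PathwayEmbedding

__all__ = [
    "ModuleScoreParams",
    "StabilityReport",
    "CoxLRTResult",
    "silhouette",
    "label_agreement",
    "cnmi",
    "coclustering_jaccard",
    "stability_resample",
    "cox_lrt",
    "module_score",
    "informative_pathways",
]


def _label_array(labels) -> np.ndarray:
    if isinstance(labels, ClusteringResult):
        return labels.labels
    return np.asarray(labels)


@dataclass
class ModuleScoreParams:
    """alpha: |Spearman rho| threshold for counting a cluster as
    associated with a module; beta: fallback score for modules with no
    association in either direction."""

    alpha: float = 0.5
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 <= self.beta <= 1):
            raise ValueError("beta must lie in [0, 1]")


def silhouette(d: DissimilarityMatrix, labels) -> float:
    """Average silhouette width from a precomputed dissimilarity.

    Per-sample s(i) = (b(i) - a(i)) / max(a(i), b(i)); singleton
    clusters and coincident points contribute 0.
    """
    y = _label_array(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("silhouette undefined for a single cluster")
    vals = silhouette_samples(d.data, y, metric="precomputed")
    return float(np.mean(vals))


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def label_agreement(a, b, metric: str = "nmi") -> float:
    """NMI (sqrt normalization) or ARI between two labelings.

    NMI is defined as 0 when either labeling has zero entropy.
    """
    a = _label_array(a)
    b = _label_array(b)
    if len(a) != len(b):
        raise ValueError(f"label length mismatch: {len(a)} vs {len(b)}")
    if metric == "ari":
        return float(adjusted_rand_score(a, b))
    if metric == "nmi":
        if _entropy(a) == 0.0 or _entropy(b) == 0.0:
            return 0.0
        return float(normalized_mutual_info_score(a, b, average_method="geometric"))
    raise ValueError(f"unknown agreement metric {metric!r}")


def cnmi(labels, subtype, batch) -> float:
    """Corrected NMI: NMI(labels, subtype) - NMI(labels, batch).

    Samples with missing subtype or batch are dropped pairwise for the
    corresponding term; NaN is returned when all subtype labels are
    missing.
    """
    y = _label_array(labels)
    s = pd.Series(np.asarray(subtype, dtype=object))
    b = pd.Series(np.asarray(batch, dtype=object))
    s_ok = s.notna().to_numpy()
    b_ok = b.notna().to_numpy()
    if not s_ok.any():
        warnings.warn("cNMI: all subtype labels missing; metric is missing")
        return float("nan")
    nmi_s = label_agreement(y[s_ok], s[s_ok].to_numpy(), "nmi")
    nmi_b = label_agreement(y[b_ok], b[b_ok].to_numpy(), "nmi") if b_ok.any() else 0.0
    return nmi_s - nmi_b


def coclustering_jaccard(a, b) -> float:
    """Jaccard similarity of the two labelings' co-clustered pairs.

    Over all unordered sample pairs, |co-clustered in both| /
    |co-clustered in either|; defined as 1 when neither labeling
    co-clusters any pair.
    """
    a = _label_array(a)
    b = _label_array(b)
    if len(a) != len(b):
        raise ValueError(f"label length mismatch: {len(a)} vs {len(b)}")
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()

    def pairs(x):
        return (x * (x - 1) // 2).sum()

    both = pairs(ct)
    in_a = pairs(ct.sum(axis=1))
    in_b = pairs(ct.sum(axis=0))
    union = in_a + in_b - both
    return 1.0 if union == 0 else float(both / union)


@dataclass
class StabilityReport:
    """Per-resample stability of a clustering pipeline."""

    records: pd.DataFrame  # columns: repeat, fold, jaccard, ari
    folds: int
    repeats: int
    seed: int

    @property
    def mean_jaccard(self) -> float:
        return float(self.records["jaccard"].mean())

    @property
    def sd_jaccard(self) -> float:
        return float(self.records["jaccard"].std(ddof=1))

    @property
    def mean_ari(self) -> float:
        return float(self.records["ari"].mean())

    @property
    def sd_ari(self) -> float:
        return float(self.records["ari"].std(ddof=1))

    @property
    def n_missing(self) -> int:
        return int(self.records["jaccard"].isna().sum())


def stability_resample(
    pipeline,
    data,
    folds: int = 5,
    repeats: int = 20,
    seed: int = 0,
) -> StabilityReport:
    """Resampled clustering stability against the full-data reference.

    ``pipeline(data_subset) -> label array`` must rerun the whole
    feature-extraction + clustering chain. For each of ``repeats``
    shuffled ``folds``-fold partitions, each fold's samples are dropped,
    the pipeline is rerun on the retained fraction, and the labels are
    compared with the reference restricted to the retained samples via
    co-clustering Jaccard and ARI. Pipeline failures are recorded as
    missing; more than 50% failures raise :class:`StabilityError`.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    sample_ids = list(data.sample_ids)
    n = len(sample_ids)
    reference = np.asarray(pipeline(data))
    if len(reference) != n:
        raise ValueError("pipeline returned labels of wrong length")

    rows = []
    for rep in range(repeats):
        splitter = KFold(
            n_splits=folds,
            shuffle=True,
            random_state=int(
                np.random.SeedSequence([int(seed), rep]).generate_state(1)[0]
                % (2**31)
            ),
        )
        for fold, (train_idx, _test_idx) in enumerate(splitter.split(np.arange(n))):
            retained = [sample_ids[i] for i in train_idx]
            try:
                sub_labels = np.asarray(pipeline(data.subset_samples(retained)))
                jac = coclustering_jaccard(reference[train_idx], sub_labels)
                ari = label_agreement(reference[train_idx], sub_labels, "ari")
            except Exception as exc:  # recorded, not fatal
                warnings.warn(f"stability resample ({rep}, {fold}) failed: {exc}")
                jac, ari = np.nan, np.nan
            rows.append((rep, fold, jac, ari))
    records = pd.DataFrame(rows, columns=["repeat", "fold", "jaccard", "ari"])
    if records["jaccard"].isna().mean() > 0.5:
        raise StabilityError("more than half of the stability resamples failed")
    return StabilityReport(records, folds, repeats, seed)


@dataclass
class CoxLRTResult:
    """Likelihood ratio test of cluster membership in a Cox PH model."""

    statistic: float
    df: int
    p_value: float
    hazard_ratios: dict[int, float]  # vs. the first (lowest-label) cluster
    n_used: int
    converged: bool = True
    notes: list[str] = field(default_factory=list)


def cox_lrt(
    clinical: ClinicalTable,
    labels,
    covariates: tuple[str, ...] = (),
    followup_cap: float | None = None,
) -> CoxLRTResult:
    """LRT between a covariate-only Cox model and one adding clusters.

    The alternative model adds k - 1 indicator terms for cluster
    membership; the statistic is 2 * (ll_alt - ll_base) on k - 1
    degrees of freedom. Hazard ratios are reported against the first
    cluster. Samples without survival data, and samples with follow-up
    beyond ``followup_cap``, are excluded.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError as LifelinesConvergence

    y = _label_array(labels)
    df = clinical.data.copy()
    if len(y) != len(df):
        raise ValueError("labels and clinical table length mismatch")
    df = df.assign(_cluster=y)
    df = df[clinical.has_survival.to_numpy()]
    if followup_cap is not None:
        df = df[df["time"] <= followup_cap]
    notes: list[str] = []

    present = sorted(df["_cluster"].unique())
    if len(present) < 2:
        raise DegenerateInputError("need >= 2 clusters among samples with survival")

    design = pd.DataFrame(index=df.index)
    design["time"] = df["time"].astype(float)
    design["event"] = df["event"].astype(int)
    for cov in covariates:
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col):
            design[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            design = design.join(dummies.astype(float))
    base_cols = [c for c in design.columns if c not in ("time", "event")]

    ref = present[0]
    cluster_cols = []
    for lab in present[1:]:
        name = f"cluster_{lab}"
        design[name] = (df["_cluster"] == lab).astype(float)
        cluster_cols.append((lab, name))
        if design.loc[design[name] == 1, "event"].sum() == 0:
            notes.append(f"cluster {lab} has zero events; HR unreliable")

    # penalizer 0 first; a whisper of ridge as fallback for singular
    # designs (e.g. cluster indicators collinear with covariates)
    alt = None
    last_exc: Exception | None = None
    for penalizer in (0.0, 1e-8):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                alt = CoxPHFitter(penalizer=penalizer)
                alt.fit(design, duration_col="time", event_col="event")
                ll_alt = float(alt.log_likelihood_)
                if base_cols:
                    base = CoxPHFitter(penalizer=penalizer)
                    base.fit(
                        design.drop(columns=[c for _, c in cluster_cols]),
                        duration_col="time",
                        event_col="event",
                    )
                    ll_base = float(base.log_likelihood_)
                else:
                    # null partial likelihood recovered from the fitter's
                    # own all-coefficients LRT: stat = 2 (ll_alt - ll_null)
                    full_test = alt.log_likelihood_ratio_test()
                    ll_base = ll_alt - float(full_test.test_statistic) / 2.0
            if penalizer > 0:
                notes.append(f"ridge fallback penalizer={penalizer}")
            break
        except (LifelinesConvergence, np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            alt = None
    if alt is None:
        return CoxLRTResult(
            statistic=float("nan"),
            df=len(present) - 1,
            p_value=float("nan"),
            hazard_ratios={},
            n_used=len(design),
            converged=False,
            notes=notes + [f"non-convergence: {last_exc}"],
        )

    stat = max(0.0, 2.0 * (ll_alt - ll_base))
    dof = len(present) - 1
    p = float(chi2.sf(stat, dof))
    hrs = {ref: 1.0}
    for lab, name in cluster_cols:
        hrs[lab] = float(np.exp(alt.params_[name]))
    return CoxLRTResult(stat, dof, p, hrs, len(design), True, notes)


def module_score(
    eigengenes: EigengeneMatrix,
    labels,
    params: ModuleScoreParams | None = None,
) -> float:
    """Gene-module relevance of a clustering.

    For each module eigen-gene e and cluster one-hot indicator c, count
    S+ = #{clusters with Spearman rho(e, c) >= alpha} and S- with
    rho <= -alpha; the module contributes
    (min(1, S+) + min(1, S-)) / (S+ + S-), or beta when no cluster is
    associated in either direction. The score is the unweighted mean
    over modules: it rewards clusterings where each expression module
    distinguishes few clusters in each direction.
    """
    params = params or ModuleScoreParams()
    y = _label_array(labels)
    eg = eigengenes.data
    if len(y) != eg.shape[0]:
        raise ValueError("labels and eigengene matrix length mismatch")
    ks = np.unique(y)
    if len(ks) < 2:
        raise DegenerateInputError("module score needs k >= 2 clusters")

    values = []
    for col in eg.columns:
        e = eg[col].to_numpy(dtype=float)
        if np.std(e) == 0:
            warnings.warn(f"eigen-gene {col} has zero variance; module skipped")
            continue
        s_pos = s_neg = 0
        for lab in ks:
            c = (y == lab).astype(float)
            rho = spearmanr(e, c).statistic
            if np.isnan(rho):
                continue
            if rho >= params.alpha:
                s_pos += 1
            elif rho <= -params.alpha:
                s_neg += 1
        total = s_pos + s_neg
        if total == 0:
            values.append(params.beta)
        else:
            values.append((min(1, s_pos) + min(1, s_neg)) / total)
    if not values:
        raise DegenerateInputError("no usable eigen-genes for the module score")
    return float(np.mean(values))


def informative_pathways(
    embedding: PathwayEmbedding,
    labels,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pathways whose scores differ between clusters.

    Kruskal-Wallis test per pathway across clusters, Benjamini-Hochberg
    correction over tested pathways; rows with adjusted p below
    ``p_threshold`` are returned sorted by ascending p. Constant
    pathways are skipped (listed in ``result.attrs['skipped']``).
    """
    y = _label_array(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("informative-pathway filter needs k >= 2")
    data = embedding.data
    if data.shape[1] != len(y):
        raise ValueError("labels and embedding sample count mismatch")

    names, stats, pvals, skipped = [], [], [], []
    groups_idx = [np.nonzero(y == lab)[0] for lab in np.unique(y)]
    for pathway in data.index:
        row = data.loc[pathway].to_numpy(dtype=float)
        if np.all(row == row[0]):
            skipped.append(str(pathway))
            continue
        groups = [row[idx] for idx in groups_idx]
        try:
            h, p = kruskal(*groups)
        except ValueError:  # all values identical within the test
            skipped.append(str(pathway))
            continue
        names.append(str(pathway))
        stats.append(float(h))
        pvals.append(float(p))

    if names:
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        p_adj = np.array([])
    table = pd.DataFrame(
        {"pathway": names, "statistic": stats, "p": pvals, "p_adjusted": p_adj}
    )
    table = table.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
    result = table[table["p_adjusted"] < p_threshold].reset_index(drop=True)
    result.attrs["n_tested"] = len(names)
    result.attrs["skipped"] = skipped
    return result
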