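"""Seeded synthetic cohorts with planted structure.

The generator emulates the ingredients a subtyping benchmark needs
without any external downloads:

* expression follows a module latent-factor model — each gene module has
  one latent activity per sample, so modules are genuinely co-expressed
  and eigen-genes have structure to find;
* subtypes shift subtype-specific subsets of module activities up or
  down, batch variables add constant offsets to random gene subsets;
* disease gene lists (split by fold-change sign) are the genes of the
  modules that move in the subtype contrast;
* gene sets and a planted-partition gene network are aligned with the
  true modules to the requested degree;
* survival times are exponential with per-subtype multiplicative
  hazards and independent exponential censoring.

All randomness flows through named, integer-tagged PRNG streams derived
from a single seed, so outputs are bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, GeneNetwork, GeneSetCollection

__all__ = ["SyntheticTruth", "simulate_cohort", "simulate_knowledge", "simulate_survival"]

# stream tags: one independent PRNG stream per generator component
_STREAM_MODULES = 1
_STREAM_FACTORS = 2
_STREAM_LABELS = 3
_STREAM_BATCH = 4
_STREAM_NOISE = 5
_STREAM_SURVIVAL = 6
_STREAM_SETS = 7
_STREAM_NETWORK = 8
_STREAM_COVARIATES = 9


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`simulate_cohort`."""

    true_subtype: np.ndarray  # per-sample int labels 0..k-1
    true_batch: dict[str, np.ndarray]  # batch variable name -> per-sample int labels
    true_modules: dict[str, int]  # gene -> module label, 0 = background
    up_genes: list[str]
    down_genes: list[str]
    hazard_ratios: np.ndarray  # per-subtype, reference = 1
    subtype_shift: np.ndarray = field(default=None)  # (k, n_modules) shift matrix

    @property
    def n_modules(self) -> int:
        labels = set(self.true_modules.values()) - {0}
        return len(labels)

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.true_modules.items() if m == module]


def simulate_cohort(
    n_genes: int = 200,
    n_samples: int = 120,
    k_subtypes: int = 3,
    n_modules: int = 6,
    subtype_effect: float = 4.0,
    batch_effect: float = 1.0,
    n_batches: int = 2,
    noise_sd: float = 1.0,
    seed: int = 0,
    module_fraction: float = 0.8,
    n_batch_vars: int = 1,
    baseline_rate: float = 1e-3,
    censor_rate: float = 5e-4,
    hazard_ratios: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Simulate an expression cohort with planted subtypes.

    Expression model for gene g (module m) in sample s::

        x[g, s] = load[g] * (f[m, s] + shift[subtype(s), m]) + batch + noise

    with latent factors ``f ~ N(0, 1)``, positive gene loadings
    ``load ~ U(0.5, 1.5)``, shifts of magnitude ``subtype_effect`` on a
    subtype-specific subset of modules, batch offsets scaled by
    ``batch_effect`` on a random half of the genes, and i.i.d. Gaussian
    noise with SD ``noise_sd``. Background genes (the ``1 -
    module_fraction`` fraction outside modules) are pure noise.
    Subtype and batch labels are balanced to within one sample.
    """
    if k_subtypes < 2:
        raise ValueError("k_subtypes must be >= 2")
    if k_subtypes > n_samples:
        raise ValueError("k_subtypes cannot exceed n_samples")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if min(n_genes, n_samples) < 2:
        raise ValueError("counts must be positive and >= 2")

    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    sample_ids = [f"s{i:04d}" for i in range(n_samples)]

    # module membership: round-robin over the covered fraction, shuffled
    rng_mod = _rng(seed, _STREAM_MODULES)
    n_covered = int(round(module_fraction * n_genes))
    module_of_gene = np.zeros(n_genes, dtype=int)
    covered = rng_mod.permutation(n_genes)[:n_covered]
    module_of_gene[covered] = (np.arange(n_covered) % n_modules) + 1
    loadings = rng_mod.uniform(0.5, 1.5, size=n_genes)

    # balanced subtype / batch labels
    rng_lab = _rng(seed, _STREAM_LABELS)
    subtype = rng_lab.permutation(np.arange(n_samples) % k_subtypes)
    rng_bat = _rng(seed, _STREAM_BATCH)
    batch_vars: dict[str, np.ndarray] = {}
    for v in range(n_batch_vars):
        name = "batch" if v == 0 else f"batch{v + 1}"
        batch_vars[name] = rng_bat.permutation(np.arange(n_samples) % n_batches)

    # subtype -> module shift pattern: every subtype owns a block of
    # modules and shifts it with alternating sign, so each subtype has a
    # distinct molecular signature (as real disease subtypes do)
    shift = np.zeros((k_subtypes, n_modules))
    blocks = np.array_split(np.arange(n_modules), k_subtypes)
    for t in range(k_subtypes):
        for pos, m in enumerate(blocks[t]):
            shift[t, m] = subtype_effect * (1.0 if pos % 2 == 0 else -1.0)

    # latent factors and expression
    rng_fac = _rng(seed, _STREAM_FACTORS)
    factors = rng_fac.standard_normal((n_modules, n_samples))
    shifted = factors + shift[subtype, :].T  # (n_modules, n_samples)
    expr = np.zeros((n_genes, n_samples))
    in_module = module_of_gene > 0
    expr[in_module] = loadings[in_module, None] * shifted[module_of_gene[in_module] - 1]

    # batch offsets on a random half of the genes
    for name, labels in batch_vars.items():
        affected = rng_bat.random(n_genes) < 0.5
        offsets = rng_bat.standard_normal(n_batches)
        expr[affected] += batch_effect * offsets[labels][None, :]

    rng_noise = _rng(seed, _STREAM_NOISE)
    expr += noise_sd * rng_noise.standard_normal((n_genes, n_samples))

    # disease gene lists: each module is shifted by exactly one subtype;
    # the disease contrast (any subtype vs. an unaffected baseline)
    # moves the module in that shift's direction
    net_shift = shift.sum(axis=0)
    up_genes = [g for g, m in zip(gene_ids, module_of_gene) if m > 0 and net_shift[m - 1] > 0]
    down_genes = [g for g, m in zip(gene_ids, module_of_gene) if m > 0 and net_shift[m - 1] < 0]

    if hazard_ratios is None:
        hazard_ratios = np.array(
            [3.0 ** (t / (k_subtypes - 1)) for t in range(k_subtypes)]
        )
    else:
        hazard_ratios = np.asarray(hazard_ratios, dtype=float)
    time, event = simulate_survival(
        subtype, hazard_ratios, baseline_rate, censor_rate, seed=seed
    )

    rng_cov = _rng(seed, _STREAM_COVARIATES)
    age = np.round(rng_cov.normal(60.0, 10.0, size=n_samples), 1)

    clin = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "subtype": [f"S{t}" for t in subtype],
            "age": age,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for name, labels in batch_vars.items():
        clin[name] = [f"B{b}" for b in labels]

    truth = SyntheticTruth(
        true_subtype=subtype,
        true_batch=batch_vars,
        true_modules=dict(zip(gene_ids, (int(m) for m in module_of_gene))),
        up_genes=up_genes,
        down_genes=down_genes,
        hazard_ratios=hazard_ratios,
        subtype_shift=shift,
    )
    expression = ExpressionMatrix(pd.DataFrame(expr, index=gene_ids, columns=sample_ids))
    clinical = ClinicalTable(clin, covariate_columns=["age"], batch_columns=list(batch_vars))
    return expression, clinical, truth


def simulate_knowledge(
    truth: SyntheticTruth,
    n_sets: int = 15,
    aligned_fraction: float = 1.0,
    p_in: float = 0.9,
    p_out: float = 0.02,
    seed: int = 0,
    set_size_range: tuple[int, int] = (10, 25),
) -> tuple[GeneSetCollection, GeneNetwork]:
    """Generate gene sets and a gene network aligned with planted modules.

    A fraction ``aligned_fraction`` of sets draws at least 80% of its
    members from a single true module (modules cycled); the rest are
    uniform random sets. The network is a planted-partition graph:
    within-module edges with probability ``p_in``, all other pairs with
    probability ``p_out`` (background genes belong to no block).
    """
    if n_sets <= 0:
        raise ValueError("n_sets must be positive")
    if not (0 <= aligned_fraction <= 1):
        raise ValueError("aligned_fraction must lie in [0, 1]")
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")

    genes = list(truth.true_modules)
    module_of = np.array([truth.true_modules[g] for g in genes])
    modules = sorted(set(module_of) - {0})
    if not modules:
        raise ValueError("truth contains no modules to align with")

    rng = _rng(seed, _STREAM_SETS)
    n_aligned = int(round(aligned_fraction * n_sets))
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    lo, hi = set_size_range
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < n_aligned:
            module = modules[i % len(modules)]
            pool = [g for g, m in zip(genes, module_of) if m == module]
            n_core = min(int(np.ceil(0.8 * size)), len(pool))
            core = list(rng.choice(pool, size=n_core, replace=False))
            others = [g for g in genes if g not in set(core)]
            n_fill = min(size - n_core, len(others))
            fill = list(rng.choice(others, size=n_fill, replace=False))
            members, desc = core + fill, f"aligned:module{module}"
        else:
            members = list(rng.choice(genes, size=min(size, len(genes)), replace=False))
            desc = "random"
        name = f"SET{i:03d}"
        sets[name] = members
        descriptions[name] = desc
    collection = GeneSetCollection(sets, descriptions)

    # planted-partition network over all genes
    rng_net = _rng(seed, _STREAM_NETWORK)
    n = len(genes)
    same = (module_of[:, None] == module_of[None, :]) & (module_of[:, None] > 0)
    prob = np.where(same, p_in, p_out)
    u = rng_net.random((n, n))
    upper = np.triu(u < prob, k=1)
    adjacency = (upper | upper.T).astype(float)
    network = GeneNetwork(genes, adjacency)
    return collection, network


def simulate_survival(
    subtype: np.ndarray,
    hazard_ratios: np.ndarray | dict,
    baseline_rate: float,
    censor_rate: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival with per-subtype multiplicative hazards.

    Event times are exponential with rate ``baseline_rate * HR(subtype)``
    and censoring is an independent exponential with rate
    ``censor_rate``; the observed time is the minimum and the event
    indicator marks whether the event preceded censoring.
    """
    if baseline_rate <= 0 or censor_rate <= 0:
        raise ValueError("rates must be > 0")
    subtype = np.asarray(subtype)
    if isinstance(hazard_ratios, dict):
        try:
            hr = np.array([float(hazard_ratios[t]) for t in subtype])
        except KeyError as exc:
            raise ValueError(f"unknown subtype label: {exc.args[0]!r}") from exc
    else:
        hazard_ratios = np.asarray(hazard_ratios, dtype=float)
        labels = subtype.astype(int)
        if labels.min() < 0 or labels.max() >= len(hazard_ratios):
            raise ValueError("subtype label outside hazard_ratios range")
        hr = hazard_ratios[labels]
    if np.any(hr <= 0):
        raise ValueError("hazard ratios must be > 0")

    rng = _rng(seed, _STREAM_SURVIVAL)
    t_event = rng.exponential(1.0 / (baseline_rate * hr))
    t_censor = rng.exponential(1.0 / censor_rate, size=len(subtype))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return time, event
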