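"""Shared fixtures: small synthetic cohorts and derived objects.

Everything is generated programmatically and seeded; session scope is
used for the objects that are expensive to build (the pathway
embedding in particular) so independent tests can share them.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

import subtypebench as sb


@pytest.fixture(scope="session")
def cohort():
    """Small cohort with planted subtypes (60 samples, 120 genes)."""
    expr, clinical, truth = sb.simulate_cohort(
        n_genes=120, n_samples=60, k_subtypes=3, n_modules=6, seed=7
    )
    return expr, clinical, truth


@pytest.fixture(scope="session")
def knowledge(cohort):
    _, _, truth = cohort
    sets, net = sb.simulate_knowledge(truth, n_sets=12, seed=7)
    return sets, net


@pytest.fixture(scope="session")
def pathway_embedding(cohort, knowledge):
    expr, _, truth = cohort
    sets, net = knowledge
    spec = sb.SeedSpec(truth.up_genes, truth.down_genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sb.rwr_fgsea_embedding(
            expr, spec, net, sets, top_n=30, n_perm=500, seed=7
        )


@pytest.fixture()
def blobs():
    """Three well-separated Gaussian blobs as an Embedding."""
    rng = np.random.default_rng(0)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    labels = np.repeat([0, 1, 2], 20)
    points = centers[labels] + rng.normal(scale=0.5, size=(60, 2))
    df = pd.DataFrame(
        points, index=[f"s{i}" for i in range(60)], columns=["dim1", "dim2"]
    )
    return sb.Embedding(df, "fixture"), labels
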