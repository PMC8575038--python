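"""Evaluation metrics against brute-force oracles and limit cases."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import subtypebench as sb
from subtypebench.errors import DegenerateInputError, StabilityError
from subtypebench.clusterers import DissimilarityMatrix
from subtypebench.netops import EigengeneMatrix
from subtypebench.synthdata import simulate_survival
from oracles import (
    brute_force_ari,
    brute_force_module_score,
    brute_force_nmi,
    brute_force_silhouette,
)


class TestSilhouette:
    def test_two_tight_far_pairs(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        d = np.abs(pts - pts.T)
        dm = DissimilarityMatrix(d, "l1", list("abcd"))
        assert sb.silhouette(dm, [1, 1, 2, 2]) >= 0.95

    def test_coincident_points_score_zero(self):
        dm = DissimilarityMatrix(np.zeros((4, 4)), "l1", list("abcd"))
        assert sb.silhouette(dm, [1, 1, 2, 2]) == 0.0

    def test_matches_per_point_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.random((15, 15))
            d = np.triu(x, 1)
            d = d + d.T
            labels = rng.integers(1, 4, size=15)
            if len(set(labels)) < 2:
                continue
            dm = DissimilarityMatrix(d, "r", [f"s{i}" for i in range(15)])
            assert sb.silhouette(dm, labels) == pytest.approx(
                brute_force_silhouette(d, labels), abs=1e-12
            )

    def test_single_cluster_rejected(self):
        dm = DissimilarityMatrix(np.zeros((3, 3)), "l1", list("abc"))
        with pytest.raises(DegenerateInputError):
            sb.silhouette(dm, [1, 1, 1])


class TestAgreement:
    def test_identity_and_constant_conventions(self):
        labels = [1, 1, 2, 2, 3]
        assert sb.label_agreement(labels, labels, "nmi") == pytest.approx(1.0)
        assert sb.label_agreement(labels, labels, "ari") == pytest.approx(1.0)
        assert sb.label_agreement(labels, [1, 1, 1, 1, 1], "nmi") == 0.0

    def test_matches_contingency_oracles(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.integers(0, 3, size=30)
            b = rng.integers(0, 4, size=30)
            assert sb.label_agreement(a, b, "nmi") == pytest.approx(
                brute_force_nmi(a, b), abs=1e-12
            )
            assert sb.label_agreement(a, b, "ari") == pytest.approx(
                brute_force_ari(a, b), abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sb.label_agreement([1, 2], [1, 2, 3])


class TestCNMI:
    def test_limit_cases(self):
        rng = np.random.default_rng(2)
        subtype = np.arange(400) % 3
        batch = rng.integers(0, 2, size=400)
        assert sb.cnmi(subtype, subtype, batch) >= 0.9
        assert sb.cnmi(batch, subtype, batch) <= -0.9
        assert sb.cnmi(subtype, subtype, subtype) == pytest.approx(0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 3, size=50)
        s = rng.integers(0, 3, size=50)
        b = rng.integers(0, 2, size=50)
        assert sb.cnmi(y, s, b) == pytest.approx(-sb.cnmi(y, b, s), abs=1e-12)

    def test_all_missing_subtype_flagged(self):
        with pytest.warns(UserWarning):
            out = sb.cnmi([1, 2], [None, None], [1, 2])
        assert np.isnan(out)


class TestJaccard:
    def test_worked_examples(self):
        assert sb.coclustering_jaccard([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert sb.coclustering_jaccard([1, 1, 2, 2], [1, 2, 1, 2]) == 0.0
        assert sb.coclustering_jaccard([1, 1, 1], [1, 1, 2]) == pytest.approx(1 / 3)

    def test_symmetric_and_label_permutation_invariant(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, size=40)
        b = rng.integers(0, 3, size=40)
        assert sb.coclustering_jaccard(a, b) == pytest.approx(
            sb.coclustering_jaccard(b, a)
        )
        relabeled = np.array([{0: 7, 1: 5, 2: 9}[x] for x in a])
        assert sb.coclustering_jaccard(a, b) == pytest.approx(
            sb.coclustering_jaccard(relabeled, b)
        )

    def test_all_singletons_convention(self):
        assert sb.coclustering_jaccard([1, 2, 3], [3, 2, 1]) == 1.0


class TestStability:
    def test_resample_invariant_pipeline_scores_one(self, cohort):
        expr, _, _ = cohort

        def pipeline(data):
            # fixed hash of the sample ID: invariant across resamples
            return np.array([hash(s) % 3 + 1 for s in data.sample_ids])

        report = sb.stability_resample(pipeline, expr, folds=5, repeats=2, seed=0)
        assert (report.records["jaccard"] == 1.0).all()
        assert (report.records["ari"] == 1.0).all()

    def test_blob_pipeline_is_stable(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [12, 0], [0, 12]])
        labels = np.repeat([0, 1, 2], 30)
        x = centers[labels] + rng.normal(scale=0.5, size=(90, 2))
        expr = sb.ExpressionMatrix(
            pd.DataFrame(
                x.T, index=["f1", "f2"], columns=[f"s{i}" for i in range(90)]
            )
        )

        def pipeline(data):
            emb = sb.reduce_dimensionality(data, "pca", 1)
            return sb.run_partitioner(emb, "kmeans", 3, seed=0).labels

        report = sb.stability_resample(pipeline, expr, folds=5, repeats=4, seed=1)
        assert report.mean_jaccard >= 0.9

    def test_default_protocol_yields_100_resamples(self, cohort):
        expr, _, _ = cohort

        def pipeline(data):
            return np.array([hash(s) % 2 + 1 for s in data.sample_ids])

        report = sb.stability_resample(pipeline, expr, folds=5, repeats=20, seed=0)
        assert len(report.records) == 100

    def test_majority_failures_raise(self, cohort):
        expr, _, _ = cohort
        state = {"n": 0}

        def pipeline(data):
            if len(data.sample_ids) < expr.n_samples:
                raise RuntimeError("boom")
            return np.ones(len(data.sample_ids), dtype=int)

        with pytest.raises(StabilityError), pytest.warns(UserWarning):
            sb.stability_resample(pipeline, expr, folds=2, repeats=2, seed=0)


class TestCoxLRT:
    def test_redundant_cluster_variable_gives_null_result(self):
        y = np.arange(200) % 2
        t, e = simulate_survival(y, np.array([1.0, 1.0]), 1e-3, 5e-4, seed=1)
        grp = np.where(y == 0, "a", "b")
        clin = sb.ClinicalTable(
            pd.DataFrame(
                {"time": t, "event": e, "grp": grp},
                index=[f"s{i}" for i in range(200)],
            ),
            covariate_columns=["grp"],
        )
        res = sb.cox_lrt(clin, y + 1, covariates=("grp",))
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-4)

    def test_df_is_k_minus_one(self):
        y = np.arange(300) % 3
        t, e = simulate_survival(y, np.array([1.0, 1.5, 2.0]), 1e-3, 5e-4, seed=2)
        clin = sb.ClinicalTable(
            pd.DataFrame({"time": t, "event": e}, index=[f"s{i}" for i in range(300)])
        )
        assert sb.cox_lrt(clin, y + 1).df == 2

    def test_power_against_planted_hazard(self):
        hits = 0
        for seed in range(10):
            y = np.arange(300) % 2
            t, e = simulate_survival(y, np.array([1.0, 3.0]), 1e-3, 5e-4, seed=seed)
            clin = sb.ClinicalTable(
                pd.DataFrame(
                    {"time": t, "event": e}, index=[f"s{i}" for i in range(300)]
                )
            )
            hits += sb.cox_lrt(clin, y + 1).p_value < 0.01
        assert hits >= 9

    def test_followup_cap_excludes_long_followup(self):
        y = np.arange(200) % 2
        t, e = simulate_survival(y, np.array([1.0, 2.0]), 1e-3, 5e-4, seed=3)
        clin = sb.ClinicalTable(
            pd.DataFrame({"time": t, "event": e}, index=[f"s{i}" for i in range(200)])
        )
        capped = sb.cox_lrt(clin, y + 1, followup_cap=float(np.median(t)))
        assert capped.n_used <= 101


class TestModuleScore:
    @staticmethod
    def _eigengenes(matrix, samples):
        df = pd.DataFrame(
            matrix, index=samples,
            columns=[f"ME{i + 1}" for i in range(matrix.shape[1])],
        )
        return EigengeneMatrix(df, {i + 1: 1.0 for i in range(matrix.shape[1])})

    def test_two_cluster_sign_flip_identity(self):
        rng = np.random.default_rng(6)
        labels = np.array([1] * 10 + [2] * 10)
        e = np.where(labels == 1, 1.0, -1.0) + rng.normal(scale=0.1, size=20)
        eg = self._eigengenes(e[:, None], [f"s{i}" for i in range(20)])
        assert sb.module_score(eg, labels) == pytest.approx(1.0)

    def test_two_same_sign_clusters_give_half(self):
        # clusters 1 and 2 sit high on the eigen-gene (rho ~ 0.61 each),
        # the three low clusters each correlate only ~ -0.41, inside
        # alpha = 0.5: S+ = 2, S- = 0 -> (1 + 0) / 2
        labels = np.repeat([1, 2, 3, 4, 5], 10)
        e = np.concatenate([np.ones(20), np.full(30, -2 / 3)])
        eg = self._eigengenes(e[:, None], [f"s{i}" for i in range(50)])
        assert sb.module_score(eg, labels) == pytest.approx(0.5)

    def test_mixed_sign_arithmetic(self):
        # S+ = 2, S- = 1 -> (1 + 1) / 3 with a balanced step profile
        labels = np.array([1] * 10 + [2] * 10 + [3] * 20)
        e = np.concatenate([np.ones(20), -np.ones(20)])
        eg = self._eigengenes(e[:, None], [f"s{i}" for i in range(40)])
        assert sb.module_score(eg, labels) == pytest.approx(2 / 3)

    def test_no_association_returns_beta(self):
        rng = np.random.default_rng(7)
        labels = np.array([1, 2] * 15)
        e = rng.normal(size=30)
        eg = self._eigengenes(e[:, None], [f"s{i}" for i in range(30)])
        params = sb.ModuleScoreParams(alpha=0.99, beta=0.0)
        assert sb.module_score(eg, labels, params) == 0.0
        params_b = sb.ModuleScoreParams(alpha=0.99, beta=0.25)
        assert sb.module_score(eg, labels, params_b) == 0.25

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(12, 40))
            n_modules = int(rng.integers(1, 6))
            k = int(rng.integers(2, 6))
            labels = rng.integers(1, k + 1, size=n)
            labels[:k] = np.arange(1, k + 1)  # ensure every cluster occurs
            e = rng.normal(size=(n, n_modules))
            eg = self._eigengenes(e, [f"s{i}" for i in range(n)])
            params = sb.ModuleScoreParams(alpha=0.3, beta=0.1)
            assert sb.module_score(eg, labels, params) == pytest.approx(
                brute_force_module_score(eg.data, labels, 0.3, 0.1), abs=1e-12
            )


class TestInformativePathways:
    def test_constant_pathway_skipped(self, pathway_embedding, cohort):
        _, _, truth = cohort
        emb = sb.PathwayEmbedding(pathway_embedding.data.copy())
        emb.data.iloc[0] = 5.0  # constant row
        result = sb.informative_pathways(emb, truth.true_subtype + 1)
        assert emb.data.index[0] in result.attrs["skipped"]

    def test_separating_pathway_ranks_first(self):
        rng = np.random.default_rng(9)
        labels = np.array([1] * 50 + [2] * 50)
        data = rng.normal(size=(5, 100))
        data[2] = np.where(labels == 1, 0.0, 10.0) + rng.normal(scale=0.1, size=100)
        emb = sb.PathwayEmbedding(
            pd.DataFrame(
                data,
                index=[f"P{i}" for i in range(5)],
                columns=[f"s{i}" for i in range(100)],
            )
        )
        result = sb.informative_pathways(emb, labels, p_threshold=0.05)
        assert result.iloc[0]["pathway"] == "P2"

    def test_label_permutation_null_is_uniform(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(1, 60))
        emb = sb.PathwayEmbedding(
            pd.DataFrame(data, index=["P0"], columns=[f"s{i}" for i in range(60)])
        )
        labels = np.array([1] * 30 + [2] * 30)
        pvals = []
        for _ in range(200):
            perm = rng.permutation(labels)
            res = sb.informative_pathways(emb, perm, p_threshold=1.1)
            pvals.append(res.iloc[0]["p"])
        assert kstest(pvals, "uniform").pvalue > 0.01
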