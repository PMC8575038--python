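"""Seed selection, random walk with restart, pre-ranked GSEA, embedding."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal

import subtypebench as sb
from subtypebench.errors import DegenerateInputError, SeedGeneError
from subtypebench.rwr_fgsea import _normalized_operator
from oracles import brute_force_es


class TestSeedSelection:
    def test_full_lists_used_when_top_n_covers_them(self):
        rng = np.random.default_rng(0)
        expr = sb.ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(6, 4)),
                index=[f"g{i}" for i in range(6)],
                columns=list("abcd"),
            )
        )
        spec = sb.SeedSpec(["g0", "g1"], ["g2", "g3"])
        seeds = sb.select_seed_genes(expr, spec, top_n=2)
        for s in "abcd":
            assert sorted(seeds.up[s]) == ["g0", "g1"]
            assert sorted(seeds.down[s]) == ["g2", "g3"]

    def test_hand_computed_z_scores_pick_per_sample_seeds(self):
        # g1 high in sample A, g2 high in sample B (z-scores flip)
        df = pd.DataFrame(
            {"A": [5.0, 1.0, 0.0], "B": [1.0, 5.0, 0.0], "C": [3.0, 3.0, 0.1]},
            index=["g1", "g2", "g3"],
        )
        expr = sb.ExpressionMatrix(df)
        spec = sb.SeedSpec(["g1", "g2"], ["g3"])
        seeds = sb.select_seed_genes(expr, spec, top_n=1)
        assert seeds.up["A"] == ["g1"]
        assert seeds.up["B"] == ["g2"]

    def test_absent_genes_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        expr = sb.ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(3, 3)),
                index=["g0", "g1", "g2"],
                columns=list("abc"),
            )
        )
        spec = sb.SeedSpec(["g0", "missing"], ["g1"])
        with pytest.warns(UserWarning):
            seeds = sb.select_seed_genes(expr, spec, top_n=1)
        assert seeds.up["a"] == ["g0"]


class TestRWR:
    def test_restart_one_returns_seed_distribution(self):
        net = sb.GeneNetwork.from_edges([("a", "b"), ("b", "c")])
        aff = sb.rwr_propagate(net, ["a"], restart=1.0)
        np.testing.assert_allclose(aff.to_numpy(), [1.0, 0.0, 0.0], atol=1e-12)

    def test_two_node_worked_case(self):
        net = sb.GeneNetwork.from_edges([("n1", "n2")])
        aff = sb.rwr_propagate(net, ["n1"], restart=0.5, normalization="symmetric")
        np.testing.assert_allclose(aff.to_numpy(), [2 / 3, 1 / 3], atol=1e-9)

    @pytest.mark.parametrize("normalization", ["symmetric", "row-stochastic"])
    def test_matches_dense_linear_solve(self, normalization):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(5, 51))
            a = np.triu((rng.random((n, n)) < 0.2).astype(float), 1)
            a = a + a.T
            for i in range(n - 1):  # keep connected
                a[i, i + 1] = a[i + 1, i] = 1.0
            nodes = [f"g{i}" for i in range(n)]
            net = sb.GeneNetwork(nodes, a)
            seeds = list(rng.choice(nodes, size=3, replace=False))
            aff = sb.rwr_propagate(net, seeds, restart=0.75, normalization=normalization)
            w = _normalized_operator(net, normalization)
            p0 = np.zeros(n)
            p0[[nodes.index(s) for s in seeds]] = 1 / 3
            oracle = 0.75 * np.linalg.solve(np.eye(n) - 0.25 * w, p0)
            assert np.abs(aff.to_numpy() - oracle).sum() <= 1e-8

    def test_row_stochastic_conserves_probability(self):
        rng = np.random.default_rng(3)
        a = np.triu((rng.random((30, 30)) < 0.3).astype(float), 1)
        a = a + a.T
        for i in range(29):
            a[i, i + 1] = a[i + 1, i] = 1.0
        net = sb.GeneNetwork([f"g{i}" for i in range(30)], a)
        aff = sb.rwr_propagate(net, ["g0", "g5"], normalization="row-stochastic")
        assert abs(aff.sum() - 1.0) <= 1e-10

    def test_seeds_outside_network_rejected(self):
        net = sb.GeneNetwork.from_edges([("a", "b")])
        with pytest.raises(SeedGeneError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sb.rwr_propagate(net, ["zzz"])


class TestGSEA:
    def test_top_singleton_set_scores_one(self):
        scores = pd.Series([4.0, 3.0, 2.0, 1.0], index=["g1", "g2", "g3", "g4"])
        sets = sb.GeneSetCollection({"top": ["g1"]})
        res = sb.preranked_gsea(scores, sets, min_size=1, n_perm=100, seed=0)
        assert res.table.loc["top", "es"] == pytest.approx(1.0)

    def test_bottom_set_scores_negative(self):
        scores = pd.Series(np.arange(10, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(10)])
        sets = sb.GeneSetCollection({"bottom": ["g8", "g9"]})
        res = sb.preranked_gsea(scores, sets, min_size=1, n_perm=100, seed=0)
        assert res.table.loc["bottom", "es"] < 0

    def test_es_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        for trial in range(10):
            scores = pd.Series(rng.normal(size=40) ** 2, index=genes)
            members = list(rng.choice(genes, size=8, replace=False))
            sets = sb.GeneSetCollection({"s": members})
            res = sb.preranked_gsea(scores, sets, n_perm=10, seed=trial)
            assert res.table.loc["s", "es"] == pytest.approx(
                brute_force_es(scores, members), abs=1e-12
            )

    def test_permutation_p_matches_exhaustive_enumeration(self):
        genes = [f"g{i}" for i in range(6)]
        scores = pd.Series([5.0, 4.0, 3.0, 2.5, 1.0, 0.5], index=genes)
        members = ["g1", "g4"]
        sets = sb.GeneSetCollection({"s": members})
        # exhaustive null: every unordered position pair exactly once
        slots = [genes.index(g) for g in members]
        perm_rows = []
        for pair in itertools.combinations(range(6), 2):
            row = np.empty(6, dtype=int)
            row[slots[0]], row[slots[1]] = pair
            rest = [x for x in range(6) if x not in pair]
            row[[i for i in range(6) if i not in slots]] = rest
            perm_rows.append(row)
        perm_matrix = np.array(perm_rows)
        res = sb.preranked_gsea(
            scores, sets, min_size=1, perm_matrix=perm_matrix
        )
        es = res.table.loc["s", "es"]
        null = []
        order = sorted(genes, key=lambda g: (-scores[g], g))
        for pair in itertools.combinations(range(6), 2):
            null.append(
                brute_force_es(scores, [order[pair[0]], order[pair[1]]])
            )
        null = np.array(null)
        same = null >= 0 if es >= 0 else null < 0
        expect_p = (1 + (np.abs(null[same]) >= abs(es)).sum()) / (1 + same.sum())
        assert res.table.loc["s", "p"] == pytest.approx(expect_p, abs=1e-12)

    def test_es_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(20)]
        scores = pd.Series(rng.random(20) + 0.1, index=genes)
        sets = sb.GeneSetCollection({"s": genes[3:9]})
        for exponent in (0.0, 1.0):
            a = sb.preranked_gsea(scores, sets, weight_exponent=exponent, n_perm=10, seed=1)
            b = sb.preranked_gsea(
                scores * 7.3, sets, weight_exponent=exponent, n_perm=10, seed=1
            )
            assert a.table.loc["s", "es"] == pytest.approx(
                b.table.loc["s", "es"], abs=1e-12
            )

    def test_constant_scores_degenerate(self):
        scores = pd.Series(np.ones(10), index=[f"g{i}" for i in range(10)])
        sets = sb.GeneSetCollection({"s": ["g1", "g2", "g3", "g4", "g5"]})
        with pytest.raises(DegenerateInputError):
            sb.preranked_gsea(scores, sets)

    def test_undersized_set_skipped(self):
        scores = pd.Series(np.arange(10, dtype=float), index=[f"g{i}" for i in range(10)])
        sets = sb.GeneSetCollection({"tiny": ["g1", "g2"]})
        res = sb.preranked_gsea(scores, sets, min_size=5, n_perm=10)
        assert bool(res.table.loc["tiny", "skipped"])


class TestEmbeddingAssembly:
    @staticmethod
    def _result(nes_p):
        rows = [
            (name, np.sign(nes), nes, p, 0, 10, False)
            for name, (nes, p) in nes_p.items()
        ]
        table = pd.DataFrame(
            rows,
            columns=["set", "es", "nes", "p", "n_more_extreme", "size_used", "skipped"],
        ).set_index("set")
        return sb.EnrichmentResult(table)

    def test_p_one_gives_zero_score(self):
        emb = sb.build_pathway_embedding({"s1": self._result({"A": (2.0, 1.0)})})
        assert emb.data.loc["A", "s1"] == 0.0

    def test_worked_arithmetic(self):
        emb = sb.build_pathway_embedding({"s1": self._result({"A": (2.0, 0.01)})})
        assert emb.data.loc["A", "s1"] == pytest.approx(4.0)

    def test_inconsistent_universes_rejected(self):
        with pytest.raises(ValueError):
            sb.build_pathway_embedding(
                {
                    "s1": self._result({"A": (1.0, 0.5)}),
                    "s2": self._result({"B": (1.0, 0.5)}),
                }
            )


class TestPipeline:
    def test_deterministic(self, cohort, knowledge):
        expr, _, truth = cohort
        sets, net = knowledge
        spec = sb.SeedSpec(truth.up_genes, truth.down_genes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = sb.rwr_fgsea_embedding(expr, spec, net, sets, top_n=20, n_perm=200, seed=3)
            b = sb.rwr_fgsea_embedding(expr, spec, net, sets, top_n=20, n_perm=200, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_aligned_pathways_separate_subtypes(self, cohort, knowledge, pathway_embedding):
        _, _, truth = cohort
        sets, _ = knowledge
        y = truth.true_subtype
        aligned = [
            n for n in pathway_embedding.pathway_ids
            if sets.descriptions[n].startswith("aligned")
        ]
        pvals = []
        for name in aligned:
            row = pathway_embedding.data.loc[name].to_numpy()
            pvals.append(kruskal(*[row[y == t] for t in np.unique(y)]).pvalue)
        assert np.median(pvals) < 0.01
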