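"""Shapley attributions: closed-form agreement, rollups, overlap statistic."""

import numpy as np
import pytest

from hallmarkgraph import interpretation as itp
from hallmarkgraph.embedding import ExpressionMatrix
from hallmarkgraph.knowledge_graph import GeneUniverse, HallmarkGeneSets


class TestSamplingShapley:
    def test_constant_model_gets_zero_attributions(self):
        rng = np.random.default_rng(0)
        f = lambda X: np.full((len(X), 2), 0.5)
        phi = itp.sampling_shapley(
            f, rng.normal(size=(10, 4)), rng.normal(size=(3, 4)),
            n_permutations=5, rng=rng,
        )
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_linear_model_matches_closed_form(self):
        rng = np.random.default_rng(1)
        F, C = 6, 2
        W = rng.normal(size=(F, C))
        f = lambda X: X @ W
        background = rng.normal(size=(200, F))
        X = rng.normal(size=(4, F))
        phi = itp.sampling_shapley(f, background, X, n_permutations=300, rng=rng)
        expected = itp.linear_shapley(W, background, X)
        # sampling error scales with background spread / sqrt(n_permutations)
        np.testing.assert_allclose(phi, expected, atol=0.25)

    def test_single_used_feature_gets_all_mass(self):
        rng = np.random.default_rng(2)
        f = lambda X: X[:, [0]] * 2.0  # ignores feature 1
        phi = itp.sampling_shapley(
            f, rng.normal(size=(50, 2)), rng.normal(size=(5, 2)),
            n_permutations=20, rng=rng,
        )
        np.testing.assert_allclose(phi[:, 1, :], 0.0, atol=1e-12)
        assert np.abs(phi[:, 0, :]).sum() > 0

    def test_efficiency_per_permutation(self):
        # summed contributions reconstruct f(x) - f(background draw) exactly
        rng = np.random.default_rng(3)
        F = 5
        W = rng.normal(size=(F, 1))
        f = lambda X: X @ W
        background = rng.normal(size=(1, F))  # single reference
        x = rng.normal(size=(1, F))
        phi = itp.sampling_shapley(f, background, x, n_permutations=7, rng=rng)
        np.testing.assert_allclose(
            phi.sum(axis=1), f(x) - f(background), atol=1e-10
        )

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            itp.sampling_shapley(lambda X: X, np.empty((0, 2)), np.ones((1, 2)),
                                 rng=np.random.default_rng(0))


class TestAttributionRollups:
    @staticmethod
    def attribution(values, genes=None):
        values = np.asarray(values, dtype=float)
        genes = genes or tuple(f"G{i}" for i in range(values.shape[0]))
        return itp.AttributionMatrix(
            values=values, genes=tuple(genes), n_background=1, n_explained=1
        )

    def test_gene_score_sums_hallmark_copies(self):
        attr = self.attribution([[0.1, 0.2], [0.3, 0.0]])
        ranking = itp.rank_genes(attr)
        assert ranking.genes == ("G0", "G1")
        assert ranking.scores[0] == pytest.approx(0.3 / 0.6)

    def test_normalized_scores_sum_to_one(self):
        rng = np.random.default_rng(4)
        attr = self.attribution(rng.uniform(0, 1, size=(7, 3)))
        assert sum(attr.gene_scores().values()) == pytest.approx(1.0, abs=1e-12)

    def test_tied_scores_order_alphabetically(self):
        attr = self.attribution([[0.2], [0.2], [0.2]], genes=("B", "C", "A"))
        assert itp.rank_genes(attr).genes == ("A", "B", "C")

    def test_hallmark_contribution_endpoints_and_interior(self):
        universe = GeneUniverse(genes=("G0", "G1", "G2"))
        sets = HallmarkGeneSets(
            names=("H0", "H1", "H2"),
            sets=(frozenset({"G0", "G1", "G2"}),) * 3,
        )
        # raw sums 3, 6, 12 over 3 genes each -> raw [1, 2, 4] -> [0, 1/3, 1]
        attr = self.attribution(np.array([[1.0, 2.0, 4.0]] * 3))
        contrib = itp.hallmark_contribution(attr, sets, universe)
        assert contrib.raw == pytest.approx((1.0, 2.0, 4.0))
        assert contrib.normalized == pytest.approx((0.0, 1 / 3, 1.0))

    def test_two_hallmark_minmax_endpoints(self):
        universe = GeneUniverse(genes=("G0",))
        sets = HallmarkGeneSets(names=("H0", "H1"),
                                sets=(frozenset({"G0"}), frozenset({"G0"})))
        attr = self.attribution([[0.2, 0.6]], genes=("G0",))
        contrib = itp.hallmark_contribution(attr, sets, universe)
        assert contrib.normalized == pytest.approx((0.0, 1.0))

    def test_all_equal_raws_normalize_to_zero(self):
        universe = GeneUniverse(genes=("G0",))
        sets = HallmarkGeneSets(names=("H0", "H1"),
                                sets=(frozenset({"G0"}), frozenset({"G0"})))
        attr = self.attribution([[0.4, 0.4]], genes=("G0",))
        assert itp.hallmark_contribution(attr, sets, universe).normalized == (0.0, 0.0)

    def test_contribution_invariant_to_gene_permutation_within_hallmark(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 1, size=(6, 2))
        genes = tuple(f"G{i}" for i in range(6))
        universe = GeneUniverse(genes=genes)
        sets = HallmarkGeneSets(names=("H0", "H1"),
                                sets=(frozenset(genes), frozenset(genes)))
        base = itp.hallmark_contribution(self.attribution(values, genes), sets, universe)
        perm = rng.permutation(6)
        permuted = itp.hallmark_contribution(
            self.attribution(values[perm], tuple(genes[i] for i in perm)), sets, universe
        )
        assert base.raw == pytest.approx(permuted.raw)


class TestTopGeneOverlap:
    @staticmethod
    def ranking(genes):
        return itp.GeneRanking(genes=tuple(genes), scores=tuple(
            np.linspace(1, 0, len(genes))
        ))

    def test_identical_rankings_overlap_one(self):
        r = self.ranking([f"G{i}" for i in range(10)])
        np.testing.assert_array_equal(itp.top_gene_overlap([r, r], k=5), np.ones((2, 2)))

    def test_disjoint_topk_overlap_zero(self):
        a = self.ranking([f"A{i}" for i in range(10)])
        b = self.ranking([f"B{i}" for i in range(10)])
        assert itp.top_gene_overlap([a, b], k=10)[0, 1] == 0.0

    def test_random_rankings_match_hypergeometric_expectation(self):
        # two independent uniform rankings over N genes share on average
        # k/N of their top-k sets
        rng = np.random.default_rng(6)
        N, k = 6448, 2000
        genes = [f"G{i}" for i in range(N)]
        overlaps = []
        for _ in range(20):
            a = self.ranking(rng.permutation(genes))
            b = self.ranking(rng.permutation(genes))
            overlaps.append(itp.top_gene_overlap([a, b], k=k)[0, 1])
        assert np.mean(overlaps) == pytest.approx(k / N, abs=0.02)

    def test_k_larger_than_ranking_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            itp.top_gene_overlap([self.ranking(["A"])], k=2)


class TestGeneCorrelation:
    @staticmethod
    def expression(values, genes):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            values=values, genes=tuple(genes),
            sample_ids=tuple(f"s{i}" for i in range(values.shape[1])),
        )

    def test_self_correlation_is_one_and_anticorrelation_minus_one(self):
        x = np.linspace(0, 1, 10)
        X = self.expression(np.vstack([x, 1 - x]), ("A", "B"))
        corr = itp.gene_correlation(X, ["A", "B"])
        assert corr[0, 0] == pytest.approx(1.0)
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_planted_bivariate_correlation_recovered(self):
        rng = np.random.default_rng(7)
        n, r = 500, 0.8
        z = rng.normal(size=n)
        a = z
        b = r * z + np.sqrt(1 - r**2) * rng.normal(size=n)
        X = self.expression(np.vstack([a, b]), ("A", "B"))
        corr = itp.gene_correlation(X, ["A", "B"])
        assert corr[0, 1] == pytest.approx(r, abs=0.05)

    def test_zero_variance_gene_reported_missing(self):
        X = self.expression(np.vstack([np.ones(5), np.arange(5.0)]), ("A", "B"))
        corr = itp.gene_correlation(X, ["A", "B"])
        assert np.isnan(corr[0, 0]) and np.isnan(corr[0, 1])
        assert corr[1, 1] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        X = self.expression(np.ones((2, 2)), ("A", "B"))
        with pytest.raises(ValueError, match="3 samples"):
            itp.gene_correlation(X, ["A"])
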