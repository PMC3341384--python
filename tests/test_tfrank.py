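"""Heat-kernel diffusion and transcription-factor ranking."""

import numpy as np
import pytest
from scipy.linalg import expm

from regsnap.expression import ExpressionMatrix
from regsnap.network import read_edge_list, transition_matrix, transpose
from regsnap.biclustering import CCCBicluster
from regsnap.tfrank import (
    DiffusionParams,
    PreferenceVector,
    build_preference_vector,
    heat_kernel_diffuse,
    rank_module_over_time,
    rank_regulators,
)
from regsnap.synthetic import generate_planted_expression, generate_planted_network

from conftest import random_walk_matrix


class TestDiffusionParams:
    def test_defaults_match_method_parameterization(self):
        p = DiffusionParams()
        assert p.t == 0.25 and p.Z == 100

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            DiffusionParams(t=-0.1)
        with pytest.raises(ValueError):
            DiffusionParams(Z=0)

    def test_large_step_warns(self):
        with pytest.warns(UserWarning, match="simplex"):
            DiffusionParams(t=2.0, Z=1)


class TestPreferenceVector:
    def test_absolute_values_of_module_expression(self, edge_tsv):
        net = read_edge_list(edge_tsv)
        expr = ExpressionMatrix(
            ["g1", "g2"], ["t1", "t2"], np.array([[-1.5, 0.0], [2.0, 0.0]])
        )
        p0 = build_preference_vector({"g1", "g2"}, expr, "t1", net)
        assert p0.p0[net.index_of("g1")] == 1.5
        assert p0.p0[net.index_of("g2")] == 2.0
        assert p0.p0.sum() == pytest.approx(3.5)

    def test_gene_absent_from_network_excluded(self, edge_tsv):
        net = read_edge_list(edge_tsv)
        expr = ExpressionMatrix(
            ["g1", "gX"], ["t1", "t2"], np.array([[1.0, 0.0], [9.0, 0.0]])
        )
        p0 = build_preference_vector({"g1", "gX"}, expr, "t1", net)
        assert p0.excluded == ["gX"]
        assert p0.p0.sum() == pytest.approx(1.0)

    def test_all_genes_absent_errors(self, edge_tsv):
        net = read_edge_list(edge_tsv)
        expr = ExpressionMatrix(
            ["gX", "gY"], ["t1", "t2"], np.array([[1.0, 0.0], [2.0, 0.0]])
        )
        with pytest.raises(ValueError):
            build_preference_vector({"gX", "gY"}, expr, "t1", net)


class TestHeatKernelDiffuse:
    def test_t_zero_is_identity(self):
        rng = np.random.default_rng(0)
        W = random_walk_matrix(rng, 12)
        p0 = rng.random(12)
        out = heat_kernel_diffuse(p0, W, DiffusionParams(t=0.0, Z=50))
        np.testing.assert_array_equal(out, p0)

    def test_three_vertex_chain_against_matrix_exponential(self):
        # a -> b -> c; diffusion limit given by the dense heat kernel
        W = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        p0 = np.array([1.0, 0.0, 0.0])
        exact = p0 @ expm(-0.25 * (np.eye(3) - W))
        it = heat_kernel_diffuse(p0, W, DiffusionParams(0.25, 10_000))
        assert np.abs(it - exact).sum() < 1e-5

    def test_convergence_to_exponential_monotone_in_Z(self):
        rng = np.random.default_rng(4)
        W = random_walk_matrix(rng, 20)
        p0 = rng.random(20)
        p0 /= p0.sum()
        exact = p0 @ expm(-0.5 * (np.eye(20) - W))
        errs = [
            np.abs(heat_kernel_diffuse(p0, W, DiffusionParams(0.5, Z)) - exact).sum()
            for Z in (10, 100, 1000, 10_000)
        ]
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_homogeneity(self):
        rng = np.random.default_rng(9)
        W = random_walk_matrix(rng, 15)
        p0 = rng.random(15)
        a = heat_kernel_diffuse(3.5 * p0, W, DiffusionParams())
        b = 3.5 * heat_kernel_diffuse(p0, W, DiffusionParams())
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_mass_conserved_when_fully_stochastic(self):
        rng = np.random.default_rng(2)
        n = 10
        W = rng.random((n, n))
        W /= W.sum(axis=1, keepdims=True)
        p0 = rng.random(n)
        pt = heat_kernel_diffuse(p0, W, DiffusionParams())
        assert abs(pt.sum() - p0.sum()) < 1e-10
        assert (pt >= 0).all()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            heat_kernel_diffuse(np.ones(3), np.eye(4), DiffusionParams())


class TestRankRegulators:
    def _rv(self, scores, net):
        from regsnap.tfrank import RankingVector
        return RankingVector(scores=np.asarray(scores, float), ranking=[])

    def test_descending_scores_rank_from_one(self, edge_tsv):
        net = read_edge_list(edge_tsv)  # regulators tfA, tfB
        scores = np.zeros(net.n_vertices)
        scores[net.index_of("tfA")] = 0.3
        scores[net.index_of("tfB")] = 0.7
        rv = rank_regulators(self._rv(scores, net), net)
        assert rv.ranking == [("tfB", 0.7, 1), ("tfA", 0.3, 2)]

    def test_ties_broken_lexicographically(self, edge_tsv):
        net = read_edge_list(edge_tsv)
        rv = rank_regulators(self._rv(np.zeros(net.n_vertices), net), net)
        assert [name for name, _, _ in rv.ranking] == ["tfA", "tfB"]

    def test_targets_never_ranked(self, edge_tsv):
        net = read_edge_list(edge_tsv)
        rv = rank_regulators(self._rv(np.ones(net.n_vertices), net), net)
        assert {name for name, _, _ in rv.ranking} == {"tfA", "tfB"}


class TestRankModuleOverTime:
    def _planted(self, seed=0):
        expr, te = generate_planted_expression(
            40, 6, [(10, (1, 5), ("U", "D", "U", "D", "U"))], seed=seed
        )
        planted = te.modules[0]
        net, _ = generate_planted_network(
            8, 40, planted=("TF_P", planted.genes), background_p=0.1,
            seed=seed + 1, target_ids=expr.gene_ids,
            max_background_coverage=0.2,
        )
        b = CCCBicluster(
            rows=planted.gene_indices, c_start=planted.c_start,
            c_end=planted.c_end, pattern=planted.pattern,
            gene_ids=planted.genes, id=1,
        )
        return expr, net, b

    def test_one_ranking_per_spanned_time_point(self):
        expr, net, b = self._planted()
        ts = rank_module_over_time(b, expr, net)
        # transitions 1..5 span time points 1..6
        assert ts.time_labels == [f"t{j}" for j in range(1, 7)]
        assert set(ts.rankings) == set(ts.time_labels)

    def test_planted_dominant_regulator_ranks_first_everywhere(self):
        expr, net, b = self._planted(seed=3)
        ts = rank_module_over_time(b, expr, net, DiffusionParams(0.25, 100))
        for label in ts.time_labels:
            assert ts.rankings[label].ranking[0][0] == "TF_P"

    def test_identical_expression_columns_identical_rankings(self):
        expr, net, b = self._planted()
        expr.values[:, 3] = expr.values[:, 2]  # t4 := t3
        ts = rank_module_over_time(b, expr, net)
        assert ts.rankings["t3"].ranking == ts.rankings["t4"].ranking

    def test_determinism_bit_identical(self):
        expr, net, b = self._planted()
        a = rank_module_over_time(b, expr, net).tsv_rows()
        c = rank_module_over_time(b, expr, net).tsv_rows()
        assert a == c

    def test_empty_seed_time_point_skipped(self):
        expr, net, b = self._planted()
        # zero out module expression at the first spanned time point
        for g in b.rows:
            expr.values[g, 0] = 0.0
        ts = rank_module_over_time(b, expr, net, use_absolute=True)
        assert "t1" in ts.skipped and "t1" not in ts.rankings
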