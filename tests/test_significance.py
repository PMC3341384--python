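"""Pattern p-values, multiple testing, overlap and enrichment statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regsnap.biclustering import CCCBicluster, bruteforce_enumerate
from regsnap.expression import DiscretizedMatrix
from regsnap.significance import (
    PatternNullModel,
    bonferroni,
    filter_biclusters,
    hypergeometric_enrichment,
    jaccard_similarity,
    pattern_pvalue,
    score_biclusters,
)

from conftest import random_discretized


def bic(rows, c_start, c_end, pattern="U", p=None):
    pattern = tuple(pattern) if len(pattern) == c_end - c_start + 1 else \
        tuple(pattern) * (c_end - c_start + 1)
    b = CCCBicluster(rows=tuple(rows), c_start=c_start, c_end=c_end,
                     pattern=pattern)
    b.corrected_pvalue = p
    return b


class TestPatternPValue:
    def test_certain_pattern_has_pvalue_one(self):
        d = DiscretizedMatrix(["a", "b"], np.array([["U"], ["U"]]), 0.0)
        model = PatternNullModel.from_matrix(d)
        b = bic([0, 1], 1, 1, "U")
        assert pattern_pvalue(b, model, 2) == pytest.approx(1.0)

    def test_all_genes_matching_is_binomial_point_mass(self):
        # f_1(U) = 1/2; both of 2 genes matching has probability (1/2)^2
        d = DiscretizedMatrix(["a", "b"], np.array([["U"], ["D"]]), 0.0)
        model = PatternNullModel.from_matrix(d)
        b = bic([0, 1], 1, 1, "U")
        assert pattern_pvalue(b, model, 2) == pytest.approx(0.25)

    def test_zero_frequency_symbol_gives_zero(self):
        d = DiscretizedMatrix(["a", "b"], np.array([["U"], ["U"]]), 0.0)
        model = PatternNullModel.from_matrix(d)
        b = bic([0, 1], 1, 1, "D")
        assert pattern_pvalue(b, model, 2) == 0.0

    def test_monte_carlo_agreement_small_matrix(self):
        """Binomial tail within 3 MC standard errors of simulated null."""
        rng = np.random.default_rng(99)
        d = random_discretized(rng, 8, 3)
        model = PatternNullModel.from_matrix(d)
        bs = bruteforce_enumerate(d)
        assert bs, "random instance produced no bicluster"
        b = max(bs, key=lambda b: pattern_pvalue(b, model, 8))
        p = pattern_pvalue(b, model, 8)
        n_rep = 20_000
        freqs = model.freqs
        draws = np.stack([
            rng.choice(3, size=(n_rep, 8), p=freqs[c]) for c in range(3)
        ], axis=2)  # (rep, gene, column) symbol indices
        sym_idx = {"D": 0, "N": 1, "U": 2}
        target = np.array([sym_idx[s] for s in b.pattern])
        cols = slice(b.c_start - 1, b.c_end)
        match = (draws[:, :, cols] == target).all(axis=2).sum(axis=1)
        mc = float(np.mean(match >= b.n_genes))
        se = math.sqrt(max(mc * (1 - mc), 1e-12) / n_rep)
        assert abs(p - mc) <= 3 * se + 1e-9

    def test_monotone_in_module_size(self):
        d = DiscretizedMatrix(
            ["a", "b", "c", "d"],
            np.array([["U"], ["U"], ["U"], ["D"]]), 0.0,
        )
        model = PatternNullModel.from_matrix(d)
        p2 = pattern_pvalue(bic([0, 1], 1, 1, "U"), model, 4)
        p3 = pattern_pvalue(bic([0, 1, 2], 1, 1, "U"), model, 4)
        assert p3 <= p2


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni([0.001, 0.5], 50) == [0.05, 1.0]
        assert bonferroni([0.5], 10) == [1.0]
        assert bonferroni([0.3, 0.7], 2) == [0.6, 1.0]

    def test_m_one_is_identity(self):
        assert bonferroni([0.123], 1) == [0.123]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], 2)

    def test_m_smaller_than_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)


class TestJaccard:
    def test_identity_and_disjoint(self):
        a = bic([0, 1], 1, 2, "UN")
        assert jaccard_similarity(a, a) == 1.0
        b = bic([2, 3], 3, 4, "DD")
        assert jaccard_similarity(a, b) == 0.0

    def test_partial_overlap_by_cell_count(self):
        # a: genes {0,1} x cols {1,2} (4 cells); b: genes {1,2} x col {2}
        # shared cell (1,2); union 5 cells
        a = bic([0, 1], 1, 2, "UN")
        b = bic([1, 2], 2, 2, "N")
        assert jaccard_similarity(a, b) == pytest.approx(1 / 5)

    @settings(derandomize=True, max_examples=30)
    @given(st.data())
    def test_symmetric(self, data):
        def rand_bic():
            rows = data.draw(st.sets(st.integers(0, 6), min_size=2, max_size=5))
            c1 = data.draw(st.integers(1, 4))
            c2 = data.draw(st.integers(c1, 5))
            return bic(sorted(rows), c1, c2, "N" * (c2 - c1 + 1))
        a, b = rand_bic(), rand_bic()
        assert jaccard_similarity(a, b) == jaccard_similarity(b, a)
        assert (jaccard_similarity(a, b) == 1.0) == (a.key() == b.key())


class TestFilterBiclusters:
    def test_pvalue_cut(self):
        bs = [bic([0, 1], 1, 2, "UN", p=0.02)]
        assert filter_biclusters(bs, p_cut=0.01) == []

    def test_identical_pair_keeps_one(self):
        a = bic([0, 1], 1, 2, "UN", p=0.001)
        b = bic([0, 1], 1, 2, "UN", p=0.002)
        kept = filter_biclusters([a, b], jac_cut=0.25)
        assert kept == [a]

    def test_size_filters(self):
        small = bic([0, 1], 1, 1, "U", p=0.0)   # spans 2 time points
        kept = filter_biclusters([small], min_genes=3, min_timepoints=2)
        assert kept == []
        kept = filter_biclusters([small], min_genes=2, min_timepoints=3)
        assert kept == []

    def test_kept_set_satisfies_all_pairwise_constraints(self):
        rng = np.random.default_rng(55)
        bs = []
        for _ in range(20):
            rows = tuple(sorted(rng.choice(10, size=3, replace=False)))
            c1 = int(rng.integers(1, 4))
            c2 = int(rng.integers(c1, 5))
            bs.append(bic(rows, c1, c2, "N" * (c2 - c1 + 1),
                          p=float(rng.random() * 0.01)))
        kept = filter_biclusters(bs, p_cut=0.01, jac_cut=0.25)
        for i, a in enumerate(kept):
            assert a.corrected_pvalue <= 0.01
            for b in kept[i + 1:]:
                assert jaccard_similarity(a, b) <= 0.25
        # greedy optimality: every discarded bicluster conflicts with a kept one
        for b in bs:
            if b.corrected_pvalue <= 0.01 and b not in kept:
                assert any(jaccard_similarity(b, k) > 0.25 for k in kept)


class TestHypergeometricEnrichment:
    def test_closed_form_example(self):
        # P(X >= 4) with N=10, K=5, n=4 equals C(5,4)C(5,0)/C(10,4) = 5/210
        background = {f"g{i}" for i in range(10)}
        module = {"g0", "g1", "g2", "g3"}
        annotations = {"T": {"g0", "g1", "g2", "g3", "g4"}}
        (r,) = hypergeometric_enrichment(module, annotations, background)
        assert r.pvalue == pytest.approx(5 / 210)
        assert r.k == 4 and r.K == 5 and r.n == 4 and r.N_bg == 10

    def test_whole_background_term_certain(self):
        background = {"a", "b", "c"}
        (r,) = hypergeometric_enrichment({"a"}, {"T": background}, background)
        assert r.pvalue == pytest.approx(1.0)

    def test_zero_overlap_upper_tail_is_one(self):
        background = {"a", "b", "c", "d"}
        (r,) = hypergeometric_enrichment({"a"}, {"T": {"b"}}, background)
        assert r.k == 0 and r.pvalue == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {}, set())

    def test_invariant_under_gene_relabeling(self):
        background = {f"g{i}" for i in range(8)}
        module = {"g0", "g1", "g2"}
        ann = {"T": {"g0", "g1", "g4"}}
        (r1,) = hypergeometric_enrichment(module, ann, background)
        relabel = {f"g{i}": f"x{7 - i}" for i in range(8)}
        (r2,) = hypergeometric_enrichment(
            {relabel[g] for g in module},
            {"T": {relabel[g] for g in ann["T"]}},
            {relabel[g] for g in background},
        )
        assert r1.pvalue == pytest.approx(r2.pvalue)


def test_score_biclusters_corrects_over_enumeration_family():
    rng = np.random.default_rng(8)
    d = random_discretized(rng, 8, 5)
    bs = bruteforce_enumerate(d)
    score_biclusters(bs, d)
    for b in bs:
        assert b.corrected_pvalue == pytest.approx(min(1.0, b.pvalue * len(bs)))
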