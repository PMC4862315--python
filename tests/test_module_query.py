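"""Exploration operations: correlation, quicksearch, ranking, enrichment,
networks and by-expression ordering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from ampelo.compendium import Compendium
from ampelo.gene_clusters import MeasurableTranscript
from ampelo.module_query import (
    correlation_network,
    enrich_terms,
    extend_module,
    gene_terms_from_sets,
    make_module,
    order_by_expression,
    quicksearch,
    rank_coexpressed_genes,
    rank_similar_contrasts,
    read_gene_sets_gmt,
    resolve_genes_to_measurables,
    shrink_module,
    uncentered_pearson,
)


def compendium_from(array, genes=None, contrasts=None, platforms=None):
    arr = np.asarray(array, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    contrasts = contrasts or [f"c{j}" for j in range(arr.shape[1])]
    return Compendium(
        pd.DataFrame(arr, index=genes, columns=contrasts), platforms or {}
    )


class TestUncenteredPearson:
    def test_self_correlation_is_one(self):
        x = np.arange(1.0, 13.0)
        assert uncentered_pearson(x, x).value == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        x = np.arange(1.0, 13.0)
        assert uncentered_pearson(x, -x).value == pytest.approx(-1.0)

    def test_orthogonal_vectors_zero(self):
        x = np.array([1.0, 0.0] * 6)
        y = np.array([0.0, 1.0] * 6)
        assert uncentered_pearson(x, y).value == pytest.approx(0.0)

    def test_matches_direct_formula_with_missing(self, rng):
        for _ in range(50):
            n = int(rng.integers(12, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            x[rng.random(n) < 0.2] = np.nan
            y[rng.random(n) < 0.2] = np.nan
            score = uncentered_pearson(x, y)
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 10:
                assert score.value is None
                continue
            xs, ys = x[mask], y[mask]
            direct = np.sum(xs * ys) / math.sqrt(
                np.sum(xs**2) * np.sum(ys**2)
            )
            assert score.value == pytest.approx(direct, abs=1e-12)
            assert score.n_overlap == mask.sum()

    def test_undefined_below_min_overlap_and_for_zero_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        assert uncentered_pearson(x, x, min_overlap=4).value is None
        z = np.zeros(12)
        assert uncentered_pearson(z, np.arange(12.0)).value is None

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        xs=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=10, max_size=30
        ),
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
    )
    def test_bounds_symmetry_and_scale_property(self, xs, a, b):
        x = np.array(xs)
        y = x[::-1].copy()
        s = uncentered_pearson(x, y)
        if s.value is None:
            return
        assert -1.0 <= s.value <= 1.0
        assert uncentered_pearson(y, x).value == pytest.approx(s.value)
        scaled = uncentered_pearson(a * x, b * y)
        assert scaled.value == pytest.approx(
            math.copysign(1, a * b) * s.value, abs=1e-9
        )


class TestQuicksearch:
    def test_scores_rank_contrasts_by_mean_abs_ratio(self):
        comp = compendium_from([[3.0, -1.0, 2.0]], genes=["g0"])
        module = quicksearch(comp, ["g0"], top_k=2)
        assert module.contrast_ids == ["c0", "c2"]

    def test_ties_broken_lexicographically(self):
        comp = compendium_from(
            [[2.0, 2.0, 1.0]], genes=["g0"], contrasts=["cB", "cA", "cC"]
        )
        module = quicksearch(comp, ["g0"], top_k=2)
        assert module.contrast_ids == ["cA", "cB"]

    def test_coverage_rule_skips_sparse_contrasts(self):
        comp = compendium_from(
            [[5.0, 1.0], [np.nan, 1.0], [np.nan, 1.0], [np.nan, 1.0]]
        )
        # c0 defined for 1/4 query genes < 50% -> skipped despite big value
        module = quicksearch(comp, ["g0", "g1", "g2", "g3"], top_k=1)
        assert module.contrast_ids == ["c1"]

    def test_cluster_member_resolves_to_cluster_row(self):
        comp = compendium_from([[1.0, 2.0]], genes=["cluster_0001"])
        ms = [
            MeasurableTranscript("cluster_0001", frozenset({"gX", "gY"}))
        ]
        resolved, notices = resolve_genes_to_measurables(["gX"], comp, ms)
        assert resolved == ["cluster_0001"]
        assert notices == {"gX": "cluster_0001"}
        module = quicksearch(comp, ["gX"], top_k=1, measurables=ms)
        assert module.gene_ids == ["cluster_0001"]

    def test_unresolvable_query_raises(self):
        comp = compendium_from([[1.0]])
        with pytest.raises(KeyError, match="ghost"):
            quicksearch(comp, ["ghost"])


def planted_compendium(rng, n_genes=30, n_contrasts=40, planted_genes=4,
                       planted_contrasts=4, effect=2.0, noise=0.25):
    arr = rng.normal(0, noise, size=(n_genes, n_contrasts))
    arr[:planted_genes, :planted_contrasts] += effect
    return compendium_from(arr)


class TestRanking:
    def test_identical_candidate_ranks_first(self):
        arr = np.vstack([np.arange(12.0)] * 2 + [np.ones(12)])
        comp = compendium_from(arr)
        module = make_module(comp, ["g0"], [f"c{j}" for j in range(12)])
        ranked = rank_coexpressed_genes(comp, module)
        assert ranked[0][0] == "g1"
        assert ranked[0][1] == pytest.approx(1.0)

    def test_anticorrelated_mode(self):
        arr = np.vstack([np.arange(12.0), -np.arange(12.0), np.ones(12)])
        comp = compendium_from(arr)
        module = make_module(comp, ["g0"], [f"c{j}" for j in range(12)])
        ranked = rank_coexpressed_genes(comp, module, mode="anticorrelated")
        assert ranked[0][0] == "g1"
        assert ranked[0][1] == pytest.approx(-1.0)

    def test_planted_partner_beats_null_genes(self, rng):
        comp = planted_compendium(rng)
        module = make_module(
            comp, ["g0", "g1"], list(comp.matrix.columns)
        )
        ranked = rank_coexpressed_genes(comp, module)
        names = [g for g, _ in ranked]
        assert set(names[:2]) == {"g2", "g3"}

    def test_duplicate_contrast_ranks_first(self):
        arr = np.column_stack(
            [np.arange(12.0), np.arange(12.0), np.ones(12)]
        )
        comp = compendium_from(arr)
        module = make_module(comp, [f"g{i}" for i in range(12)], ["c0"])
        ranked = rank_similar_contrasts(comp, module)
        assert ranked[0][0] == "c1"
        assert ranked[0][1] == pytest.approx(1.0)

    def test_all_missing_candidate_excluded(self):
        arr = np.column_stack([np.arange(12.0), np.full(12, np.nan)])
        comp = compendium_from(arr)
        module = make_module(comp, [f"g{i}" for i in range(12)], ["c0"])
        ranked = rank_similar_contrasts(comp, module)
        assert ranked == []

    def test_empty_module_axis_rejected(self):
        comp = compendium_from([[1.0]])
        module = make_module(comp, ["g0"], ["c0"])
        object.__setattr__(module, "contrast_ids", [])
        with pytest.raises(ValueError):
            rank_coexpressed_genes(comp, module)

    def test_rank_invariant_to_candidate_order(self, rng):
        comp = planted_compendium(rng)
        module = make_module(comp, ["g0", "g1"], list(comp.matrix.columns))
        cands = [f"g{i}" for i in range(2, 30)]
        ref = rank_coexpressed_genes(comp, module, candidates=cands)
        shuffled = list(cands)
        rng.shuffle(shuffled)
        assert rank_coexpressed_genes(comp, module, candidates=shuffled) == ref


class TestCorrelationNetwork:
    def test_threshold_zero_connects_all_defined_pairs(self, rng):
        comp = compendium_from(rng.normal(size=(5, 15)))
        module = make_module(
            comp, list(comp.matrix.index), list(comp.matrix.columns)
        )
        edges = correlation_network(module, 0.0)
        assert len(edges) == 5 * 4 // 2
        assert all(a < b for a, b, _ in edges)

    def test_threshold_one_keeps_only_duplicates(self, rng):
        # integer-valued rows keep the arithmetic exact, so only the
        # scaled duplicate reaches |r| == 1.0 precisely
        arr = rng.integers(-9, 10, size=(4, 15)).astype(float)
        arr[1] = arr[0] * 2.0
        comp = compendium_from(arr)
        module = make_module(
            comp, list(comp.matrix.index), list(comp.matrix.columns)
        )
        edges = correlation_network(module, 1.0)
        assert [(a, b) for a, b, _ in edges] == [("g0", "g1")]

    def test_matches_all_pairs_oracle(self, rng):
        comp = compendium_from(rng.normal(size=(6, 20)))
        module = make_module(
            comp, list(comp.matrix.index), list(comp.matrix.columns)
        )
        threshold = 0.3
        edges = {
            (a, b): r for a, b, r in correlation_network(module, threshold)
        }
        genes = sorted(module.gene_ids)
        for i, g in enumerate(genes):
            for h in genes[i + 1:]:
                r = uncentered_pearson(
                    module.values.loc[g], module.values.loc[h]
                ).value
                if abs(r) >= threshold:
                    assert edges[(g, h)] == pytest.approx(r, abs=1e-12)
                else:
                    assert (g, h) not in edges


def hypergeom_tail_oracle(N, K, n, k):
    """P(X >= k) by explicit summation of point masses."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += (
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        )
    return total


class TestEnrichment:
    def test_fully_enriched_term_exact_p(self):
        # all 5 module genes carry the term held by 5 of 20 background genes
        background = {f"g{i}" for i in range(20)}
        module = {f"g{i}" for i in range(5)}
        terms = {f"g{i}": ["T"] for i in range(5)}
        (res,) = enrich_terms(module, background, terms)
        assert res.k == res.K == res.n == 5
        assert res.p_value == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_absent_terms_excluded(self):
        background = {"a", "b", "c", "d"}
        terms = {"c": ["T"], "d": ["T"]}
        results = enrich_terms({"a", "b"}, background, terms)
        assert results == []

    def test_matches_summation_oracle(self, rng):
        for _ in range(40):
            N = int(rng.integers(5, 40))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            background = {f"g{i}" for i in range(N)}
            carriers = set(rng.choice(sorted(background), K, replace=False))
            module = set(rng.choice(sorted(background), n, replace=False))
            k = len(module & carriers)
            if k == 0:
                continue
            terms = {g: ["T"] for g in carriers}
            (res,) = enrich_terms(module, background, terms)
            assert res.p_value == pytest.approx(
                hypergeom_tail_oracle(N, K, n, k), abs=1e-12
            )
            assert res.p_value == pytest.approx(
                hypergeom.sf(k - 1, N, K, n), abs=1e-14
            )

    def test_fdr_is_stepup_monotone_and_above_p(self, rng):
        N = 60
        background = {f"g{i}" for i in range(N)}
        terms = {}
        for t in range(8):
            carriers = rng.choice(sorted(background), 12, replace=False)
            for g in carriers:
                terms.setdefault(g, []).append(f"T{t}")
        module = set(rng.choice(sorted(background), 15, replace=False))
        results = enrich_terms(module, background, terms)
        ps = [r.p_value for r in results]
        fdrs = [r.fdr for r in results]
        assert ps == sorted(ps)
        assert all(f >= p - 1e-15 for p, f in zip(ps, fdrs))
        assert fdrs == sorted(fdrs)  # monotone along sorted p

    def test_cluster_measurable_contributes_member_terms(self):
        ms = [
            MeasurableTranscript("cluster_0001", frozenset({"gA", "gB"})),
            MeasurableTranscript("gC", frozenset({"gC"})),
            MeasurableTranscript("gD", frozenset({"gD"})),
        ]
        terms = {"gA": ["T"], "gB": ["T"]}
        results = enrich_terms(
            {"cluster_0001"},
            {"cluster_0001", "gC", "gD"},
            terms,
            measurables=ms,
        )
        (res,) = results
        assert res.k == 2  # both cluster members carry the term

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            enrich_terms(set(), set(), {})


class TestOrdering:
    def test_identical_rows_adjacent(self, rng):
        arr = rng.normal(size=(5, 20))
        arr[3] = arr[0]
        comp = compendium_from(arr)
        module = make_module(
            comp, list(comp.matrix.index), list(comp.matrix.columns)
        )
        rows, _ = order_by_expression(module)
        assert abs(rows.index("g0") - rows.index("g3")) == 1

    def test_order_invariant_to_input_permutation(self, rng):
        arr = rng.normal(size=(6, 15))
        comp = compendium_from(arr)
        genes = list(comp.matrix.index)
        module = make_module(comp, genes, list(comp.matrix.columns))
        ref = order_by_expression(module)
        perm = list(genes)
        rng.shuffle(perm)
        permuted = make_module(comp, perm, list(comp.matrix.columns))
        assert order_by_expression(permuted) == ref

    def test_planted_blocks_contiguous(self, rng):
        block1 = np.tile(rng.normal(size=20), (4, 1)) + rng.normal(
            0, 0.1, size=(4, 20)
        )
        block2 = np.tile(rng.normal(size=20), (4, 1)) + rng.normal(
            0, 0.1, size=(4, 20)
        )
        comp = compendium_from(np.vstack([block1, block2]))
        module = make_module(
            comp, list(comp.matrix.index), list(comp.matrix.columns)
        )
        rows, _ = order_by_expression(module)
        positions = [rows.index(f"g{i}") for i in range(4)]
        assert max(positions) - min(positions) == 3  # block 1 contiguous

    def test_single_row_and_column_identity(self):
        comp = compendium_from([[1.0]])
        module = make_module(comp, ["g0"], ["c0"])
        assert order_by_expression(module) == (["g0"], ["c0"])


def test_extend_then_shrink_round_trip(rng):
    comp = compendium_from(rng.normal(size=(6, 8)))
    module = make_module(comp, ["g0", "g1"], ["c0", "c1", "c2"])
    grown = extend_module(comp, module, genes=["g4"], contrasts=["c5"])
    back = shrink_module(comp, grown, genes=["g4"], contrasts=["c5"])
    assert back.gene_ids == module.gene_ids
    assert back.contrast_ids == module.contrast_ids
    assert back.values.equals(module.values)


def test_gene_set_parsing_and_inversion():
    text = "T1\tdesc\tg1\tg2\nT2\tdesc\tg2\tg3\n"
    sets = read_gene_sets_gmt(text)
    assert sets == {"T1": {"g1", "g2"}, "T2": {"g2", "g3"}}
    terms = gene_terms_from_sets(sets)
    assert terms["g2"] == {"T1", "T2"}
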