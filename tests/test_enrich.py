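"""Hypergeometric tails, count pooling, BH FDR and the prediction driver."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from smorfpred import (
    DataError,
    Dataset,
    DatasetCounts,
    GeneSet,
    bh_fdr,
    hypergeom_tail,
    make_background,
    pooled_p,
    predict_functions,
    results_frame,
)
from smorfpred.enrich import pool_counts
from conftest import random_expression


def enumeration_tail(total, n_term, n_draw, i_min):
    """Oracle: enumerate every C(total, n_draw) draw and count successes."""
    population = list(range(total))
    in_term = set(range(n_term))
    hits = sum(
        1
        for draw in itertools.combinations(population, n_draw)
        if len(in_term & set(draw)) >= i_min
    )
    return hits / math.comb(total, n_draw)


def counts(i, m, n, t, dataset_id="d1"):
    return DatasetCounts(dataset_id, i, m, n, t)


class TestBackground:
    def test_intersection_of_dataset_genes_and_set_union(self):
        sets = [
            GeneSet("t1", "custom", frozenset({"a", "b"})),
            GeneSet("t2", "custom", frozenset({"b", "d"})),
        ]
        assert make_background({"a", "b", "c"}, sets) == {"a", "b"}

    def test_disjoint_inputs_abort(self):
        sets = [GeneSet("t1", "custom", frozenset({"x"}))]
        with pytest.raises(DataError):
            make_background({"a", "b"}, sets)

    def test_constructed_overlap_size(self):
        annotated = {f"g{i}" for i in range(120)}
        union_members = {f"g{i}" for i in range(40, 140)}  # 100 genes, 80 overlap
        sets = [
            GeneSet("t1", "custom", frozenset(list(union_members)[:60])),
            GeneSet("t2", "custom", frozenset(list(union_members)[40:])),
        ]
        bg = make_background(annotated, sets)
        assert bg == annotated & union_members
        assert len(bg) == 80


class TestHypergeomTail:
    def test_zero_overlap_gives_one_exactly(self):
        assert hypergeom_tail(counts(0, 5, 4, 10)) == 1.0

    def test_hand_enumerated_example(self):
        # (C(5,3)C(5,1) + C(5,4)C(5,0)) / C(10,4) = 55/210
        assert hypergeom_tail(counts(3, 5, 4, 10)) == pytest.approx(
            55 / 210, rel=1e-12
        )

    def test_single_term_tail(self):
        assert hypergeom_tail(counts(4, 4, 4, 10)) == pytest.approx(
            1 / 210, rel=1e-12
        )

    def test_matches_enumeration_oracle_small_grid(self):
        for t in range(2, 9):
            for m in range(0, t + 1):
                for n in range(1, t + 1):
                    for i in range(0, min(m, n) + 1):
                        expected = enumeration_tail(t, m, n, i)
                        got = hypergeom_tail(counts(i, m, n, t))
                        assert got == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_matches_scipy_survival_function(self, rng):
        for _ in range(200):
            t = int(rng.integers(5, 2000))
            m = int(rng.integers(1, t + 1))
            n = int(rng.integers(1, t + 1))
            i = int(rng.integers(0, min(m, n) + 1))
            ours = hypergeom_tail(counts(i, m, n, t))
            ref = float(hypergeom.sf(i - 1, t, m, n))
            assert ours == pytest.approx(ref, rel=1e-10, abs=1e-300)

    def test_tail_monotone_in_overlap(self):
        ps = [hypergeom_tail(counts(i, 20, 15, 100)) for i in range(0, 16)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_counts_abort(self):
        with pytest.raises(DataError):
            counts(5, 4, 10, 20)  # I > M
        with pytest.raises(DataError):
            counts(1, 30, 10, 20)  # M > T


class TestPooledP:
    def test_single_dataset_identity(self):
        c = counts(3, 5, 4, 10)
        assert pooled_p([c]) == hypergeom_tail(c)

    def test_two_copies_sum_parameters(self):
        c = counts(3, 5, 4, 10)
        expected = enumeration_tail(20, 10, 8, 6)
        assert pooled_p([c, counts(3, 5, 4, 10, "d2")]) == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_overlap_everywhere_gives_one(self):
        cs = [counts(0, 5, 4, 10, f"d{i}") for i in range(3)]
        assert pooled_p(cs) == 1.0

    def test_empty_list_aborts(self):
        with pytest.raises(DataError):
            pooled_p([])

    def test_pool_counts_componentwise(self):
        pooled = pool_counts([counts(1, 2, 3, 10), counts(2, 3, 4, 12, "d2")])
        assert (
            pooled.n_overlap,
            pooled.n_term,
            pooled.n_correlated,
            pooled.n_background,
        ) == (3, 5, 7, 22)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.05]).tolist() == [0.05]

    def test_hand_stepped_up_example(self):
        # sorted: 0.01*3/1=0.03; 0.03*3/2=0.045 floored to 0.04; 0.04*3/3=0.04
        assert np.allclose(bh_fdr([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_uniform_list_fixed_point(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_adjusted_never_below_raw_and_order_preserved(self, rng):
        p = rng.uniform(1e-6, 1.0, size=25)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        # monotone: a smaller p never gets a larger adjusted value
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5, np.nan])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(DataError):
            bh_fdr([0.5, bad])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_step_up_matches_hand_rolled_oracle(self, pvals):
        p = np.asarray(pvals)
        order = np.argsort(p, kind="stable")
        m = len(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_fdr(p), expected, atol=1e-12)


def _planted_datasets(rng, n_genes=60, n_samples=20, planted=10):
    """Two datasets where the smORF tracks the first `planted` genes exactly."""
    datasets = []
    for d in range(2):
        driver = rng.normal(size=n_samples)
        genes = random_expression(rng, n_genes, n_samples)
        for i in range(planted):
            genes.iloc[i] = driver + 0.01 * rng.normal(size=n_samples)
        smorfs = pd.DataFrame(
            [driver], index=["m1"], columns=genes.columns
        )
        datasets.append(Dataset(f"d{d}", genes, smorfs))
    return datasets


class TestPredictFunctions:
    def test_planted_term_ranks_first_and_is_selected(self, rng):
        datasets = _planted_datasets(rng)
        member_ids = [f"g{i:04d}" for i in range(10)]
        sets = [
            GeneSet("planted", "GO-BP", frozenset(member_ids)),
            GeneSet("decoy", "GO-BP", frozenset(f"g{i:04d}" for i in range(30, 55))),
        ]
        report = predict_functions("m1", datasets, sets, k=50, rho_min=0.5)
        assert report.status == "ok"
        assert report.results[0].term_id == "planted"
        assert report.results[0].selected
        frame = results_frame(report)
        assert frame.loc[frame.term_id == "planted", "I_sum"].item() == 20

    def test_unquantifiable_smorf_reports_status(self, rng):
        datasets = _planted_datasets(rng)
        sets = [GeneSet("t", "custom", frozenset({"g0001"}))]
        report = predict_functions("missing_smorf", datasets, sets)
        assert report.status == "unquantifiable"
        assert report.results == []

    def test_no_correlated_genes_gives_all_p_one(self, rng):
        genes = random_expression(rng, 30, 15)
        smorfs = pd.DataFrame(
            [-(genes.iloc[0].to_numpy())], index=["m1"], columns=genes.columns
        )
        sets = [GeneSet("t", "custom", frozenset(genes.index[:10]))]
        report = predict_functions(
            "m1", [Dataset("d1", genes, smorfs)], sets, rho_min=0.999999
        )
        assert all(r.p == 1.0 for r in report.results)
        assert not any(r.selected for r in report.results)

    def test_terms_absent_from_background_skipped(self, rng):
        datasets = _planted_datasets(rng)
        sets = [
            GeneSet("present", "custom", frozenset({"g0001", "g0002"})),
            GeneSet("absent", "custom", frozenset({"not_a_gene"})),
        ]
        report = predict_functions("m1", datasets, sets)
        assert {r.term_id for r in report.results} == {"present"}

    def test_fdr_families_per_collection_vs_joint(self, rng):
        datasets = _planted_datasets(rng)
        sets = [
            GeneSet("a", "GO-BP", frozenset(f"g{i:04d}" for i in range(10))),
            GeneSet("b", "KEGG", frozenset(f"g{i:04d}" for i in range(10, 25))),
            GeneSet("c", "KEGG", frozenset(f"g{i:04d}" for i in range(25, 40))),
        ]
        per = predict_functions("m1", datasets, sets, fdr_family="per-collection")
        joint = predict_functions("m1", datasets, sets, fdr_family="all")
        p_of = lambda rep: {r.term_id: r.p for r in rep.results}
        assert p_of(per) == p_of(joint)  # p never depends on the family
        solo = {r.term_id: r.fdr for r in per.results}
        assert solo["a"] == p_of(per)["a"]  # lone term in its collection
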