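"""Rank transform, correlation distance, and exact index/brute-force parity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from smorfpred import (
    CorrelationIndex,
    DataError,
    RankMatrix,
    correlation_distance,
    query_correlated_genes,
    rank_transform,
)
from smorfpred.coexpr import brute_force_query
from conftest import random_expression


class TestRankTransform:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([2, 2, 3], [1.5, 1.5, 3]),
            ([1, 2, 3], [1, 2, 3]),
            ([5, 1, 5, 5], [3, 1, 3, 3]),
        ],
    )
    def test_mean_rank_for_ties(self, values, expected):
        assert rank_transform(values).tolist() == expected

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError):
            rank_transform([1, 2])

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            rank_transform([1.0, np.nan, 3.0])

    def test_rank_sum_is_m_times_m_plus_1_over_2(self, rng):
        for _ in range(20):
            row = rng.normal(size=12)
            row[rng.integers(0, 12)] = row[0]  # force a tie
            m = len(row)
            assert rank_transform(row).sum() == pytest.approx(m * (m + 1) / 2)


class TestCorrelationDistance:
    def test_identical_ranks_give_zero(self):
        r = rank_transform([3, 1, 4, 1, 5])
        assert correlation_distance(r, r) == pytest.approx(0.0, abs=1e-15)

    def test_reversed_ranks_give_two(self):
        a = rank_transform([1, 2, 3, 4])
        b = rank_transform([4, 3, 2, 1])
        assert correlation_distance(a, b) == pytest.approx(2.0, abs=1e-15)

    def test_hand_computed_half_distance(self):
        # centered ranks (-1,0,1) vs (-1,1,0): rho = 1/2, distance = 1/2
        assert correlation_distance(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 3.0, 2.0])
        ) == pytest.approx(0.5, abs=1e-15)

    def test_symmetry(self, rng):
        a = rank_transform(rng.normal(size=10))
        b = rank_transform(rng.normal(size=10))
        assert correlation_distance(a, b) == correlation_distance(b, a)

    def test_zero_variance_is_an_error_not_zero(self):
        flat = np.array([2.0, 2.0, 2.0])
        with pytest.raises(DataError):
            correlation_distance(flat, rank_transform([1, 2, 3]))

    def test_one_minus_distance_equals_scipy_spearman(self, rng):
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        d = correlation_distance(rank_transform(x), rank_transform(y))
        assert 1.0 - d == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)


class TestRankMatrix:
    def test_zero_variance_rows_excluded_and_listed(self, rng):
        df = random_expression(rng, 5, 10)
        df.loc["g0002"] = 3.14
        rm = RankMatrix.from_expression(df)
        assert rm.excluded == ["g0002"]
        assert "g0002" not in rm.feature_ids
        assert rm.embedding.shape == (4, 10)

    def test_embedding_rows_centered_unit_norm(self, rng):
        rm = RankMatrix.from_expression(random_expression(rng, 20, 15, ties=True))
        assert np.allclose(rm.embedding.sum(axis=1), 0.0, atol=1e-10)
        assert np.allclose(np.linalg.norm(rm.embedding, axis=1), 1.0)


class TestQueries:
    def test_self_query_on_single_gene_index(self, rng):
        df = random_expression(rng, 1, 8)
        rm = RankMatrix.from_expression(df)
        hits = CorrelationIndex(rm).query(rank_transform(df.iloc[0]))
        assert len(hits) == 1
        assert hits[0].gene_id == "g0000"
        assert hits[0].rho == pytest.approx(1.0, abs=1e-12)
        assert hits[0].distance == pytest.approx(0.0, abs=1e-12)

    def test_identical_gene_row_ranks_first(self, rng):
        df = random_expression(rng, 50, 20)
        smorf_values = df.loc["g0031"].to_numpy()
        hits = query_correlated_genes(df, smorf_values, k=10, rho_min=0.5)
        assert hits[0].gene_id == "g0031"
        assert hits[0].rho == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("strategy", ["raw", "preranked", "tree"])
    def test_three_strategies_identical(self, rng, strategy):
        df = random_expression(rng, 80, 25, ties=True)
        smorf_values = 0.8 * df.loc["g0010"].to_numpy() + rng.normal(size=25)
        reference = query_correlated_genes(df, smorf_values, k=15, rho_min=0.2,
                                           strategy="preranked")
        got = query_correlated_genes(df, smorf_values, k=15, rho_min=0.2,
                                     strategy=strategy)
        assert [(h.gene_id, h.rho) for h in got] == [
            (h.gene_id, h.rho) for h in reference
        ]

    def test_threshold_and_k_truncation_match_brute_force_oracle(self, rng):
        df = random_expression(rng, 50, 20)
        smorf_values = rng.normal(size=20)
        k, rho_min = 10, 0.1
        hits = query_correlated_genes(df, smorf_values, k=k, rho_min=rho_min)
        # independent oracle: scipy spearman against every gene, then filter/sort
        oracle = []
        for gid, row in df.iterrows():
            rho = spearmanr(row.to_numpy(), smorf_values).statistic
            if rho >= rho_min:
                oracle.append((gid, rho))
        oracle.sort(key=lambda t: (-t[1], t[0]))
        oracle = oracle[:k]
        assert [h.gene_id for h in hits] == [gid for gid, _ in oracle]
        assert np.allclose([h.rho for h in hits], [r for _, r in oracle], atol=1e-12)

    def test_kth_place_ties_broken_by_gene_id(self, rng):
        base = rng.normal(size=12)
        df = pd.DataFrame(
            [base, base + 1.0, base * 2.0, rng.normal(size=12)],
            index=["b_gene", "d_gene", "a_gene", "z_gene"],
            columns=[f"s{i}" for i in range(12)],
        )
        # three rows are rank-identical (rho = 1); with k=2 the lexicographically
        # smallest ids win
        hits = query_correlated_genes(df, base, k=2, rho_min=0.5)
        assert [h.gene_id for h in hits] == ["a_gene", "b_gene"]

    def test_no_hits_below_threshold(self, rng):
        df = random_expression(rng, 30, 15)
        anti = -df.loc["g0000"].to_numpy()
        hits = query_correlated_genes(df, anti, k=5, rho_min=0.999)
        assert all(h.rho >= 0.999 for h in hits)

    def test_invalid_rho_min_rejected(self, rng):
        df = random_expression(rng, 5, 8)
        with pytest.raises(ValueError):
            query_correlated_genes(df, df.iloc[0].to_numpy(), rho_min=-1.0)

    def test_zero_variance_query_rejected(self, rng):
        rm = RankMatrix.from_expression(random_expression(rng, 5, 8))
        with pytest.raises(DataError):
            brute_force_query(rm, np.full(8, 4.5))

    @settings(derandomize=True, max_examples=20)
    @given(
        seed=st.integers(0, 10_000),
        transform=st.sampled_from(["affine", "exp", "cube"]),
    )
    def test_monotone_transform_invariance(self, seed, transform):
        """Strictly increasing per-feature transforms leave ranks, rho values
        and hit lists unchanged (the basis of Spearman's robustness)."""
        rng = np.random.default_rng(seed)
        df = random_expression(rng, 25, 12, ties=False)
        smorf_values = rng.normal(size=12)
        fn = {
            "affine": lambda x: 2.5 * x + 3.0,
            "exp": np.exp,
            "cube": lambda x: x**3,
        }[transform]
        warped = df.copy()
        warped.loc["g0003"] = fn(warped.loc["g0003"].to_numpy())
        base = query_correlated_genes(df, smorf_values, k=25, rho_min=-0.9)
        after = query_correlated_genes(warped, smorf_values, k=25, rho_min=-0.9)
        assert [(h.gene_id, h.rho) for h in base] == [
            (h.gene_id, h.rho) for h in after
        ]
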