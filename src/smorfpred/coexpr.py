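"""Spearman co-expression search with an exact BallTree fast path.

Expression rows are converted to within-row ranks (mean rank for ties), so
Pearson correlation of rank vectors equals Spearman correlation of the raw
values, and the correlation distance is

    distance = 1 - cov(rank_gene, rank_smorf) / (sigma_gene * sigma_smorf)
             = 1 - rho  in [0, 2].

1 - rho is not a metric (it violates the triangle inequality), so the spatial
index is built on standardised rank vectors — each rank row centred and
scaled to unit Euclidean norm — under the Euclidean metric, where

    d_euclid^2 = 2 * (1 - rho).

The map rho -> d is strictly decreasing, so Euclidean neighbour order equals
correlation order and tree queries are exact, not approximate. Candidate hits
from a (slightly padded) radius query are re-scored by the exact dot product
of standardised rank vectors, which is bit-identical to the brute-force
score, so tree-backed and brute-force searches return identical hit lists.

Constant (zero rank variance) features carry no correlation information;
they are excluded from the index and listed on the RankMatrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.neighbors import BallTree

from .errors import DataError

DEFAULT_LEAF_SIZE = 5
DEFAULT_K = 1000
DEFAULT_RHO_MIN = 0.5

#: Padding added to the tree query radius; candidates are re-scored exactly,
#: so the padding only guards against float round-off at the radius boundary.
_RADIUS_PAD = 1e-7

MIN_SAMPLES = 3


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Within-row ranks, ascending, ties replaced by their mean rank."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("rank_transform expects a 1-D row")
    if arr.size < MIN_SAMPLES:
        raise DataError(
            f"row has {arr.size} samples; at least {MIN_SAMPLES} are required "
            "for a meaningful correlation"
        )
    if not np.all(np.isfinite(arr)):
        raise DataError("non-finite values in expression row")
    return rankdata(arr, method="average")


def _standardize(ranks: np.ndarray) -> np.ndarray | None:
    """Centre and scale to unit norm; None for zero-variance rows."""
    centred = ranks - ranks.mean()
    norm = np.linalg.norm(centred)
    if norm == 0.0:
        return None
    return centred / norm


def correlation_distance(rank_a: np.ndarray, rank_b: np.ndarray) -> float:
    """1 - Spearman rho computed from two rank vectors; in [0, 2]."""
    a = np.asarray(rank_a, dtype=float)
    b = np.asarray(rank_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("rank vectors differ in length")
    sa = _standardize(a)
    sb = _standardize(b)
    if sa is None or sb is None:
        raise DataError("correlation distance undefined for zero-variance rank vector")
    return 1.0 - float(sa @ sb)


@dataclass(frozen=True)
class CorrelationHit:
    """One correlated gene: Spearman rho and the distance 1 - rho."""

    gene_id: str
    rho: float

    @property
    def distance(self) -> float:
        return 1.0 - self.rho


@dataclass
class RankMatrix:
    """Per-feature rank vectors plus the standardised embedding for the index."""

    feature_ids: list[str]
    sample_ids: list[str]
    ranks: np.ndarray
    embedding: np.ndarray
    excluded: list[str]

    @classmethod
    def from_expression(cls, expr: pd.DataFrame) -> "RankMatrix":
        """Rank every row of a features x samples matrix.

        Zero-variance rows are excluded from the ranks/embedding and recorded
        in ``excluded``.
        """
        if expr.shape[1] < MIN_SAMPLES:
            raise DataError(
                f"dataset has {expr.shape[1]} samples; at least "
                f"{MIN_SAMPLES} are required"
            )
        values = expr.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise DataError("non-finite values in expression matrix")
        ranks = rankdata(values, method="average", axis=1)
        centred = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centred, axis=1)
        valid = norms > 0.0
        embedding = centred[valid] / norms[valid, None]
        feature_ids = [f for f, ok in zip(expr.index, valid) if ok]
        excluded = [f for f, ok in zip(expr.index, valid) if not ok]
        return cls(
            feature_ids=feature_ids,
            sample_ids=list(expr.columns),
            ranks=ranks[valid],
            embedding=embedding,
            excluded=excluded,
        )


def _validate_query_params(k: int, rho_min: float) -> None:
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not (-1.0 < rho_min <= 1.0):
        raise ValueError(f"rho_min must lie in (-1, 1], got {rho_min}")


def _select_hits(
    rank_matrix: RankMatrix,
    candidate_rows: np.ndarray,
    query_embedding: np.ndarray,
    k: int,
    rho_min: float,
) -> list[CorrelationHit]:
    """Exact re-scoring, threshold filter, deterministic order, truncation.

    Hits are sorted by rho descending then gene id ascending; ties at the
    k-th place are broken by gene id, so results are reproducible across
    platforms and search strategies.
    """
    if candidate_rows.size == 0:
        return []
    embedding = rank_matrix.embedding
    # per-row 1-D dots: bit-identical whether a row is scored inside a tree
    # candidate subset or a full brute-force sweep (a matrix-vector BLAS call
    # can differ in the last ulp depending on the operand shape)
    hits = []
    for row in candidate_rows:
        rho = float(embedding[row] @ query_embedding)
        if rho >= rho_min:
            hits.append(CorrelationHit(rank_matrix.feature_ids[row], rho))
    hits.sort(key=lambda h: (-h.rho, h.gene_id))
    return hits[:k]


class CorrelationIndex:
    """BallTree over standardised rank vectors; exact correlation queries."""

    def __init__(self, rank_matrix: RankMatrix, leaf_size: int = DEFAULT_LEAF_SIZE):
        if rank_matrix.embedding.shape[0] < 1:
            raise DataError("cannot build an index over zero valid features")
        self.rank_matrix = rank_matrix
        self.leaf_size = leaf_size
        self._tree = BallTree(rank_matrix.embedding, leaf_size=leaf_size)

    def query(
        self,
        smorf_ranks: np.ndarray,
        k: int = DEFAULT_K,
        rho_min: float = DEFAULT_RHO_MIN,
    ) -> list[CorrelationHit]:
        """Genes with Spearman rho >= rho_min versus the query, at most k.

        ``smorf_ranks`` is a rank vector over the same samples as the index.
        """
        _validate_query_params(k, rho_min)
        q = _standardize(np.asarray(smorf_ranks, dtype=float))
        if q is None:
            raise DataError("query rank vector has zero variance")
        if q.size != self.rank_matrix.embedding.shape[1]:
            raise DataError("query length does not match index sample count")
        radius = np.sqrt(max(0.0, 2.0 * (1.0 - rho_min))) + _RADIUS_PAD
        candidates = self._tree.query_radius(q[None, :], r=radius)[0]
        return _select_hits(self.rank_matrix, candidates, q, k, rho_min)

    @property
    def metadata(self) -> dict:
        return {
            "leaf_size": self.leaf_size,
            "n_features": len(self.rank_matrix.feature_ids),
            "n_samples": len(self.rank_matrix.sample_ids),
            "excluded_zero_variance": ",".join(self.rank_matrix.excluded),
        }


def brute_force_query(
    rank_matrix: RankMatrix,
    smorf_ranks: np.ndarray,
    k: int = DEFAULT_K,
    rho_min: float = DEFAULT_RHO_MIN,
) -> list[CorrelationHit]:
    """Pre-ranked brute force: score every feature, no index."""
    _validate_query_params(k, rho_min)
    q = _standardize(np.asarray(smorf_ranks, dtype=float))
    if q is None:
        raise DataError("query rank vector has zero variance")
    candidates = np.arange(rank_matrix.embedding.shape[0])
    return _select_hits(rank_matrix, candidates, q, k, rho_min)


def query_correlated_genes(
    expr: pd.DataFrame,
    smorf_values: Sequence[float],
    k: int = DEFAULT_K,
    rho_min: float = DEFAULT_RHO_MIN,
    strategy: str = "tree",
    leaf_size: int = DEFAULT_LEAF_SIZE,
) -> list[CorrelationHit]:
    """One-shot search for genes correlated with a smORF expression row.

    ``strategy`` selects among the three equivalent search paths:
    ``raw`` ranks rows on the fly and scores them all (no pre-ranking, brute
    force); ``preranked`` ranks once then scores all; ``tree`` ranks once and
    queries the BallTree. All three return identical hit lists; they differ
    only in speed.
    """
    if strategy not in ("raw", "preranked", "tree"):
        raise ValueError(f"unknown strategy {strategy!r}")
    smorf_ranks = rank_transform(smorf_values)
    if strategy == "raw":
        # Ranking row-by-row at query time; scoring shares _select_hits so
        # results are bit-identical to the pre-ranked paths.
        rows = []
        ids = []
        excluded = []
        for fid, row in zip(expr.index, expr.to_numpy(dtype=float)):
            r = rank_transform(row)
            s = _standardize(r)
            if s is None:
                excluded.append(fid)
                continue
            rows.append((r, s))
            ids.append(fid)
        rm = RankMatrix(
            feature_ids=ids,
            sample_ids=list(expr.columns),
            ranks=np.array([r for r, _ in rows]),
            embedding=np.array([s for _, s in rows]),
            excluded=excluded,
        )
        return brute_force_query(rm, smorf_ranks, k=k, rho_min=rho_min)
    rm = RankMatrix.from_expression(expr)
    if strategy == "preranked":
        return brute_force_query(rm, smorf_ranks, k=k, rho_min=rho_min)
    return CorrelationIndex(rm, leaf_size=leaf_size).query(
        smorf_ranks, k=k, rho_min=rho_min
    )
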