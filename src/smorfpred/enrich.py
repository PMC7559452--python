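"""Function prediction by hypergeometric gene-set enrichment.

A smORF's correlated genes (guilt by association) are tested against
functional gene sets. Within one dataset S, with a background of T_S genes of
which M_S belong to the term, and N_S correlated genes of which I_S belong to
the term, the enrichment p-value is the upper hypergeometric tail

    p_S = sum_{x=I_S}^{N_S} C(M_S, x) * C(T_S - M_S, N_S - x) / C(T_S, N_S),

terms with x > M_S or N_S - x > T_S - M_S contributing zero. Evidence from
several datasets is pooled by summing the counts component-wise
(sum I_S, sum M_S, sum N_S, sum T_S) and evaluating the same tail on the
sums — never by combining the p-values themselves. The Benjamini–Hochberg
step-up procedure controls the FDR across the tested terms (within each
gene-set collection by default), and a term is called a predicted function
when pooled p <= 0.05 and FDR <= 0.2.

The background T_S is the intersection of the genes quantifiable on the
platform (annotated by probe sets) with the union of all gene-set members,
so both the draw and the urn live in the same gene universe.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .coexpr import (
    DEFAULT_K,
    DEFAULT_LEAF_SIZE,
    DEFAULT_RHO_MIN,
    CorrelationIndex,
    RankMatrix,
    rank_transform,
)
from .errors import DataError

DEFAULT_P_MAX = 0.05
DEFAULT_FDR_MAX = 0.2

COLLECTIONS = ("GO-BP", "GO-CC", "GO-MF", "KEGG", "REACTOME", "custom")


@dataclass(frozen=True)
class GeneSet:
    """A named functional term with its member genes."""

    term_id: str
    collection: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError(f"gene set {self.term_id} has no members")
        if self.collection not in COLLECTIONS:
            raise DataError(
                f"gene set {self.term_id}: unknown collection {self.collection!r}"
            )


@dataclass(frozen=True)
class DatasetCounts:
    """The 2x2-table counts of one term in one dataset.

    n_overlap   correlated genes belonging to the term (I_S)
    n_term      term genes present in the background (M_S)
    n_correlated correlated genes present in the background (N_S)
    n_background background size (T_S)
    """

    dataset_id: str
    n_overlap: int
    n_term: int
    n_correlated: int
    n_background: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.n_overlap <= min(self.n_term, self.n_correlated)
            and self.n_term <= self.n_background
            and self.n_correlated <= self.n_background
        )
        if not ok:
            raise DataError(
                f"inconsistent counts in dataset {self.dataset_id}: "
                f"I={self.n_overlap}, M={self.n_term}, "
                f"N={self.n_correlated}, T={self.n_background}"
            )


def make_background(
    dataset_genes: Iterable[str], gene_sets: Sequence[GeneSet]
) -> set[str]:
    """Background universe: platform-annotated genes ∩ union of set members."""
    genes = set(dataset_genes)
    if not genes:
        raise DataError("dataset gene list is empty")
    if not gene_sets:
        raise DataError("no gene sets supplied")
    union: set[str] = set()
    for gs in gene_sets:
        union |= gs.members
    background = genes & union
    if not background:
        raise DataError(
            "background is empty: no overlap between dataset genes and "
            "gene-set members"
        )
    return background


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _hypergeom_sf(i_min: int, total: int, n_term: int, n_draw: int) -> float:
    """P[X >= i_min] for X ~ Hypergeom(total, n_term, n_draw), via log-gamma."""
    support_min = max(0, n_draw - (total - n_term))
    if i_min <= support_min:
        return 1.0
    hi = min(n_term, n_draw)
    if i_min > hi:
        return 0.0
    x = np.arange(i_min, hi + 1, dtype=float)
    log_terms = (
        _log_comb(float(n_term), x)
        + _log_comb(float(total - n_term), n_draw - x)
        - _log_comb(float(total), float(n_draw))
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def hypergeom_tail(counts: DatasetCounts) -> float:
    """Upper-tail enrichment p-value for one dataset's counts."""
    return _hypergeom_sf(
        counts.n_overlap, counts.n_background, counts.n_term, counts.n_correlated
    )


def pool_counts(per_dataset: Sequence[DatasetCounts]) -> DatasetCounts:
    """Component-wise sums of the counts across datasets."""
    if not per_dataset:
        raise DataError("cannot pool an empty list of dataset counts")
    return DatasetCounts(
        dataset_id="pooled",
        n_overlap=sum(c.n_overlap for c in per_dataset),
        n_term=sum(c.n_term for c in per_dataset),
        n_correlated=sum(c.n_correlated for c in per_dataset),
        n_background=sum(c.n_background for c in per_dataset),
    )


def pooled_p(per_dataset: Sequence[DatasetCounts]) -> float:
    """The hypergeometric tail evaluated on the across-dataset count sums."""
    return hypergeom_tail(pool_counts(per_dataset))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class Dataset:
    """One expression dataset: gene-level and smORF-level log2 matrices."""

    dataset_id: str
    genes: pd.DataFrame
    smorfs: pd.DataFrame


@dataclass
class EnrichmentResult:
    """One term's evidence across datasets plus the pooled verdict."""

    term_id: str
    collection: str
    per_dataset: list[tuple[DatasetCounts, float]]
    pooled: DatasetCounts
    p: float
    fdr: float = float("nan")
    selected: bool = False


@dataclass
class PredictionReport:
    """Full prediction output for one smORF."""

    smorf_id: str
    status: str  # "ok" or "unquantifiable"
    results: list[EnrichmentResult] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def predict_functions(
    smorf_id: str,
    datasets: Sequence[Dataset],
    gene_sets: Sequence[GeneSet],
    k: int = DEFAULT_K,
    rho_min: float = DEFAULT_RHO_MIN,
    p_max: float = DEFAULT_P_MAX,
    fdr_max: float = DEFAULT_FDR_MAX,
    leaf_size: int = DEFAULT_LEAF_SIZE,
    fdr_family: str = "per-collection",
) -> PredictionReport:
    """Predict a smORF's functions from its correlated genes.

    Per dataset in which the smORF is quantified, at most ``k`` genes with
    Spearman rho >= ``rho_min`` are retained and tested against every gene
    set; counts are pooled across those datasets; BH FDR is computed within
    each collection (``fdr_family="per-collection"``, default) or jointly
    (``"all"``); a term is selected when p <= ``p_max`` and FDR <=
    ``fdr_max``. Datasets lacking the smORF contribute nothing to the pooled
    sums; terms absent from a dataset's background are skipped there.
    Results are sorted by pooled p ascending, then term id.
    """
    if fdr_family not in ("per-collection", "all"):
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    params = {
        "k": k,
        "rho_min": rho_min,
        "p_max": p_max,
        "fdr_max": fdr_max,
        "leaf_size": leaf_size,
        "fdr_family": fdr_family,
    }
    usable = [d for d in datasets if smorf_id in d.smorfs.index]
    if not usable:
        return PredictionReport(smorf_id, "unquantifiable", [], params)

    collection_of = {gs.term_id: gs.collection for gs in gene_sets}
    per_term: dict[str, list[tuple[DatasetCounts, float]]] = defaultdict(list)
    for ds in usable:
        background = make_background(ds.genes.index, gene_sets)
        # Zero-variance genes are uninformative: excluded from both the index
        # and the background so T_S counts only testable genes.
        rm = RankMatrix.from_expression(ds.genes.loc[sorted(background)])
        effective_bg = set(rm.feature_ids)
        index = CorrelationIndex(rm, leaf_size=leaf_size)
        smorf_ranks = rank_transform(ds.smorfs.loc[smorf_id].to_numpy(dtype=float))
        hits = index.query(smorf_ranks, k=k, rho_min=rho_min)
        correlated = {h.gene_id for h in hits}
        n_corr = len(correlated)
        n_bg = len(effective_bg)
        for gs in gene_sets:
            n_term = len(gs.members & effective_bg)
            if n_term == 0:
                continue
            counts = DatasetCounts(
                dataset_id=ds.dataset_id,
                n_overlap=len(correlated & gs.members),
                n_term=n_term,
                n_correlated=n_corr,
                n_background=n_bg,
            )
            per_term[gs.term_id].append((counts, hypergeom_tail(counts)))

    results = []
    for term_id, entries in per_term.items():
        pooled = pool_counts([c for c, _ in entries])
        results.append(
            EnrichmentResult(
                term_id=term_id,
                collection=collection_of[term_id],
                per_dataset=entries,
                pooled=pooled,
                p=hypergeom_tail(pooled),
            )
        )

    if results:
        if fdr_family == "per-collection":
            groups: dict[str, list[EnrichmentResult]] = defaultdict(list)
            for r in results:
                groups[r.collection].append(r)
            families = list(groups.values())
        else:
            families = [results]
        for family in families:
            adjusted = bh_fdr([r.p for r in family])
            for r, q in zip(family, adjusted):
                r.fdr = float(q)
                r.selected = r.p <= p_max and r.fdr <= fdr_max

    results.sort(key=lambda r: (r.p, r.term_id))
    return PredictionReport(smorf_id, "ok", results, params)


def results_frame(report: PredictionReport) -> pd.DataFrame:
    """Summary table: one row per term with pooled counts, p, FDR, selection."""
    rows = [
        {
            "term_id": r.term_id,
            "collection": r.collection,
            "I_sum": r.pooled.n_overlap,
            "M_sum": r.pooled.n_term,
            "N_sum": r.pooled.n_correlated,
            "T_sum": r.pooled.n_background,
            "p": r.p,
            "fdr": r.fdr,
            "selected": r.selected,
        }
        for r in report.results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "term_id", "collection", "I_sum", "M_sum", "N_sum", "T_sum",
            "p", "fdr", "selected",
        ],
    )


def per_dataset_frame(report: PredictionReport) -> pd.DataFrame:
    """Detail table: one row per (term, dataset) with counts and p_S."""
    rows = [
        {
            "term_id": r.term_id,
            "dataset_id": c.dataset_id,
            "I": c.n_overlap,
            "M": c.n_term,
            "N": c.n_correlated,
            "T": c.n_background,
            "p_dataset": p,
        }
        for r in report.results
        for c, p in r.per_dataset
    ]
    return pd.DataFrame(
        rows,
        columns=["term_id", "dataset_id", "I", "M", "N", "T", "p_dataset"],
    )
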