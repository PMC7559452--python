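"""Glue between the stages: bundle -> datasets -> prediction, and the
planted-truth benchmark loop used for validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .coexpr import DEFAULT_K, DEFAULT_LEAF_SIZE, DEFAULT_RHO_MIN
from .enrich import (
    DEFAULT_FDR_MAX,
    DEFAULT_P_MAX,
    Dataset,
    PredictionReport,
    predict_functions,
)
from .errors import DataError
from .genome import GenomicInterval, ProbeSetAnnotation, SmORF
from .quant import aggregate_duplicate_features, estimate_smorf_expression
from .simulate import (
    ExpressionBundle,
    SimulationConfig,
    simulate_expression,
    simulate_genome_and_platform,
    with_seed,
)


def build_dataset(
    dataset_id: str,
    probe_signals: pd.DataFrame,
    id_map: Mapping[str, str],
    annotations: Iterable[ProbeSetAnnotation],
    estimator: str = "median",
    weight_min: float = 0.1,
) -> Dataset:
    """Split one probe-set matrix into gene-level and smORF-level matrices.

    Probe sets present in ``id_map`` are aggregated to genes (duplicates by
    median); smORF expression is estimated from the annotation weights.
    """
    gene_rows = probe_signals.loc[[p for p in probe_signals.index if p in id_map]]
    genes = aggregate_duplicate_features(gene_rows, id_map)
    smorfs, _ = estimate_smorf_expression(
        probe_signals, annotations, estimator=estimator, weight_min=weight_min
    )
    return Dataset(dataset_id=dataset_id, genes=genes, smorfs=smorfs)


def bundle_to_datasets(
    bundle: ExpressionBundle,
    annotations: Iterable[ProbeSetAnnotation],
    estimator: str = "median",
    weight_min: float = 0.1,
) -> list[Dataset]:
    annotations = list(annotations)
    return [
        build_dataset(ds_id, matrix, bundle.id_map, annotations,
                      estimator=estimator, weight_min=weight_min)
        for ds_id, matrix in bundle.probe_matrices.items()
    ]


def resolve_smorf_query(
    smorfs: Sequence[SmORF],
    genome: Mapping[str, str] | None = None,
    smorf_id: str | None = None,
    coordinate: str | None = None,
    sequence: str | None = None,
) -> SmORF:
    """Resolve a query (id, 'chrom:start-end' coordinate, or exact sequence)
    to a single smORF; coordinate queries match by interval overlap."""
    modes = [m for m in (smorf_id, coordinate, sequence) if m is not None]
    if len(modes) != 1:
        raise DataError("supply exactly one of smorf_id, coordinate, sequence")
    if smorf_id is not None:
        for s in smorfs:
            if s.smorf_id == smorf_id:
                return s
        raise DataError(f"smORF {smorf_id!r} not found")
    if coordinate is not None:
        try:
            chrom, span = coordinate.rsplit(":", 1)
            start, end = (int(x) for x in span.split("-"))
            query = GenomicInterval(chrom, start, end)
        except (ValueError, DataError) as exc:
            raise DataError(
                f"cannot parse coordinate {coordinate!r}; expected chrom:start-end"
            ) from exc
        hits = [s for s in smorfs if s.interval.overlaps(query)]
        if not hits:
            nearest = sorted(
                (s for s in smorfs if s.interval.chrom == chrom),
                key=lambda s: min(
                    abs(s.interval.start - start), abs(s.interval.end - end)
                ),
            )[:3]
            hint = ", ".join(
                f"{s.smorf_id}@{s.interval.chrom}:{s.interval.start}-{s.interval.end}"
                for s in nearest
            )
            raise DataError(
                f"no smORF overlaps {coordinate}; nearest: {hint or 'none on chromosome'}"
            )
        hits.sort(key=lambda s: (s.interval.start, s.smorf_id))
        return hits[0]
    if genome is None:
        raise DataError("sequence queries require the genome FASTA")
    seq = sequence.strip().upper()
    for s in smorfs:
        iv = s.interval
        chrom_seq = genome.get(iv.chrom)
        if chrom_seq is not None and chrom_seq[iv.start : iv.end] == seq:
            return s
    raise DataError("no smORF with that exact sequence")


@dataclass
class ReplicateOutcome:
    """Planted-truth recovery for one simulated replicate."""

    report: PredictionReport
    planted_term: str
    planted_selected: bool
    planted_rank: int | None  # 0-based rank by pooled p, None if untested


def run_planted_replicate(
    config: SimulationConfig,
    seed: int,
    k: int = DEFAULT_K,
    rho_min: float = DEFAULT_RHO_MIN,
    p_max: float = DEFAULT_P_MAX,
    fdr_max: float = DEFAULT_FDR_MAX,
    leaf_size: int = DEFAULT_LEAF_SIZE,
) -> ReplicateOutcome:
    """Simulate one replicate and test recovery of the first planted module.

    The expression layer is generated from the replicate seed and pushed
    through quantification, correlation search and enrichment using the
    platform truth annotations (the platform layer is deterministic given
    the config and is exercised separately).
    """
    cfg = with_seed(config, seed)
    module = cfg.module_spec[0]
    platform = simulate_genome_and_platform(cfg)
    expression = simulate_expression(cfg)
    datasets = bundle_to_datasets(expression, platform.truth_annotations())
    report = predict_functions(
        module.smorf_id,
        datasets,
        expression.gene_sets,
        k=k,
        rho_min=rho_min,
        p_max=p_max,
        fdr_max=fdr_max,
        leaf_size=leaf_size,
    )
    rank = None
    selected = False
    for i, r in enumerate(report.results):
        if r.term_id == module.term_id:
            rank = i
            selected = r.selected
            break
    return ReplicateOutcome(report, module.term_id, selected, rank)


def recovery_rate(
    config: SimulationConfig, n_replicates: int, base_seed: int
) -> float:
    """Fraction of replicates in which the planted term is selected."""
    hits = 0
    for i in range(n_replicates):
        outcome = run_planted_replicate(config, seed=base_seed + i)
        hits += outcome.planted_selected
    return hits / n_replicates
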