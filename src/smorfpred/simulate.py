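"""Synthetic fixtures with planted ground truth.

Two generators cover the pipeline's inputs end to end:

``simulate_genome_and_platform``
    Builds a genome whose sequence embeds each probe the intended number of
    times, smORF intervals overlapping known subsets of probe sets, and a
    truth table of intended (probe_set, smorf, weight) annotations. Decoys
    exercise the filters: a probe planted in 100 tandem copies (rejected by
    the <100-matches rule), an unmatchable probe, and probe sets whose
    overlap weight is exactly 0.1 (dropped by quantification).

``simulate_expression``
    Draws multi-dataset probe-set signal matrices on a log2-like scale with
    planted co-expression: a module (gene set, smORF, target Spearman rho*)
    shares a Gaussian latent factor. For a bivariate Gaussian with Pearson
    correlation r, the Spearman correlation is (6/pi)*asin(r/2), so the
    factor loading uses r = 2*sin(pi*rho*/6) and planted pairs reach rho*
    in expectation. Rank-based downstream analysis is unaffected by the
    location/scale used to place values on the log2 scale. A configurable
    fraction of values is rounded to one decimal to force rank ties.

Both are deterministic functions of the single config seed; sub-generators
derive child seeds from it. What the generator deliberately does not model:
probe-affinity effects, batch effects, array saturation, or multi-exon
smORFs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import GeneSet
from .errors import CalibrationError
from .genome import GenomicInterval, Probe, ProbeSetAnnotation, SmORF
from . import io as sio

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedModule:
    """One planted co-expression module: a term, a smORF, a target Spearman."""

    term_id: str
    smorf_id: str
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise CalibrationError(
                f"module {self.term_id}: target rho {self.rho} not attainable; "
                "need 0 <= rho < 1"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: 2000 background genes, 3 smORFs, 3 datasets of 60 samples,
    40 gene sets of 50 genes, one module planting rho* = 0.8 between the
    first smORF and the first term's members. Probe sets carry 10 probes of
    25 nt; the main smORF probe sets overlap 8/10 probes (weight 0.8) and
    low-weight decoy sets overlap 1/10 (weight 0.1, sub-threshold).
    """

    seed: int = 0
    n_genes: int = 2000
    n_smorfs: int = 3
    n_samples: int = 60
    n_datasets: int = 3
    module_spec: tuple[PlantedModule, ...] = (
        PlantedModule("SET_0001", "smorf_0001", 0.8),
    )
    noise_sd: float = 1.0
    tie_fraction: float = 0.1
    probes_per_set: int = 10
    decoy_weight_fraction: float = 0.34
    n_gene_sets: int = 40
    gene_set_size: int = 50
    probe_length: int = 25
    overlapping_probes: int = 8
    baseline_log2: float = 7.0
    probe_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        positive = {
            "n_genes": self.n_genes,
            "n_smorfs": self.n_smorfs,
            "n_samples": self.n_samples,
            "n_datasets": self.n_datasets,
            "probes_per_set": self.probes_per_set,
            "n_gene_sets": self.n_gene_sets,
            "gene_set_size": self.gene_set_size,
            "probe_length": self.probe_length,
            "overlapping_probes": self.overlapping_probes,
        }
        for name, value in positive.items():
            if value <= 0:
                raise CalibrationError(f"{name} must be positive, got {value}")
        if self.noise_sd <= 0 or self.probe_noise_sd < 0:
            raise CalibrationError("noise_sd must be positive")
        if not (0.0 <= self.tie_fraction < 1.0):
            raise CalibrationError("tie_fraction must lie in [0, 1)")
        if not (0.0 <= self.decoy_weight_fraction <= 1.0):
            raise CalibrationError("decoy_weight_fraction must lie in [0, 1]")
        if self.overlapping_probes > self.probes_per_set:
            raise CalibrationError(
                "overlapping_probes cannot exceed probes_per_set"
            )
        if self.overlapping_probes * self.probe_length > 303:
            raise CalibrationError(
                "smORF would exceed 303 nt; reduce overlapping_probes or "
                "probe_length"
            )
        if self.gene_set_size > self.n_genes:
            raise CalibrationError("gene_set_size cannot exceed n_genes")
        for module in self.module_spec:
            if module.rho > 0:
                r = pearson_for_spearman(module.rho)
                if not r < 1.0:
                    raise CalibrationError(
                        f"module {module.term_id}: rho {module.rho} needs a "
                        f"latent Pearson loading {r:.3f} >= 1"
                    )


def pearson_for_spearman(rho_s: float) -> float:
    """Pearson r giving Spearman rho_s under a bivariate Gaussian copula."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    # crc32 is a stable hash (str hash randomisation would break determinism)
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(stream.encode())])
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def gene_ids(config: SimulationConfig) -> list[str]:
    return [f"g{i:05d}" for i in range(config.n_genes)]


def smorf_ids(config: SimulationConfig) -> list[str]:
    return [f"smorf_{i + 1:04d}" for i in range(config.n_smorfs)]


@dataclass
class PlatformBundle:
    """Genome + platform layer with its planted annotation truth."""

    genome: dict[str, str]
    probes: list[Probe]
    smorfs: list[SmORF]
    truth: pd.DataFrame  # columns: probe_set_id, smorf_id, weight

    def truth_annotations(self) -> list[ProbeSetAnnotation]:
        return [
            ProbeSetAnnotation(r.probe_set_id, r.smorf_id, float(r.weight))
            for r in self.truth.itertuples(index=False)
        ]


def simulate_genome_and_platform(config: SimulationConfig) -> PlatformBundle:
    """Construct genome, probes and smORFs whose reannotation is known.

    Layout (single chromosome): per smORF, a main probe set of
    ``probes_per_set`` contiguous probes with the smORF covering the first
    ``overlapping_probes`` of them (weight overlapping/total); a fraction of
    smORFs also gets a decoy probe set contributing exactly one probe that
    straddles the smORF boundary (weight 1/probes_per_set = 0.1 at the
    defaults). One probe set carries a probe planted in 100 tandem copies
    (too ambiguous to retain), one probe that never matches, and one probe
    with a non-ACGT character.
    """
    rng = _child_rng(config.seed, "platform")
    L = config.probe_length
    per_set = config.probes_per_set
    chrom = "chr1"

    segments: list[str] = []
    cursor = 0

    def emit(seq: str) -> int:
        nonlocal cursor
        start = cursor
        segments.append(seq)
        cursor += len(seq)
        return start

    def filler(n: int = 37) -> None:
        emit(_random_seq(rng, n))

    probes: list[Probe] = []
    smorfs: list[SmORF] = []
    truth_rows: list[tuple[str, str, float]] = []

    n_decoy = int(round(config.decoy_weight_fraction * config.n_smorfs))
    filler(50)
    for i, smorf_id in enumerate(smorf_ids(config)):
        set_id = f"ps_{smorf_id}"
        probe_seqs = [_random_seq(rng, L) for _ in range(per_set)]
        block_start = emit("".join(probe_seqs))
        for j, seq in enumerate(probe_seqs):
            probes.append(Probe(set_id, f"{set_id}_p{j:02d}", seq))
        n_over = config.overlapping_probes
        smorf_start = block_start
        smorf_end = block_start + n_over * L
        smorfs.append(
            SmORF(smorf_id, GenomicInterval(chrom, smorf_start, smorf_end, "+"))
        )
        truth_rows.append((set_id, smorf_id, n_over / per_set))

        if i < n_decoy:
            # One decoy probe straddling the smORF 3' boundary: its sequence
            # is read from the genome so it matches exactly once and shares
            # 12 bases with the smORF interval.
            decoy_id = f"ps_decoy_{smorf_id}"
            genome_so_far = "".join(segments)
            straddle_start = smorf_end - 12
            decoy_seq = genome_so_far[straddle_start : straddle_start + L]
            probes.append(Probe(decoy_id, f"{decoy_id}_p00", decoy_seq))
            for j in range(1, per_set):
                seq = _random_seq(rng, L)
                emit(seq)
                filler(11)
                probes.append(Probe(decoy_id, f"{decoy_id}_p{j:02d}", seq))
            truth_rows.append((decoy_id, smorf_id, 1 / per_set))
        filler()

    # Multi-copy decoy: first probe planted in exactly 100 tandem copies.
    multi_id = "ps_multicopy"
    multi_seq = _random_seq(rng, L)
    emit(multi_seq * 100)
    filler()
    probes.append(Probe(multi_id, f"{multi_id}_p00", multi_seq))
    for j in range(1, per_set):
        seq = _random_seq(rng, L)
        emit(seq)
        filler(11)
        probes.append(Probe(multi_id, f"{multi_id}_p{j:02d}", seq))

    # Never-matching probe and a probe with a non-DNA character.
    unmatched = _random_seq(rng, L)
    genome_seq = "".join(segments)
    while unmatched in genome_seq:  # pragma: no cover - astronomically unlikely
        unmatched = _random_seq(rng, L)
    probes.append(Probe("ps_unmatched", "ps_unmatched_p00", unmatched))
    probes.append(Probe("ps_invalid", "ps_invalid_p00", "ACGTN" + "A" * (L - 5)))
    filler(50)

    genome = {chrom: "".join(segments)}
    truth = pd.DataFrame(truth_rows, columns=["probe_set_id", "smorf_id", "weight"])
    return PlatformBundle(genome=genome, probes=probes, smorfs=smorfs, truth=truth)


def make_gene_sets(config: SimulationConfig) -> list[GeneSet]:
    """Planted terms (dedicated member blocks) plus random decoy terms."""
    rng = _child_rng(config.seed, "gene_sets")
    genes = gene_ids(config)
    sets: list[GeneSet] = []
    planted_terms = {m.term_id for m in config.module_spec}
    block = 0
    collections = ("GO-BP", "GO-CC", "GO-MF", "KEGG", "REACTOME")
    for k, module in enumerate(config.module_spec):
        members = genes[block : block + config.gene_set_size]
        block += config.gene_set_size
        sets.append(GeneSet(module.term_id, collections[k % len(collections)], frozenset(members)))
    for k in range(len(sets), config.n_gene_sets):
        term_id = f"SET_{k + 1:04d}"
        if term_id in planted_terms:
            term_id = f"SET_DECOY_{k + 1:04d}"
        members = rng.choice(genes, size=config.gene_set_size, replace=False)
        sets.append(
            GeneSet(term_id, collections[k % len(collections)], frozenset(members))
        )
    return sets


def planted_members(config: SimulationConfig) -> dict[str, list[str]]:
    """term_id -> the dedicated member genes of each planted module."""
    genes = gene_ids(config)
    out = {}
    block = 0
    for module in config.module_spec:
        out[module.term_id] = genes[block : block + config.gene_set_size]
        block += config.gene_set_size
    return out


@dataclass
class ExpressionBundle:
    """Per-dataset probe-set matrices plus the id map and latent truth."""

    probe_matrices: dict[str, pd.DataFrame]
    id_map: dict[str, str]  # gene probe set -> gene id
    gene_sets: list[GeneSet]
    config: SimulationConfig
    smorf_probe_sets: dict[str, list[str]] = field(default_factory=dict)


def _gene_probe_map(config: SimulationConfig) -> dict[str, str]:
    """One probe set per gene; the first 10 genes get a duplicate set to
    exercise median aggregation of duplicate gene ids."""
    id_map = {f"psg_{g}": g for g in gene_ids(config)}
    for g in gene_ids(config)[: min(10, config.n_genes)]:
        id_map[f"psg_{g}_b"] = g
    return id_map


def simulate_expression(
    config: SimulationConfig, dataset_seed_offset: int = 0
) -> ExpressionBundle:
    """Draw probe-set level log2 signal matrices with planted correlation.

    Planted module members and the module's smORF share a latent factor with
    loading sqrt(r), r = 2*sin(pi*rho*/6); everything else is independent
    noise. smORF probe sets repeat the smORF latent signal with small probe
    noise, so the estimated smORF expression tracks the latent and the
    planted pairwise Spearman approaches rho*.
    """
    genes = gene_ids(config)
    id_map = _gene_probe_map(config)
    gene_sets = make_gene_sets(config)
    members = planted_members(config)
    module_of_gene: dict[str, int] = {}
    module_of_smorf: dict[str, int] = {}
    loadings = []
    for m_idx, module in enumerate(config.module_spec):
        loadings.append(math.sqrt(pearson_for_spearman(module.rho)))
        module_of_smorf[module.smorf_id] = m_idx
        for g in members[module.term_id]:
            module_of_gene[g] = m_idx

    smorf_probe_sets = {
        s: [f"ps_{s}"] for s in smorf_ids(config)
    }

    matrices: dict[str, pd.DataFrame] = {}
    for d in range(config.n_datasets):
        rng = _child_rng(config.seed, f"expr_{d + dataset_seed_offset}")
        n = config.n_samples
        factors = rng.standard_normal((len(config.module_spec), n))

        def latent(feature: str, modules: dict[str, int]) -> np.ndarray:
            eps = rng.standard_normal(n)
            m_idx = modules.get(feature)
            if m_idx is None:
                return eps
            a = loadings[m_idx]
            return a * factors[m_idx] + math.sqrt(1.0 - a * a) * eps

        rows: dict[str, np.ndarray] = {}
        for g in genes:
            z = latent(g, module_of_gene)
            rows[f"psg_{g}"] = config.baseline_log2 + config.noise_sd * z
        for g in genes[: min(10, config.n_genes)]:
            dup = rows[f"psg_{g}"] + config.probe_noise_sd * rng.standard_normal(n)
            rows[f"psg_{g}_b"] = dup
        for s in smorf_ids(config):
            z = latent(s, module_of_smorf)
            base = config.baseline_log2 + config.noise_sd * z
            for ps in smorf_probe_sets[s]:
                rows[ps] = base + config.probe_noise_sd * rng.standard_normal(n)
        # Decoy probe sets: independent noise (their weights are dropped).
        n_decoy = int(round(config.decoy_weight_fraction * config.n_smorfs))
        for s in smorf_ids(config)[:n_decoy]:
            rows[f"ps_decoy_{s}"] = (
                config.baseline_log2 + config.noise_sd * rng.standard_normal(n)
            )

        matrix = pd.DataFrame.from_dict(
            rows,
            orient="index",
            columns=[f"ds{d + 1}_s{j + 1:03d}" for j in range(n)],
        )
        if config.tie_fraction > 0:
            mask = rng.random(matrix.shape) < config.tie_fraction
            values = matrix.to_numpy()
            values[mask] = np.round(values[mask], 1)
            matrix = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
        matrix.index.name = "probe_set_id"
        matrices[f"ds{d + 1}"] = matrix

    return ExpressionBundle(
        probe_matrices=matrices,
        id_map=id_map,
        gene_sets=gene_sets,
        config=config,
        smorf_probe_sets=smorf_probe_sets,
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)


def write_bundle(
    outdir: str | Path,
    platform: PlatformBundle,
    expression: ExpressionBundle,
) -> dict[str, Path]:
    """Write a complete fixture bundle in the formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "probes": outdir / "probes.tsv",
        "smorfs": outdir / "smorfs.bed",
        "truth": outdir / "annotation_truth.tsv",
        "id_map": outdir / "probeset_gene_map.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
    }
    sio.write_genome_fasta(paths["genome"], platform.genome)
    sio.write_probe_table(paths["probes"], platform.probes)
    sio.write_smorf_bed(paths["smorfs"], platform.smorfs)
    platform.truth.to_csv(paths["truth"], sep="\t", index=False)
    sio.write_id_map(paths["id_map"], expression.id_map)
    sio.write_gmt(paths["gene_sets"], expression.gene_sets)
    for ds_id, matrix in expression.probe_matrices.items():
        p = outdir / f"expression_{ds_id}.tsv"
        sio.write_expression_matrix(p, matrix)
        paths[f"expression_{ds_id}"] = p
    return paths
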