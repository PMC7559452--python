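"""Probe reannotation: exact genome matching, smORF intersection, weights.

Microarray probes are short oligos grouped into probe sets that are summarised
into one signal per sample. To attribute probe-set signal to small open
reading frames (smORFs, < 100 codons), each probe is matched exactly
(zero mismatches, both strands) against the genome; probes with at least one
match and fewer than ``max_hits`` (default 100) matches are retained. A probe
set is annotated to a smORF when at least one retained probe shares >= 1 base
with the smORF interval, and the annotation carries the weight

    w = (retained probes of the set overlapping the smORF)
        / (retained probes of the set)

so ``0 < w <= 1``. Weights for distinct smORFs hit by the same probe set are
not normalised against each other: overlapping smORFs legitimately share the
probe-set signal. Coordinates are 0-based half-open (BED convention)
throughout.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .errors import DataError

log = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")

#: Longest smORF in nucleotides: 100 codons plus the stop codon.
MAX_SMORF_NT = 303

#: A probe with this many genomic matches or more is discarded as ambiguous.
DEFAULT_MAX_HITS = 100

_DNA_RE = re.compile(r"[ACGT]+\Z")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise DataError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base (strand-agnostic)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SmORF:
    """A small open reading frame modelled as one contiguous interval."""

    smorf_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.length_nt > MAX_SMORF_NT:
            raise DataError(
                f"smORF {self.smorf_id} spans {self.length_nt} nt, "
                f"exceeding the {MAX_SMORF_NT} nt (100-codon) limit"
            )

    @property
    def length_nt(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class Probe:
    probe_set_id: str
    probe_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.strip().upper())
        if not self.sequence:
            raise DataError(f"probe {self.probe_id}: empty sequence")

    @property
    def is_valid_dna(self) -> bool:
        return bool(_DNA_RE.match(self.sequence))


@dataclass
class ProbeAlignment:
    """All exact genomic matches of one probe, plus the retention verdict."""

    probe: Probe
    matches: list[GenomicInterval] = field(default_factory=list)
    retained: bool = False


def match_probe(
    probe: Probe,
    genome: Mapping[str, str],
    max_hits: int = DEFAULT_MAX_HITS,
) -> ProbeAlignment:
    """Find every exact occurrence of a probe in the genome, both strands.

    Forward-strand occurrences of the probe sequence are reported on ``+``;
    occurrences of its reverse complement are reported on ``-``. The probe is
    retained iff it has at least one match and fewer than ``max_hits``
    matches. Probes containing non-ACGT characters are rejected (reported
    unmatched) with a log diagnostic. Matches are ordered by
    (chrom, start, strand).
    """
    if not probe.is_valid_dna:
        log.warning(
            "probe %s/%s contains non-ACGT characters; treated as unmatched",
            probe.probe_set_id,
            probe.probe_id,
        )
        return ProbeAlignment(probe)

    seq = probe.sequence
    patterns = [(seq, "+")]
    rc = reverse_complement(seq)
    if rc != seq:  # a palindromic probe's rc occurrence is the same locus
        patterns.append((rc, "-"))

    matches: list[GenomicInterval] = []
    for chrom in sorted(genome):
        chrom_seq = genome[chrom]
        for pattern, strand in patterns:
            pos = chrom_seq.find(pattern)
            while pos != -1:
                matches.append(
                    GenomicInterval(chrom, pos, pos + len(seq), strand)
                )
                pos = chrom_seq.find(pattern, pos + 1)
    matches.sort()
    retained = 0 < len(matches) < max_hits
    return ProbeAlignment(probe, matches, retained)


def intersect_with_smorfs(
    alignments: Iterable[ProbeAlignment],
    smorfs: Iterable[SmORF],
) -> dict[tuple[str, str], int]:
    """Count, per (probe set, smORF), the retained probes overlapping the smORF.

    A probe overlaps a smORF iff any of its match intervals shares at least
    one base with the smORF interval (strand-agnostic, matching the default
    behaviour of standard interval-intersection tools). A probe with several
    matches hitting the same smORF still counts once for that smORF.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for smorf in smorfs:
        iv = smorf.interval
        trees[iv.chrom].addi(iv.start, iv.end, smorf.smorf_id)

    counts: dict[tuple[str, str], int] = defaultdict(int)
    for aln in alignments:
        if not aln.retained:
            continue
        hit_smorfs: set[str] = set()
        for m in aln.matches:
            tree = trees.get(m.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(m.start, m.end):
                hit_smorfs.add(hit.data)
        for smorf_id in hit_smorfs:
            counts[(aln.probe.probe_set_id, smorf_id)] += 1
    return dict(counts)


@dataclass(frozen=True)
class ProbeSetAnnotation:
    """A (probe set, smORF) link weighted by the overlapping-probe fraction."""

    probe_set_id: str
    smorf_id: str
    weight: float

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise DataError(
                f"annotation {self.probe_set_id}->{self.smorf_id}: "
                f"weight {self.weight} outside (0, 1]"
            )


def retained_counts(alignments: Iterable[ProbeAlignment]) -> dict[str, int]:
    """Number of retained probes per probe set."""
    out: dict[str, int] = defaultdict(int)
    for aln in alignments:
        if aln.retained:
            out[aln.probe.probe_set_id] += 1
    return dict(out)


def compute_weights(
    counts: Mapping[tuple[str, str], int],
    retained_per_set: Mapping[str, int],
) -> list[ProbeSetAnnotation]:
    """Turn overlap counts into annotation weights w = count / retained.

    Sub-threshold weights (w <= 0.1) are kept here; dropping them is the
    quantification step's job so the threshold lives in one place.
    """
    annotations = []
    for (set_id, smorf_id), count in sorted(counts.items()):
        denom = retained_per_set.get(set_id, 0)
        if denom <= 0:
            raise DataError(
                f"probe set {set_id} has overlap counts but no retained probes"
            )
        if count > denom:
            raise DataError(
                f"probe set {set_id}: overlap count {count} exceeds "
                f"retained probe count {denom}"
            )
        annotations.append(ProbeSetAnnotation(set_id, smorf_id, count / denom))
    return annotations


def annotate_probe_sets(
    probes: Iterable[Probe],
    genome: Mapping[str, str],
    smorfs: Iterable[SmORF],
    max_hits: int = DEFAULT_MAX_HITS,
    denominator: str = "retained",
) -> tuple[list[ProbeSetAnnotation], dict[str, int]]:
    """Full reannotation: match -> intersect -> weight.

    ``denominator`` selects what "all the probes in the set" means for the
    weight: ``"retained"`` (default) divides by probes surviving the exact
    match / multi-hit filter; ``"all"`` divides by every probe originally in
    the set. Returns the annotations plus summary statistics.
    """
    if denominator not in ("retained", "all"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    probes = list(probes)
    smorfs = list(smorfs)
    alignments = [match_probe(p, genome, max_hits=max_hits) for p in probes]
    counts = intersect_with_smorfs(alignments, smorfs)
    if denominator == "retained":
        per_set = retained_counts(alignments)
    else:
        per_set = defaultdict(int)
        for p in probes:
            per_set[p.probe_set_id] += 1
    annotations = compute_weights(counts, per_set)
    stats = {
        "probes_read": len(probes),
        "probes_retained": sum(a.retained for a in alignments),
        "smorfs_read": len(smorfs),
        "annotations": len(annotations),
        "annotated_probe_sets": len({a.probe_set_id for a in annotations}),
    }
    return annotations, stats
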