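"""Readers and writers for the plain-text formats the pipeline consumes.

Genome FASTA (via pyfaidx), probe tables (TSV), smORF intervals (BED6),
annotation weights (TSV), expression matrices (TSV, features x samples),
gene sets (GMT), and flat key=value config/metadata sidecars.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from pyfaidx import Fasta

from .enrich import COLLECTIONS, GeneSet
from .errors import DataError
from .genome import GenomicInterval, Probe, ProbeSetAnnotation, SmORF

# MSigDB-style term prefixes mapped onto collections.
_GMT_PREFIXES = {
    "GOBP_": "GO-BP",
    "GOCC_": "GO-CC",
    "GOMF_": "GO-MF",
    "KEGG_": "KEGG",
    "REACTOME_": "REACTOME",
}


def read_genome_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a (possibly line-wrapped, multi-record) FASTA as uppercase strings."""
    try:
        fasta = Fasta(str(path), rebuild=True, build_index=True)
    except Exception as exc:  # pyfaidx raises several flavours
        raise DataError(f"cannot read FASTA {path}: {exc}") from exc
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def write_genome_fasta(path: str | os.PathLike, genome: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_probe_table(path: str | os.PathLike) -> list[Probe]:
    """TSV with columns probe_set_id, probe_id, sequence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_set_id", "probe_id", "sequence"}
    if not required.issubset(df.columns):
        raise DataError(
            f"probe table {path} must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    return [
        Probe(row.probe_set_id, row.probe_id, row.sequence)
        for row in df.itertuples(index=False)
    ]


def write_probe_table(path: str | os.PathLike, probes: Iterable[Probe]) -> None:
    pd.DataFrame(
        [(p.probe_set_id, p.probe_id, p.sequence) for p in probes],
        columns=["probe_set_id", "probe_id", "sequence"],
    ).to_csv(path, sep="\t", index=False)


def read_smorf_bed(path: str | os.PathLike) -> list[SmORF]:
    """BED6 smORF intervals: chrom, start, end, name, score (ignored), strand.

    Malformed lines raise DataError with the offending line number.
    """
    smorfs: list[SmORF] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise DataError(
                    f"{path}: line {lineno}: expected >= 4 BED columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise DataError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                smorfs.append(
                    SmORF(fields[3], GenomicInterval(fields[0], start, end, strand))
                )
            except DataError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from exc
    return smorfs


def write_smorf_bed(path: str | os.PathLike, smorfs: Iterable[SmORF]) -> None:
    with open(path, "w") as fh:
        for s in smorfs:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.smorf_id}\t0\t{iv.strand}\n"
            )


def read_annotations(path: str | os.PathLike) -> list[ProbeSetAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"probe_set_id": str, "smorf_id": str})
    required = {"probe_set_id", "smorf_id", "weight"}
    if not required.issubset(df.columns):
        raise DataError(
            f"annotation table {path} must have columns {sorted(required)}"
        )
    return [
        ProbeSetAnnotation(row.probe_set_id, row.smorf_id, float(row.weight))
        for row in df.itertuples(index=False)
    ]


def write_annotations(
    path: str | os.PathLike, annotations: Iterable[ProbeSetAnnotation]
) -> None:
    with open(path, "w") as fh:
        fh.write("probe_set_id\tsmorf_id\tweight\n")
        for a in annotations:
            fh.write(f"{a.probe_set_id}\t{a.smorf_id}\t{a.weight:.8g}\n")


def read_expression_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Features x samples TSV: first column feature id, header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        raise DataError(f"expression matrix {path} has duplicate feature ids")
    return df


def write_expression_matrix(path: str | os.PathLike, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")


def read_id_map(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV mapping probe_set_id -> gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"id map {path} needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_id_map(path: str | os.PathLike, id_map: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("probe_set_id\tgene_id\n")
        for key in id_map:
            fh.write(f"{key}\t{id_map[key]}\n")


def _collection_for_term(term_id: str) -> str:
    for prefix, collection in _GMT_PREFIXES.items():
        if term_id.startswith(prefix):
            return collection
    return "custom"


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """GMT gene sets: term, description, then member genes, tab-separated.

    The collection is inferred from MSigDB-style term prefixes (GOBP_, GOCC_,
    GOMF_, KEGG_, REACTOME_); anything else is 'custom'. A description field
    exactly matching a collection name overrides the prefix rule.
    """
    gene_sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}: line {lineno}: GMT needs term, description and "
                    "at least one member"
                )
            term, description = fields[0], fields[1]
            collection = (
                description
                if description in COLLECTIONS
                else _collection_for_term(term)
            )
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise DataError(f"{path}: line {lineno}: gene set has no members")
            gene_sets.append(GeneSet(term, collection, members))
    return gene_sets


def write_gmt(path: str | os.PathLike, gene_sets: Iterable[GeneSet]) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.term_id}\t{gs.collection}\t{members}\n")


def read_keyvalue(path: str | os.PathLike) -> dict[str, str]:
    """Flat key=value file; '#' starts a comment, blank lines ignored."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise DataError(f"{path}: line {lineno}: expected key=value")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def write_keyvalue(path: str | os.PathLike, data: Mapping[str, object]) -> None:
    with open(path, "w") as fh:
        for key, value in data.items():
            fh.write(f"{key}={value}\n")
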