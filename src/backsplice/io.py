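"""Readers, writers and run configuration.

Internal coordinates are 0-based half-open; GTF (1-based closed) and BED
dialects are converted exactly once, here.  Tabular outputs are TSV with
``#``-prefixed metadata header lines; gzip is auto-detected on read by the
``.gz`` suffix.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd
import pyfaidx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .annotation import (
    DIALECTS,
    ConfigError,
    Gene,
    GenomeAnnotation,
    Transcript,
    normalize_record,
)
from .quant import CountTable

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables; serialized verbatim into output metadata.

    j: exact-seed half-width in bases on each side of a junction.
    m: mismatch budget outside the seed (and for exclusion placements).
    W: junction-window half-width in bases; ``None`` means the read length.
    c: cutoff, the fraction of linear junctions declared RNase R-sensitive.
    """

    j: int = 5
    m: int = 2
    W: Optional[int] = None
    c: float = 0.90
    min_mock: int = 1
    min_reads: int = 2
    strandedness: str = "forward"
    pairing: str = "SE"
    tolerance: int = 0
    seed: int = 0
    random_tiebreak: bool = False
    raw_ratio: bool = False
    fold_cutoff: Optional[float] = None
    dialects: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.j < 1:
            raise ConfigError("j must be >= 1")
        if self.m < 0:
            raise ConfigError("m must be >= 0")
        if not 0.0 < self.c < 1.0:
            raise ConfigError("c must be in (0, 1)")
        if self.strandedness not in ("forward", "unstranded"):
            raise ConfigError(f"unknown strandedness {self.strandedness!r}")
        if self.pairing not in ("SE", "PE"):
            raise ConfigError(f"pairing must be SE or PE, got {self.pairing!r}")
        for name, dialect in (self.dialects or {}).items():
            if dialect not in DIALECTS:
                raise ConfigError(f"unknown dialect {dialect!r} for pipeline {name!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_genome_fasta(genome: dict[str, str], path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def load_genome(path) -> pyfaidx.Fasta:
    """Open an indexed genome FASTA (builds the .fai on first use)."""
    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a plain or gzipped FASTQ file."""
    with _open_text(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper()


def write_fastq(reads, path) -> Path:
    """Write (read_id, sequence) pairs as FASTQ with constant 'I' qualities."""
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path) -> GenomeAnnotation:
    """Parse exon features of a GTF (UCSC dialect) into gene models.

    1-based closed GTF coordinates become internal 0-based half-open.
    Missing gene_id/transcript_id attributes are fatal with the offending
    line number; non-exon features are skipped.  Overlapping exon lines
    within one transcript fail validation.
    """
    tx_info: dict[str, dict] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feature = feature_from_line(line)
            if feature.featuretype != "exon":
                continue
            try:
                gene_id = feature.attributes["gene_id"][0]
                tx_id = feature.attributes["transcript_id"][0]
            except KeyError as exc:
                raise ValueError(
                    f"{path} line {lineno}: exon lacks mandatory attribute {exc}"
                ) from None
            slot = tx_info.setdefault(
                tx_id,
                {"gene_id": gene_id, "chrom": feature.seqid,
                 "strand": feature.strand, "exons": []},
            )
            slot["exons"].append((feature.start - 1, feature.end))

    genes: dict[str, list[Transcript]] = {}
    gene_loc: dict[str, tuple[str, str]] = {}
    for tx_id in sorted(tx_info):
        info = tx_info[tx_id]
        exons = tuple(sorted(info["exons"]))
        transcript = Transcript(
            id=tx_id,
            gene_id=info["gene_id"],
            chrom=info["chrom"],
            strand=info["strand"],
            exons=exons,
        )
        genes.setdefault(info["gene_id"], []).append(transcript)
        gene_loc.setdefault(info["gene_id"], (info["chrom"], info["strand"]))
    return GenomeAnnotation(
        Gene(id=gid, chrom=gene_loc[gid][0], strand=gene_loc[gid][1],
             transcripts=tuple(txs))
        for gid, txs in sorted(genes.items())
    )


def write_gtf(annotation: GenomeAnnotation, path) -> Path:
    """Write exon features (1-based closed) with gene_id/transcript_id."""
    path = Path(path)
    with open(path, "w") as fh:
        for gene in annotation.genes:
            for tx in gene.transcripts:
                for s, e in tx.exons:
                    attrs = f'gene_id "{gene.id}"; transcript_id "{tx.id}";'
                    fh.write(
                        "\t".join(
                            [tx.chrom, "backsplice", "exon", str(s + 1), str(e),
                             ".", tx.strand, ".", attrs]
                        )
                        + "\n"
                    )
    return path


# ---------------------------------------------------------------------------
# BED candidate lists


def read_candidates_bed(path, dialect: str) -> tuple[list[tuple], int]:
    """Read a BED6 candidate list into normalized raw records.

    Returns ``(records, n_rejected)`` where each record is
    ``(chrom, start, end, strand, count_or_None)`` in internal 0-based
    half-open coordinates.  Records with strand '.' or malformed fields are
    rejected with a warning (strand is semantically required for a
    backsplice junction).
    """
    if dialect not in DIALECTS:
        raise ConfigError(f"unknown coordinate dialect {dialect!r}")
    records: list[tuple] = []
    n_rejected = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if len(f) < 6:
                    raise ValueError("fewer than 6 columns")
                chrom, start, end, _name, score, strand = f[:6]
                if strand not in ("+", "-"):
                    raise ValueError(f"strand {strand!r} is not + or -")
                chrom, s, e, strand = normalize_record(
                    chrom, int(start), int(end), strand, dialect
                )
                count = None if score in (".", "") else float(score)
            except ValueError as exc:
                n_rejected += 1
                log.warning("%s line %d rejected: %s", path, lineno, exc)
                continue
            records.append((chrom, s, e, strand, count))
    records.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    return records, n_rejected


def write_candidates_bed(candidates, path) -> Path:
    """Write merged candidates as BED6 (0-based half-open; score = total
    supporting-pipeline count)."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                "\t".join(
                    [c.chrom, str(c.start), str(c.end), c.circ_id,
                     str(len(c.pipelines)), c.strand]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# TSV with metadata headers


def write_tsv(df: pd.DataFrame, path, meta: Optional[dict] = None,
              index: bool = True) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_tsv(path, index_col=0) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with _open_text(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t", index_col=index_col)
    # classification columns hold 'true'/'false'/'rescued' strings, which
    # pandas would otherwise coerce to booleans
    if "classification" in df.columns and df["classification"].dtype == bool:
        df["classification"] = df["classification"].map({True: "true", False: "false"})
    return df, meta


def write_count_table(table: CountTable, path, extra_meta: Optional[dict] = None) -> Path:
    meta = {**table.summary(), **(extra_meta or {})}
    return write_tsv(table.counts, path, meta=meta)


def read_count_table(path) -> CountTable:
    df, meta = read_tsv(path, index_col="circ_id")
    return CountTable(
        library_id=meta.get("library_id", ""),
        library_size=int(meta.get("library_size", 0)),
        counts=df.astype(int),
        n_ambiguous=int(meta.get("n_ambiguous", 0)),
        n_excluded_genome=int(meta.get("n_excluded_genome", 0)),
        n_excluded_transcriptome=int(meta.get("n_excluded_transcriptome", 0)),
    )
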