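"""Construction of junction-centred reference sequences.

For every assigned circRNA candidate we build:

* a *circular window* — the last ``min(W, circle_length)`` bases of the
  circle sequence followed by its first ``min(W, circle_length)`` bases, so
  the backsplice junction sits at a recorded offset.  Only junction-spanning
  reads are ever counted, so a window of half-width ``W`` (at least the read
  length) carries the same counting semantics as indexing the full circle
  while staying small.  For circles shorter than ``W`` the window is the
  doubled circle, which still contains exactly one junction copy.
* *linear_left* / *linear_right* — the closest annotated exon upstream
  (downstream) of the circle within the chosen host transcript concatenated
  to the 5' (3') end of the circle sequence, carrying the host gene's
  canonical splice junction.  These quantify the linear mRNA of the host.

All sequences read 5'->3' on the transcript strand; a junction offset
points at the base immediately left of the junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .annotation import BoundaryAssignment, GenomeAnnotation, Transcript

log = logging.getLogger(__name__)


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Extract genome[chrom][start:end) from a dict of strings or an
    indexed FASTA (pyfaidx.Fasta)."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    length = len(genome[chrom])
    if start < 0 or end > length:
        raise ValueError(
            f"interval {chrom}:{start}-{end} outside chromosome of length {length}"
        )
    return str(genome[chrom][start:end]).upper()


@dataclass(frozen=True)
class JunctionReference:
    """Junction-centred sequences for one circRNA candidate.

    Offsets point at the base immediately left of the junction within the
    corresponding sequence. Absent linear sides are ``None``.
    """

    circ_id: str
    strand: str
    score: int
    circle_length: int
    W: int
    window: str
    window_offset: int
    linear_left: Optional[str] = None
    linear_left_offset: Optional[int] = None
    linear_right: Optional[str] = None
    linear_right_offset: Optional[int] = None

    def sequence(self, kind: str) -> Optional[str]:
        return {
            "circular": self.window,
            "linear_left": self.linear_left,
            "linear_right": self.linear_right,
        }[kind]

    def offset(self, kind: str) -> Optional[int]:
        return {
            "circular": self.window_offset,
            "linear_left": self.linear_left_offset,
            "linear_right": self.linear_right_offset,
        }[kind]


def circle_sequence(assignment: BoundaryAssignment, genome) -> str:
    """Circle sequence of an assigned candidate, 5'->3' on its strand.

    Score >= 1 candidates are spliced over the best-fit exon chain; score-0
    candidates fall back to the unspliced genomic span.
    """
    cand = assignment.candidate
    if assignment.score >= 1:
        pieces = [fetch(genome, cand.chrom, s, e) for s, e in assignment.exon_chain]
        seq = "".join(pieces)
    else:
        seq = fetch(genome, cand.chrom, cand.start, cand.end)
    if cand.strand == "-":
        seq = reverse_complement(seq)
    return seq


def build_circular_window(circle_seq: str, W: int) -> tuple[str, int]:
    """Rolled junction window: suffix(circle, k) + prefix(circle, k) with
    k = min(W, len); the junction sits between positions k-1 and k."""
    if not circle_seq:
        raise ValueError("empty circle sequence")
    if W < 1:
        raise ValueError("window half-width W must be >= 1")
    k = min(W, len(circle_seq))
    return circle_seq[-k:] + circle_seq[:k], k - 1


def _transcript_order_exons(transcript: Transcript) -> list[tuple[int, int]]:
    exons = list(transcript.exons)
    return exons[::-1] if transcript.strand == "-" else exons


def _exon_seq(genome, transcript: Transcript, exon: tuple[int, int]) -> str:
    seq = fetch(genome, transcript.chrom, exon[0], exon[1])
    return reverse_complement(seq) if transcript.strand == "-" else seq


def build_linear_references(
    assignment: BoundaryAssignment,
    annotation: GenomeAnnotation,
    genome,
    W: int,
    circle_seq: Optional[str] = None,
) -> tuple[Optional[tuple[str, int]], Optional[tuple[str, int]]]:
    """Linear junction sequences of the host transcript, or ``None`` sides.

    ``linear_left`` joins the closest upstream exon (transcript orientation)
    to the first ``W`` circle bases; ``linear_right`` joins the last ``W``
    circle bases to the closest downstream exon.  A circle at a transcript
    terminus lacks the corresponding neighbour; a score-0 assignment has no
    host transcript and yields no linear reference at all.
    """
    if assignment.score == 0 or assignment.transcript_id is None:
        log.debug(
            "no linear references for score-0 candidate %s",
            assignment.candidate.circ_id,
        )
        return None, None
    transcript = annotation.transcripts_by_id[assignment.transcript_id]
    cand = assignment.candidate
    if circle_seq is None:
        circle_seq = circle_sequence(assignment, genome)
    tx_exons = _transcript_order_exons(transcript)
    inside = [
        i for i, (s, e) in enumerate(tx_exons) if s < cand.end and e > cand.start
    ]
    if not inside:
        return None, None
    first, last = inside[0], inside[-1]
    k = min(W, len(circle_seq))

    left = None
    if first > 0:
        up = _exon_seq(genome, transcript, tx_exons[first - 1])
        left = (up + circle_seq[:k], len(up) - 1)
    right = None
    if last < len(tx_exons) - 1:
        down = _exon_seq(genome, transcript, tx_exons[last + 1])
        right = (circle_seq[-k:] + down, k - 1)
    return left, right


def build_references(
    assignments: Iterable[BoundaryAssignment],
    annotation: GenomeAnnotation,
    genome,
    W: int,
) -> list[JunctionReference]:
    """Build circular windows and linear references for all assignments."""
    refs = []
    seen: set[str] = set()
    for assignment in assignments:
        circ_id = assignment.candidate.circ_id
        if circ_id in seen:
            raise ValueError(f"duplicate circ_id {circ_id}")
        seen.add(circ_id)
        seq = circle_sequence(assignment, genome)
        window, offset = build_circular_window(seq, W)
        left, right = build_linear_references(
            assignment, annotation, genome, W, circle_seq=seq
        )
        refs.append(
            JunctionReference(
                circ_id=circ_id,
                strand=assignment.candidate.strand,
                score=assignment.score,
                circle_length=len(seq),
                W=W,
                window=window,
                window_offset=offset,
                linear_left=left[0] if left else None,
                linear_left_offset=left[1] if left else None,
                linear_right=right[0] if right else None,
                linear_right_offset=right[1] if right else None,
            )
        )
    return refs


def spliced_transcript_sequences(annotation: GenomeAnnotation, genome) -> dict[str, str]:
    """Spliced sequence of every transcript, 5'->3' on its strand.

    Used both as the linear transcriptome for the exclusion filter and for
    transcript-level exports.
    """
    out = {}
    for t in annotation.transcripts:
        seq = "".join(fetch(genome, t.chrom, s, e) for s, e in t.exons)
        if t.strand == "-":
            seq = reverse_complement(seq)
        out[t.id] = seq
    return out


OFFSETS_COLUMNS = [
    "circ_id",
    "strand",
    "score",
    "circle_length",
    "W",
    "window_len",
    "window_offset",
    "linear_left_len",
    "linear_left_offset",
    "linear_right_len",
    "linear_right_offset",
]


def write_reference_fasta(references: list[JunctionReference], outdir) -> dict[str, Path]:
    """Emit circular.fa / linear_left.fa / linear_right.fa plus offsets.tsv.

    Round-trips losslessly through :func:`read_reference_fasta`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seen: set[str] = set()
    for ref in references:
        if ref.circ_id in seen:
            raise ValueError(f"duplicate circ_id {ref.circ_id}")
        seen.add(ref.circ_id)

    paths = {
        "circular": outdir / "circular.fa",
        "linear_left": outdir / "linear_left.fa",
        "linear_right": outdir / "linear_right.fa",
        "offsets": outdir / "offsets.tsv",
    }
    for kind in ("circular", "linear_left", "linear_right"):
        records = [
            SeqRecord(Seq(ref.sequence(kind)), id=ref.circ_id, description="")
            for ref in references
            if ref.sequence(kind) is not None
        ]
        with open(paths[kind], "w") as fh:
            SeqIO.write(records, fh, "fasta")
    with open(paths["offsets"], "w") as fh:
        fh.write("\t".join(OFFSETS_COLUMNS) + "\n")
        for ref in references:
            row = [
                ref.circ_id,
                ref.strand,
                ref.score,
                ref.circle_length,
                ref.W,
                len(ref.window),
                ref.window_offset,
                len(ref.linear_left) if ref.linear_left is not None else ".",
                ref.linear_left_offset if ref.linear_left_offset is not None else ".",
                len(ref.linear_right) if ref.linear_right is not None else ".",
                ref.linear_right_offset if ref.linear_right_offset is not None else ".",
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")
    return paths


def read_reference_fasta(outdir) -> list[JunctionReference]:
    """Read back a reference set written by :func:`write_reference_fasta`."""
    outdir = Path(outdir)
    seqs: dict[str, dict[str, str]] = {"circular": {}, "linear_left": {}, "linear_right": {}}
    for kind in seqs:
        path = outdir / f"{kind}.fa"
        if path.exists():
            for rec in SeqIO.parse(str(path), "fasta"):
                seqs[kind][rec.id] = str(rec.seq)
    refs = []
    with open(outdir / "offsets.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != OFFSETS_COLUMNS:
            raise ValueError(f"unexpected offsets.tsv header in {outdir}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            row = dict(zip(OFFSETS_COLUMNS, f))
            circ_id = row["circ_id"]
            has_left = row["linear_left_offset"] != "."
            has_right = row["linear_right_offset"] != "."
            refs.append(
                JunctionReference(
                    circ_id=circ_id,
                    strand=row["strand"],
                    score=int(row["score"]),
                    circle_length=int(row["circle_length"]),
                    W=int(row["W"]),
                    window=seqs["circular"][circ_id],
                    window_offset=int(row["window_offset"]),
                    linear_left=seqs["linear_left"].get(circ_id) if has_left else None,
                    linear_left_offset=int(row["linear_left_offset"]) if has_left else None,
                    linear_right=seqs["linear_right"].get(circ_id) if has_right else None,
                    linear_right_offset=int(row["linear_right_offset"]) if has_right else None,
                )
            )
    return refs
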