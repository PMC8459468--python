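"""Candidate merging and exon-boundary scoring for backsplice junctions.

Upstream circRNA-discovery tools report putative backsplice junctions in
slightly different coordinate dialects.  This module normalizes those
records into one deduplicated candidate set with per-tool provenance, and
re-annotates every candidate against a transcript model: a candidate whose
start and end both fall exactly on annotated exon boundaries of some
transcript gets a boundary score of 2, one matching boundary scores 1, and
no match scores 0.  The best-fitting transcript supplies the exon chain
used later to extract the circle sequence.

All internal coordinates are 0-based half-open on the forward genomic
strand; dialect conversion happens exactly once, at ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

Interval = tuple[int, int]

#: Coordinate dialects as (start_shift, end_shift) added to raw (start, end)
#: to obtain internal 0-based half-open coordinates.
DIALECTS: dict[str, tuple[int, int]] = {
    "bed": (0, 0),
    "zero_based_half_open": (0, 0),
    "one_based_closed": (-1, 0),
    "gtf": (-1, 0),
    "one_based_half_open": (-1, -1),
    "zero_based_closed": (0, 1),
}


class ConfigError(ValueError):
    """Raised for unusable run configuration (e.g. an unknown dialect)."""


@dataclass(frozen=True)
class Transcript:
    """One transcript model: ordered, non-overlapping exon intervals."""

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"transcript {self.id}: empty exon ({s},{e})")
            if s < prev_end:
                raise ValueError(
                    f"transcript {self.id}: exons overlap or are unsorted at ({s},{e})"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...] = ()


class GenomeAnnotation:
    """A set of gene models indexed for interval overlap queries."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = list(genes)
        self.transcripts: list[Transcript] = [
            t for g in self.genes for t in g.transcripts
        ]
        self.transcripts_by_id: dict[str, Transcript] = {}
        for t in self.transcripts:
            if t.id in self.transcripts_by_id:
                raise ValueError(f"duplicate transcript id {t.id}")
            self.transcripts_by_id[t.id] = t
        self._by_chrom: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda t: (t.start, t.end, t.id))

    def overlapping_transcripts(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> list[Transcript]:
        """Transcripts whose genomic span overlaps [start, end)."""
        out = []
        for t in self._by_chrom.get(chrom, ()):
            if t.start >= end:
                break
            if t.end > start and (strand is None or t.strand == strand):
                out.append(t)
        return out


@dataclass(frozen=True)
class CircCandidate:
    """A putative backsplice junction with per-pipeline provenance."""

    chrom: str
    start: int
    end: int
    strand: str
    pipelines: frozenset[str]
    per_pipeline_counts: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"candidate {self.key} has start >= end")
        if not self.pipelines:
            raise ValueError(f"candidate {self.key} has no supporting pipeline")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


@dataclass(frozen=True)
class BoundaryAssignment:
    """A candidate bound to its best-fitting transcript.

    ``exon_chain`` holds the chosen transcript's exons intersected with the
    candidate span, with the terminal exons clipped to the candidate
    boundaries.  For a candidate with no overlapping transcript (or one that
    overlaps only introns) the chain degenerates to the raw genomic span.
    """

    candidate: CircCandidate
    transcript_id: Optional[str]
    score: int
    exon_chain: tuple[Interval, ...]


def normalize_record(
    chrom: str, start: int, end: int, strand: str, dialect: str
) -> tuple[str, int, int, str]:
    """Convert one raw record to internal 0-based half-open coordinates."""
    try:
        ds, de = DIALECTS[dialect]
    except KeyError:
        raise ConfigError(
            f"unknown coordinate dialect {dialect!r}; known: {sorted(DIALECTS)}"
        ) from None
    return chrom, start + ds, end + de, strand


def merge_candidates(
    candidate_lists: Sequence[tuple[str, Sequence[tuple]]],
    coordinate_dialects: Mapping[str, str],
    tolerance: int = 0,
) -> list[CircCandidate]:
    """Merge per-pipeline candidate lists into one deduplicated set.

    Parameters
    ----------
    candidate_lists
        ``(pipeline_name, records)`` pairs.  Each record is a tuple
        ``(chrom, start, end, strand)`` optionally followed by a read count.
    coordinate_dialects
        Pipeline name -> dialect key in :data:`DIALECTS`.
    tolerance
        With ``tolerance > 0``, candidates on the same chromosome and
        strand whose start *and* end coordinates each differ by at most
        ``tolerance`` bases are clustered (single linkage); the coordinates
        of the cluster member supported by the most pipelines (ties:
        smallest start, then smallest end) represent the cluster.

    Malformed records are skipped with a logged warning; the per-pipeline
    rejected-record counts are logged at the end.
    """
    merged: dict[tuple, dict] = {}
    rejected: dict[str, int] = {}
    for pipeline, records in candidate_lists:
        dialect = coordinate_dialects.get(pipeline)
        if dialect is None:
            raise ConfigError(f"no coordinate dialect configured for {pipeline!r}")
        if dialect not in DIALECTS:
            raise ConfigError(f"unknown coordinate dialect {dialect!r} for {pipeline!r}")
        for rec in records:
            try:
                chrom, start, end, strand = rec[:4]
                count = rec[4] if len(rec) > 4 else None
                if strand not in ("+", "-"):
                    raise ValueError(f"bad strand {strand!r}")
                key = normalize_record(chrom, int(start), int(end), strand, dialect)
                if key[1] >= key[2]:
                    raise ValueError("start >= end after normalization")
            except ConfigError:
                raise
            except Exception as exc:  # noqa: BLE001 - malformed record, keep going
                rejected[pipeline] = rejected.get(pipeline, 0) + 1
                log.warning("skipping malformed record %r from %s: %s", rec, pipeline, exc)
                continue
            slot = merged.setdefault(key, {"pipelines": set(), "counts": {}})
            slot["pipelines"].add(pipeline)
            if count is not None:
                slot["counts"][pipeline] = slot["counts"].get(pipeline, 0) + float(count)
    for pipeline, n in rejected.items():
        log.warning("%s: %d record(s) rejected", pipeline, n)

    candidates = [
        CircCandidate(
            chrom=k[0],
            start=k[1],
            end=k[2],
            strand=k[3],
            pipelines=frozenset(v["pipelines"]),
            per_pipeline_counts=dict(v["counts"]) or None,
        )
        for k, v in merged.items()
    ]
    if tolerance > 0:
        candidates = _cluster_candidates(candidates, tolerance)
    candidates.sort(key=lambda c: c.key)
    return candidates


def _cluster_candidates(
    candidates: list[CircCandidate], tolerance: int
) -> list[CircCandidate]:
    """Single-linkage clustering of near-identical junction coordinates."""
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: candidates[i].key)
    for a_pos, i in enumerate(order):
        ci = candidates[i]
        for j in order[a_pos + 1 :]:
            cj = candidates[j]
            if cj.chrom != ci.chrom or cj.start - ci.start > tolerance:
                break
            if (
                cj.strand == ci.strand
                and abs(cj.start - ci.start) <= tolerance
                and abs(cj.end - ci.end) <= tolerance
            ):
                union(i, j)

    clusters: dict[int, list[CircCandidate]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(candidates[i])

    out = []
    for members in clusters.values():
        rep = min(members, key=lambda c: (-len(c.pipelines), c.start, c.end))
        pipelines = frozenset().union(*(c.pipelines for c in members))
        counts: dict[str, float] = {}
        for c in members:
            for p, v in (c.per_pipeline_counts or {}).items():
                counts[p] = counts.get(p, 0.0) + v
        out.append(replace(rep, pipelines=pipelines, per_pipeline_counts=counts or None))
    return out


def score_candidate_against_transcript(
    candidate: CircCandidate, transcript: Transcript
) -> int:
    """Boundary-consistency score of a candidate against one transcript.

    Returns 2 when the candidate start coincides with some exon start *and*
    its end with some exon end; 1 when exactly one boundary matches; 0
    otherwise.  A chromosome or strand mismatch means the transcript cannot
    host the circle and scores 0.
    """
    if candidate.chrom != transcript.chrom or candidate.strand != transcript.strand:
        return 0
    starts = {s for s, _ in transcript.exons}
    ends = {e for _, e in transcript.exons}
    return int(candidate.start in starts) + int(candidate.end in ends)


def _clip_exon_chain(
    transcript: Transcript, start: int, end: int
) -> tuple[Interval, ...]:
    chain = tuple(
        (max(s, start), min(e, end))
        for s, e in transcript.exons
        if s < end and e > start
    )
    return chain


def assign_best_transcript(
    candidate: CircCandidate,
    annotation: GenomeAnnotation,
    rng: Optional[np.random.Generator] = None,
) -> BoundaryAssignment:
    """Pick the transcript that best fits a candidate circle.

    Among transcripts overlapping ``[start, end)`` on the same chromosome
    and strand, the one with the maximal boundary score wins.  Equal-score
    ties are broken by the lexicographically smallest transcript id, which
    keeps reruns reproducible; pass a seeded ``rng`` to resolve ties by a
    random draw instead.  With no overlapping transcript the assignment is
    score 0 with the raw genomic span as its chain.
    """
    hits = annotation.overlapping_transcripts(
        candidate.chrom, candidate.start, candidate.end, candidate.strand
    )
    if not hits:
        return BoundaryAssignment(
            candidate=candidate,
            transcript_id=None,
            score=0,
            exon_chain=((candidate.start, candidate.end),),
        )
    scored = [(score_candidate_against_transcript(candidate, t), t) for t in hits]
    best_score = max(s for s, _ in scored)
    best = sorted((t for s, t in scored if s == best_score), key=lambda t: t.id)
    if rng is not None and len(best) > 1:
        chosen = best[int(rng.integers(len(best)))]
    else:
        chosen = best[0]
    chain = _clip_exon_chain(chosen, candidate.start, candidate.end)
    if not chain:  # candidate overlaps the transcript span via introns only
        chain = ((candidate.start, candidate.end),)
    return BoundaryAssignment(
        candidate=candidate,
        transcript_id=chosen.id,
        score=best_score,
        exon_chain=chain,
    )
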