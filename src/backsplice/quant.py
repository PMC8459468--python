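"""Seed-anchored junction read counting with genome/transcriptome exclusion.

A read supports a junction only when it spans it: the read must cover at
least ``j`` bases on each side of the junction and the ``2j`` bases centred
on the junction must match the reference exactly (the *seed*; default
``j = 5``, a 10-base exact seed for the backsplice).  Outside the seed up
to ``m`` mismatches are tolerated; any ``N`` counts as a mismatch and
alignment is strictly ungapped.

Reads matching a circular window are then screened against the genome
(both strands) and the spliced linear transcriptome: a read with *any*
ungapped end-to-end placement with at most ``m`` mismatches there cannot be
unambiguously circular and is discarded.  The exclusion search uses
pigeonhole k-mer seeding: a placement of a length-``L`` read with at most
``m`` mismatches must contain an exact k-mer for ``k = floor(L/(m+1))``, so
looking up ``m + 1`` disjoint read chunks in a k-mer index of the targets
finds every qualifying placement.

Counting is fragment-level: a paired-end fragment whose two mates hit the
same junction contributes one count, never two, and a fragment hitting more
than one distinct circular junction is dropped as ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import reverse_complement

from .annotation import GenomeAnnotation
from .refbuild import JunctionReference, spliced_transcript_sequences

log = logging.getLogger(__name__)

JUNCTION_KINDS = ("circular", "linear_left", "linear_right")


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    mate: Optional[int]  # 1, 2 or None for single-end
    seq: str
    source_file: str = ""


@dataclass(frozen=True)
class JunctionHit:
    read_id: str
    circ_id: str
    junction_kind: str
    align_offset: int
    mismatches_outside_seed: int
    mate: Optional[int] = None


@dataclass
class CountTable:
    """Fragment-level junction counts for one sequencing library.

    ``library_size`` is the number of input reads that found any ungapped
    placement (genome, transcriptome or junction references); it is the
    denominator for per-million normalization.
    """

    library_id: str
    library_size: int
    counts: pd.DataFrame  # index circ_id; circ_count, linear_left_count, linear_right_count
    n_ambiguous: int = 0
    n_excluded_genome: int = 0
    n_excluded_transcriptome: int = 0

    def summary(self) -> dict:
        return {
            "library_id": self.library_id,
            "library_size": int(self.library_size),
            "n_ambiguous": int(self.n_ambiguous),
            "n_excluded_genome": int(self.n_excluded_genome),
            "n_excluded_transcriptome": int(self.n_excluded_transcriptome),
        }


def _mismatch_outside_seed(
    ref: str, seq: str, place: int, seed_lo: int, seed_hi: int, m: int
) -> int:
    """Mismatches of seq placed at ``place`` on ref, skipping the seed zone
    [seed_lo, seed_hi); returns m + 1 as soon as the budget is exceeded."""
    mm = 0
    for r, base in enumerate(seq):
        p = place + r
        if seed_lo <= p < seed_hi:
            continue
        ref_base = ref[p]
        if base != ref_base or base == "N":
            mm += 1
            if mm > m:
                return mm
    return mm


class JunctionMatcher:
    """Matches reads against a set of junction references.

    The 2j-base seed of every reference is unique per placement, so reads
    are scanned for exact occurrences of reference seeds; each occurrence
    pins down a single ungapped placement which is then verified against
    the mismatch budget.  This is exactly equivalent to sliding the read
    over every reference (the seed must match exactly somewhere, and its
    position determines the placement) but runs in O(read length) per read.
    """

    def __init__(
        self,
        references: Sequence[JunctionReference],
        j: int = 5,
        m: int = 2,
        kinds: Sequence[str] = JUNCTION_KINDS,
    ):
        if j < 1:
            raise ValueError("seed half-width j must be >= 1")
        if m < 0:
            raise ValueError("mismatch budget m must be >= 0")
        self.j = j
        self.m = m
        self.entries: list[tuple[str, str, str, int]] = []  # circ_id, kind, seq, offset
        self._index: dict[str, list[int]] = {}
        for ref in references:
            for kind in kinds:
                seq = ref.sequence(kind)
                if seq is None:
                    continue
                offset = ref.offset(kind)
                seed = seq[offset - j + 1 : offset + j + 1]
                if len(seed) < 2 * j or "N" in seed:
                    log.warning(
                        "reference %s/%s cannot anchor a %d-base seed; skipped",
                        ref.circ_id,
                        kind,
                        2 * j,
                    )
                    continue
                self.entries.append((ref.circ_id, kind, seq, offset))
                self._index.setdefault(seed, []).append(len(self.entries) - 1)

    def match_sequence(self, seq: str) -> dict[tuple[str, str], tuple[int, int]]:
        """Best hit per (circ_id, kind) for one oriented read sequence.

        Returns ``(circ_id, kind) -> (mismatches_outside_seed, offset)``,
        keeping for each junction the placement with the fewest mismatches
        (ties: smallest offset).
        """
        j, m = self.j, self.m
        L = len(seq)
        width = 2 * j
        if L < width:
            return {}
        best: dict[tuple[str, str], tuple[int, int]] = {}
        for q in range(L - width + 1):
            kmer = seq[q : q + width]
            hits = self._index.get(kmer)
            if not hits:
                continue
            for idx in hits:
                circ_id, kind, ref, offset = self.entries[idx]
                place = offset - j + 1 - q
                if place < 0 or place + L > len(ref):
                    continue
                mm = _mismatch_outside_seed(ref, seq, place, offset - j + 1, offset + j + 1, m)
                if mm > m:
                    continue
                key = (circ_id, kind)
                cur = best.get(key)
                if cur is None or (mm, place) < cur:
                    best[key] = (mm, place)
        return best


def match_read_to_junction(
    read: ReadRecord,
    ref: JunctionReference,
    kind: str,
    j: int = 5,
    m: int = 2,
    strandedness: str = "forward",
) -> Optional[JunctionHit]:
    """Match one read against one junction of one reference.

    ``strandedness='forward'`` matches the read as given; ``'unstranded'``
    also tries its reverse complement and keeps the better placement.
    Returns ``None`` when the read cannot span the junction (shorter than
    ``2j``) or no qualifying placement exists.
    """
    if ref.sequence(kind) is None:
        return None
    if len(read.seq) < 2 * j:
        log.debug("read %s shorter than 2j=%d; cannot span a junction", read.read_id, 2 * j)
        return None
    matcher = JunctionMatcher([ref], j=j, m=m, kinds=(kind,))
    candidates = [matcher.match_sequence(read.seq)]
    if strandedness == "unstranded":
        candidates.append(matcher.match_sequence(reverse_complement(read.seq)))
    elif strandedness != "forward":
        raise ValueError(f"unknown strandedness {strandedness!r}")
    best = None
    for cand in candidates:
        hit = cand.get((ref.circ_id, kind))
        if hit is not None and (best is None or hit < best):
            best = hit
    if best is None:
        return None
    return JunctionHit(
        read_id=read.read_id,
        circ_id=ref.circ_id,
        junction_kind=kind,
        align_offset=best[1],
        mismatches_outside_seed=best[0],
        mate=read.mate,
    )


class MismatchSearcher:
    """Ungapped end-to-end placement search with <= m mismatches.

    Pigeonhole k-mer seeding over a dictionary of target sequences; both
    the query and its reverse complement are searched (targets are indexed
    on their forward strand only).
    """

    def __init__(self, sequences: Mapping[str, str], m: int = 2):
        self.seqs = {name: seq.upper() for name, seq in sequences.items()}
        self.m = m
        self._indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _index_for(self, k: int) -> dict[str, list[tuple[str, int]]]:
        idx = self._indexes.get(k)
        if idx is None:
            idx = {}
            for name, seq in self.seqs.items():
                for pos in range(len(seq) - k + 1):
                    kmer = seq[pos : pos + k]
                    if "N" in kmer:
                        continue
                    idx.setdefault(kmer, []).append((name, pos))
            self._indexes[k] = idx
        return idx

    def _mismatches_at(self, ref: str, seq: str, place: int) -> int:
        if ref[place : place + len(seq)] == seq and "N" not in seq:
            return 0
        mm = 0
        for r, base in enumerate(seq):
            ref_base = ref[place + r]
            if base != ref_base or base == "N":
                mm += 1
                if mm > self.m:
                    return mm
        return mm

    def _search_oriented(self, seq: str) -> bool:
        L = len(seq)
        k = L // (self.m + 1)
        if k < 1:
            # read shorter than the mismatch budget: brute force
            for ref in self.seqs.values():
                for place in range(len(ref) - L + 1):
                    if self._mismatches_at(ref, seq, place) <= self.m:
                        return True
            return False
        idx = self._index_for(k)
        tried: set[tuple[str, int]] = set()
        for i in range(self.m + 1):
            q = i * k
            kmer = seq[q : q + k]
            if "N" in kmer:
                continue
            for name, pos in idx.get(kmer, ()):
                place = pos - q
                ref = self.seqs[name]
                if place < 0 or place + L > len(ref):
                    continue
                key = (name, place)
                if key in tried:
                    continue
                tried.add(key)
                if self._mismatches_at(ref, seq, place) <= self.m:
                    return True
        return False

    def has_placement(self, seq: str, both_strands: bool = True) -> bool:
        seq = seq.upper()
        if self._search_oriented(seq):
            return True
        return both_strands and self._search_oriented(reverse_complement(seq))


def exclusion_filter(
    hits: Iterable[JunctionHit],
    reads: Mapping[str, str],
    genome_searcher: MismatchSearcher,
    transcriptome_searcher: MismatchSearcher,
) -> tuple[list[JunctionHit], int, int]:
    """Discard circular hits whose read placed end-to-end on the genome or
    linear transcriptome; linear-junction hits pass through untouched.

    ``reads`` maps ``(read_id, mate)``-style keys produced by
    :func:`_read_key` to sequences.  Returns the retained hits and the
    number of reads excluded by the genome and transcriptome respectively.
    """
    retained = []
    verdict: dict[tuple, Optional[str]] = {}
    n_genome = n_tx = 0
    for hit in hits:
        if hit.junction_kind != "circular":
            retained.append(hit)
            continue
        key = _read_key(hit.read_id, hit.mate)
        if key not in verdict:
            seq = reads[key]
            if genome_searcher.has_placement(seq):
                verdict[key] = "genome"
                n_genome += 1
            elif transcriptome_searcher.has_placement(seq):
                verdict[key] = "transcriptome"
                n_tx += 1
            else:
                verdict[key] = None
        if verdict[key] is None:
            retained.append(hit)
    return retained, n_genome, n_tx


def _read_key(read_id: str, mate: Optional[int]) -> tuple[str, int]:
    return (read_id, mate or 0)


def count_junctions(
    hits: Iterable[JunctionHit],
    pairing: str = "SE",
    circ_ids: Optional[Sequence[str]] = None,
    library_id: str = "",
    library_size: int = 0,
) -> CountTable:
    """Fragment-level counting of retained junction hits.

    Mates share a ``read_id``, so grouping hits by read id collapses a
    paired-end fragment whose two mates hit the same junction into one
    count.  A fragment hitting more than one distinct circular junction is
    ambiguous and contributes nothing (logged); the same rule applies
    within each linear junction kind.
    """
    if pairing not in ("SE", "PE"):
        raise ValueError(f"pairing must be SE or PE, got {pairing!r}")
    per_fragment: dict[str, dict[str, set[str]]] = {}
    for hit in hits:
        per_fragment.setdefault(hit.read_id, {}).setdefault(
            hit.junction_kind, set()
        ).add(hit.circ_id)

    counts: dict[str, dict[str, int]] = {}
    n_ambiguous = 0
    col_for = {
        "circular": "circ_count",
        "linear_left": "linear_left_count",
        "linear_right": "linear_right_count",
    }
    for frag_id, by_kind in per_fragment.items():
        for kind, ids in by_kind.items():
            if len(ids) > 1:
                if kind == "circular":
                    n_ambiguous += 1
                    log.debug("fragment %s ambiguous across %s", frag_id, sorted(ids))
                continue
            (circ_id,) = ids
            slot = counts.setdefault(
                circ_id,
                {"circ_count": 0, "linear_left_count": 0, "linear_right_count": 0},
            )
            slot[col_for[kind]] += 1

    index = list(circ_ids) if circ_ids is not None else sorted(counts)
    df = pd.DataFrame(
        0,
        index=pd.Index(index, name="circ_id"),
        columns=["circ_count", "linear_left_count", "linear_right_count"],
        dtype=int,
    )
    for circ_id, slot in counts.items():
        if circ_id not in df.index:
            raise ValueError(f"hit references unknown circ_id {circ_id}")
        for col, v in slot.items():
            df.loc[circ_id, col] = v
    return CountTable(
        library_id=library_id,
        library_size=library_size,
        counts=df,
        n_ambiguous=n_ambiguous,
    )


def iter_fastq_reads(fastq_paths: Sequence, pairing: str = "SE"):
    """Yield :class:`ReadRecord` from one (SE) or two (PE R1/R2) FASTQ files."""
    from .io import read_fastq  # local import to avoid a cycle

    if pairing == "SE":
        (path,) = fastq_paths
        for read_id, seq in read_fastq(path):
            yield ReadRecord(read_id=read_id, mate=None, seq=seq, source_file=str(path))
    else:
        r1, r2 = fastq_paths
        for path, mate in ((r1, 1), (r2, 2)):
            for read_id, seq in read_fastq(path):
                base = read_id.rsplit("/", 1)[0] if read_id.endswith(("/1", "/2")) else read_id
                yield ReadRecord(read_id=base, mate=mate, seq=seq, source_file=str(path))


def quantify_library(
    fastq_paths: Sequence,
    references: Sequence[JunctionReference],
    annotation: GenomeAnnotation,
    genome,
    j: int = 5,
    m: int = 2,
    strandedness: str = "forward",
    pairing: str = "SE",
    library_id: str = "library",
    transcriptome: Optional[Mapping[str, str]] = None,
) -> tuple[CountTable, pd.DataFrame]:
    """Quantify circular and linear junction reads in one library.

    Composes junction matching, the genome/transcriptome exclusion filter
    for circular hits, and fragment-level counting.  Returns the count
    table plus a per-read evidence report (read id, junction, offset,
    mismatches, status) for auditability.
    """
    if strandedness not in ("forward", "unstranded"):
        raise ValueError(f"unknown strandedness {strandedness!r}")
    matcher = JunctionMatcher(references, j=j, m=m)
    if transcriptome is None:
        transcriptome = spliced_transcript_sequences(annotation, genome)
    genome_seqs = {chrom: str(genome[chrom][:]) for chrom in _chrom_names(genome)}
    genome_searcher = MismatchSearcher(genome_seqs, m=m)
    tx_searcher = MismatchSearcher(dict(transcriptome), m=m)

    library_size = 0
    n_reads = 0
    hits: list[JunctionHit] = []
    placement_status: dict[tuple, str] = {}
    evidence_rows: list[tuple] = []
    seen: set[tuple] = set()
    for read in iter_fastq_reads(fastq_paths, pairing=pairing):
        key = _read_key(read.read_id, read.mate)
        if key in seen:
            raise ValueError(
                f"read {read.read_id} mate {read.mate} appears twice in the input"
            )
        seen.add(key)
        n_reads += 1
        oriented = [read.seq]
        if pairing == "PE" and read.mate == 2 and strandedness == "forward":
            # FR library layout: mate 2 reads antisense to the transcript
            oriented = [reverse_complement(read.seq)]
        elif strandedness == "unstranded":
            oriented = [read.seq, reverse_complement(read.seq)]

        best: dict[tuple[str, str], tuple[int, int]] = {}
        for seq in oriented:
            for jkey, placement in matcher.match_sequence(seq).items():
                cur = best.get(jkey)
                if cur is None or placement < cur:
                    best[jkey] = placement
        if genome_searcher.has_placement(read.seq):
            placement_status[key] = "excluded_genome"
        elif tx_searcher.has_placement(read.seq):
            placement_status[key] = "excluded_transcriptome"
        else:
            placement_status[key] = ""
        if best or placement_status[key]:
            library_size += 1
        if best:
            for (circ_id, kind), (mm, offset) in best.items():
                hits.append(
                    JunctionHit(
                        read_id=read.read_id,
                        circ_id=circ_id,
                        junction_kind=kind,
                        align_offset=offset,
                        mismatches_outside_seed=mm,
                        mate=read.mate,
                    )
                )

    # exclusion of circular hits whose read also places linearly
    retained: list[JunctionHit] = []
    n_excl_genome = n_excl_tx = 0
    counted_exclusions: set[tuple] = set()
    for hit in hits:
        if hit.junction_kind != "circular":
            retained.append(hit)
            evidence_rows.append(_evidence_row(hit, "counted-candidate"))
            continue
        key = _read_key(hit.read_id, hit.mate)
        status = placement_status[key]
        if status:
            if key not in counted_exclusions:
                counted_exclusions.add(key)
                if status == "excluded_genome":
                    n_excl_genome += 1
                else:
                    n_excl_tx += 1
            evidence_rows.append(_evidence_row(hit, status))
        else:
            retained.append(hit)
            evidence_rows.append(_evidence_row(hit, "counted-candidate"))

    table = count_junctions(
        retained,
        pairing=pairing,
        circ_ids=[r.circ_id for r in references],
        library_id=library_id,
        library_size=library_size,
    )
    table.n_excluded_genome = n_excl_genome
    table.n_excluded_transcriptome = n_excl_tx
    evidence = pd.DataFrame(
        evidence_rows,
        columns=["read_id", "mate", "circ_id", "junction_kind", "align_offset",
                 "mismatches_outside_seed", "status"],
    )
    log.info(
        "%s: %d reads, library_size=%d, %d junction hits, %d retained, "
        "%d excluded (genome %d / transcriptome %d), %d ambiguous fragments",
        library_id, n_reads, library_size, len(hits), len(retained),
        n_excl_genome + n_excl_tx, n_excl_genome, n_excl_tx, table.n_ambiguous,
    )
    if n_reads == 0:
        log.warning("%s: empty input; all counts zero", library_id)
    return table, evidence


def _evidence_row(hit: JunctionHit, status: str) -> tuple:
    return (
        hit.read_id,
        hit.mate if hit.mate is not None else 0,
        hit.circ_id,
        hit.junction_kind,
        hit.align_offset,
        hit.mismatches_outside_seed,
        status,
    )


def _chrom_names(genome) -> list[str]:
    keys = genome.keys()
    return list(keys)
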