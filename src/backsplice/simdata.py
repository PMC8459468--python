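"""Synthetic toy genomes, planted circRNAs and mock/RNase R read libraries.

The generator emulates the experimental design the classifier expects: a
toy genome with multi-exon gene models, a set of *true* circles whose
boundaries sit exactly on exon boundaries (boundary score 2 by
construction), a set of *decoy* junctions standing in for pipeline
artifacts (boundaries shifted 1-10 bases off exon boundaries, or
intergenic spans), and per-set mock/RNase R FASTQ libraries.  Junction
reads are drawn with uniform random start positions constrained to span
the junction; the RNase R library keeps each circular read with
probability ``survival_circ`` and each linear or decoy read with
``survival_linear``.  Every emitted read id encodes its origin and is
recorded exactly once in a machine-readable truth ledger.

Reads are error-free and qualities are constant: the counting method never
uses base qualities, and sequencing-error and duplicate artefacts are out
of scope here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotation import (
    BoundaryAssignment,
    CircCandidate,
    Gene,
    GenomeAnnotation,
    Transcript,
    assign_best_transcript,
    score_candidate_against_transcript,
)
from .quant import MismatchSearcher
from .refbuild import (
    JunctionReference,
    build_references,
    fetch,
    spliced_transcript_sequences,
)
from . import io as bio_io

log = logging.getLogger(__name__)

PIPELINE_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon")
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults encode the reference design used throughout the test suite:
    50 true circles and 50 decoys at 60 junction-spanning reads per
    junction, 70-base single-end reads, RNase R survival 0.9 for circular
    reads and 0.05 for linear/decoy reads.
    """

    seed: int = 0
    n_genes: int = 120
    n_chroms: int = 2
    exon_length: tuple[int, int] = (80, 250)
    intron_length: tuple[int, int] = (60, 200)
    intergenic_length: tuple[int, int] = (200, 400)
    n_true_circles: int = 50
    n_decoys: int = 50
    read_length: int = 70
    n_sets: int = 1
    set_halving: bool = False
    reads_per_circle_set1: int = 60
    linear_reads_per_gene: int = 60
    survival_circ: float = 0.9
    survival_linear: float = 0.05
    pairing: str = "SE"
    fragment_length: int = 150
    junction_overhang: int = 5
    mismatch_budget: int = 2
    W: Optional[int] = None

    def __post_init__(self) -> None:
        for p in (self.survival_circ, self.survival_linear):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"survival probability {p} outside [0, 1]")
        if self.read_length < 2 * self.junction_overhang:
            raise ValueError("read_length must be >= twice the junction overhang")
        if self.pairing not in ("SE", "PE"):
            raise ValueError(f"pairing must be SE or PE, got {self.pairing!r}")
        if self.pairing == "PE" and self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length for PE")
        for lo, hi in (self.exon_length, self.intron_length, self.intergenic_length):
            if not 1 <= lo <= hi:
                raise ValueError(f"infeasible length range ({lo}, {hi})")

    @property
    def effective_W(self) -> int:
        if self.W is not None:
            return self.W
        return max(self.read_length, self.fragment_length if self.pairing == "PE" else 0)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def make_toy_genome(config: SimConfig) -> tuple[dict[str, str], GenomeAnnotation]:
    """Deterministic toy genome and annotation for a seed.

    Genes have 2-8 exons with lengths drawn from the configured ranges and
    are laid out with intergenic gaps, alternating across chromosomes.
    """
    rng = np.random.default_rng([config.seed, 0])
    parts: dict[str, list[str]] = {}
    pos: dict[str, int] = {}
    genes: list[Gene] = []
    for gi in range(config.n_genes):
        chrom = f"chrS{gi % config.n_chroms + 1}"
        if chrom not in parts:
            parts[chrom] = []
            pos[chrom] = 0
        gap = int(rng.integers(config.intergenic_length[0], config.intergenic_length[1] + 1))
        parts[chrom].append(_rand_seq(rng, gap))
        pos[chrom] += gap
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 9))
        exons = []
        for ei in range(n_exons):
            if ei > 0:
                intron = int(
                    rng.integers(config.intron_length[0], config.intron_length[1] + 1)
                )
                parts[chrom].append(_rand_seq(rng, intron))
                pos[chrom] += intron
            exon_len = int(
                rng.integers(config.exon_length[0], config.exon_length[1] + 1)
            )
            exons.append((pos[chrom], pos[chrom] + exon_len))
            parts[chrom].append(_rand_seq(rng, exon_len))
            pos[chrom] += exon_len
        gene_id = f"g{gi:04d}"
        tx = Transcript(
            id=f"{gene_id}.t1",
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
        )
        genes.append(Gene(id=gene_id, chrom=chrom, strand=strand, transcripts=(tx,)))
    for chrom in parts:
        tail = int(rng.integers(config.intergenic_length[0], config.intergenic_length[1] + 1))
        parts[chrom].append(_rand_seq(rng, tail))
    genome = {chrom: "".join(p) for chrom, p in parts.items()}
    return genome, GenomeAnnotation(genes)


def _intergenic_intervals(
    genome: dict[str, str], annotation: GenomeAnnotation
) -> dict[str, list[tuple[int, int]]]:
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for gene in annotation.genes:
        for tx in gene.transcripts:
            spans[gene.chrom].append((tx.start, tx.end))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, lst in spans.items():
        lst.sort()
        gaps = []
        cur = 0
        for s, e in lst:
            if s > cur:
                gaps.append((cur, s))
            cur = max(cur, e)
        if cur < len(genome[chrom]):
            gaps.append((cur, len(genome[chrom])))
        out[chrom] = gaps
    return out


def plant_circles(
    annotation: GenomeAnnotation,
    config: SimConfig,
    genome: Optional[dict[str, str]] = None,
) -> tuple[list[CircCandidate], dict[str, str]]:
    """Plant true circles and decoy junctions on a toy annotation.

    True circles span internal exon runs of a host transcript, so both
    boundaries sit on exon boundaries (score 2).  Half of the decoys take
    such a span and shift its boundaries 1-10 bases off the exon edges
    (score <= 1); the rest are intergenic spans (score 0).  Returns the
    candidate list plus a ``circ_id -> {'circle', 'decoy'}`` truth map.
    """
    rng = np.random.default_rng([config.seed, 1])
    hosts = [t for t in annotation.transcripts if len(t.exons) >= 3]
    n_shifted = config.n_decoys // 2
    n_intergenic = config.n_decoys - n_shifted
    if len(hosts) < config.n_true_circles + n_shifted:
        raise ValueError(
            f"{config.n_true_circles} circles + {n_shifted} shifted decoys "
            f"requested but only {len(hosts)} transcripts with >= 3 exons"
        )
    hosts = list(hosts)
    rng.shuffle(hosts)

    candidates: list[CircCandidate] = []
    kinds: dict[str, str] = {}
    used: set[tuple] = set()

    def exon_span(tx: Transcript) -> tuple[int, int]:
        n = len(tx.exons)
        i = int(rng.integers(1, n - 1))
        k = int(rng.integers(i, n - 1))
        return tx.exons[i][0], tx.exons[k][1]

    def support(kind: str) -> frozenset[str]:
        size = int(rng.integers(3, 6)) if kind == "circle" else int(rng.integers(1, 3))
        return frozenset(rng.choice(PIPELINE_NAMES, size=size, replace=False))

    for tx in hosts[: config.n_true_circles]:
        start, end = exon_span(tx)
        cand = CircCandidate(tx.chrom, start, end, tx.strand, support("circle"))
        if cand.key in used:
            continue
        used.add(cand.key)
        candidates.append(cand)
        kinds[cand.circ_id] = "circle"

    for tx in hosts[config.n_true_circles : config.n_true_circles + n_shifted]:
        for _attempt in range(20):
            start, end = exon_span(tx)
            # shift one boundary (score 1) or both (score 0) off the exon edges
            mode = rng.integers(3)
            ds = int(rng.integers(1, 11)) * (1 if rng.random() < 0.5 else -1)
            de = int(rng.integers(1, 11)) * (1 if rng.random() < 0.5 else -1)
            if mode == 0:
                de = 0
            elif mode == 1:
                ds = 0
            start, end = start + ds, end + de
            if end - start < config.read_length:
                continue
            cand = CircCandidate(tx.chrom, start, end, tx.strand, support("decoy"))
            score = max(
                (
                    score_candidate_against_transcript(cand, t)
                    for t in annotation.overlapping_transcripts(
                        cand.chrom, cand.start, cand.end, cand.strand
                    )
                ),
                default=0,
            )
            if score <= 1 and cand.key not in used:
                used.add(cand.key)
                candidates.append(cand)
                kinds[cand.circ_id] = "decoy"
                break
        else:
            raise ValueError(f"could not place a shifted decoy on {tx.id}")

    if n_intergenic:
        if genome is None:
            raise ValueError("intergenic decoys require the genome sequence")
        gaps = _intergenic_intervals(genome, annotation)
        flat = [(c, s, e) for c, lst in gaps.items() for s, e in lst if e - s >= 180]
        for _ in range(n_intergenic):
            for _attempt in range(50):
                c, s, e = flat[int(rng.integers(len(flat)))]
                span = int(rng.integers(150, min(400, e - s) + 1))
                start = int(rng.integers(s, e - span + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                cand = CircCandidate(c, start, start + span, strand, support("decoy"))
                if cand.key not in used:
                    used.add(cand.key)
                    candidates.append(cand)
                    kinds[cand.circ_id] = "decoy"
                    break
            else:
                raise ValueError("could not place an intergenic decoy")
    return candidates, kinds


def _junction_read_starts(
    rng: np.random.Generator, seq_len: int, offset: int, read_len: int,
    overhang: int, n: int
) -> np.ndarray:
    """Uniform start positions such that the read lies inside the sequence
    and covers >= overhang bases on each side of the junction."""
    lo = max(0, offset + 1 + overhang - read_len)
    hi = min(seq_len - read_len, offset + 1 - overhang)
    if lo > hi:
        raise ValueError(
            f"cannot span junction: window {seq_len}, offset {offset}, "
            f"read {read_len}, overhang {overhang}"
        )
    return rng.integers(lo, hi + 1, size=n)


@dataclass
class SimOutput:
    config: SimConfig
    genome: dict[str, str]
    annotation: GenomeAnnotation
    candidates: list[CircCandidate]
    kinds: dict[str, str]
    assignments: list[BoundaryAssignment]
    references: list[JunctionReference]
    ledger: dict
    fastq: dict[str, dict[str, list[Path]]]  # set -> library -> paths
    paths: dict[str, Path] = field(default_factory=dict)


def generate_reads(
    annotation: GenomeAnnotation,
    genome: dict[str, str],
    candidates: Sequence[CircCandidate],
    kinds: dict[str, str],
    config: SimConfig,
    outdir,
) -> SimOutput:
    """Generate per-set mock/RNase R FASTQ libraries plus the truth ledger.

    Set ``s`` plants ``round(reads_per_circle_set1 / 2**(s-1))`` junction
    reads per junction when halving is on.  Linear junction reads are drawn
    from the host's linear_left/linear_right references.  The RNase R
    library is the per-read Bernoulli thinning of the mock library.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 2])
    assignments = [assign_best_transcript(c, annotation) for c in candidates]
    W = config.effective_W
    references = build_references(assignments, annotation, genome, W)
    by_id = {r.circ_id: r for r in references}
    L = config.read_length
    ov = config.junction_overhang
    pe = config.pairing == "PE"

    # Planted backsplice reads must be junction-diagnostic: a read whose
    # short junction overhang happens to continue colinearly in the genome
    # or transcriptome (within the mismatch budget) would be discarded by
    # the exclusion filter, so such draws are rejected and redrawn.
    genome_searcher = MismatchSearcher(genome, m=config.mismatch_budget)
    tx_searcher = MismatchSearcher(
        spliced_transcript_sequences(annotation, genome), m=config.mismatch_budget
    )

    def _diagnostic(read_seq: str) -> bool:
        return not (
            genome_searcher.has_placement(read_seq)
            or tx_searcher.has_placement(read_seq)
        )

    ledger: dict = {"entries": {}, "libraries": {}}
    fastq: dict[str, dict[str, list[Path]]] = {}
    for cand, assignment in zip(candidates, assignments):
        ref = by_id[cand.circ_id]
        ledger["entries"][cand.circ_id] = {
            "kind": kinds[cand.circ_id],
            "chrom": cand.chrom,
            "start": cand.start,
            "end": cand.end,
            "strand": cand.strand,
            "score": assignment.score,
            "circle_length": ref.circle_length,
            "sets": {},
        }

    for s in range(1, config.n_sets + 1):
        set_name = f"set{s}"
        n_bsj = (
            int(round(config.reads_per_circle_set1 / 2 ** (s - 1)))
            if config.set_halving
            else config.reads_per_circle_set1
        )
        mock: list[tuple[str, str]] = []  # SE: (id, seq); PE stores fragments
        mock_pe: list[tuple[str, str, str]] = []
        surviving: dict[str, list[str]] = {}

        def emit(circ_id: str, category: str, seq: str, offset: int, n: int,
                 p_survive: float, entry_sets: dict) -> None:
            if n <= 0:
                return
            tmpl_len = min(config.fragment_length, len(seq)) if pe else L
            keep = rng.random(n) < p_survive
            ids = []
            for i in range(n):
                r1 = r2_region = frag = ""
                for _attempt in range(60):
                    u = int(
                        _junction_read_starts(rng, len(seq), offset, tmpl_len, ov, 1)[0]
                    )
                    frag = seq[u : u + tmpl_len]
                    jpos = offset - u  # base left of the junction, fragment coords
                    if pe:
                        r1 = frag[:L]
                        r2_region = frag[-L:]
                        spans1 = ov - 1 <= jpos <= L - 1 - ov
                        spans2 = ov - 1 <= jpos - (tmpl_len - L) <= L - 1 - ov
                        if not (spans1 or spans2):
                            continue
                        if category != "bsj":
                            break
                        if (spans1 and _diagnostic(r1)) or (spans2 and _diagnostic(r2_region)):
                            break
                    else:
                        if category != "bsj" or _diagnostic(frag):
                            break
                else:
                    log.warning(
                        "%s %s read %d: no junction-diagnostic draw in 60 tries; "
                        "keeping the last one", circ_id, category, i,
                    )
                read_id = f"{circ_id}|{category}|{set_name}|{i:05d}"
                ids.append(read_id)
                if pe:
                    mock_pe.append((read_id, r1, reverse_complement(r2_region)))
                else:
                    mock.append((read_id, frag))
                if keep[i]:
                    surviving.setdefault(circ_id, []).append(read_id)
            entry_sets.setdefault(category, []).extend(ids)

        for cand in candidates:
            ref = by_id[cand.circ_id]
            entry = ledger["entries"][cand.circ_id]
            set_slot: dict = {"n_bsj_reads": n_bsj, "read_ids": {}}
            entry["sets"][set_name] = set_slot
            is_circle = kinds[cand.circ_id] == "circle"
            p_bsj = config.survival_circ if is_circle else config.survival_linear
            emit(cand.circ_id, "bsj", ref.window, ref.window_offset, n_bsj,
                 p_bsj, set_slot["read_ids"])
            if ref.linear_left is not None:
                emit(cand.circ_id, "linear_left", ref.linear_left,
                     ref.linear_left_offset, config.linear_reads_per_gene,
                     config.survival_linear, set_slot["read_ids"])
            if ref.linear_right is not None:
                emit(cand.circ_id, "linear_right", ref.linear_right,
                     ref.linear_right_offset, config.linear_reads_per_gene,
                     config.survival_linear, set_slot["read_ids"])
            set_slot["rnaser_read_ids"] = surviving.get(cand.circ_id, [])
            surviving.pop(cand.circ_id, None)

        fastq[set_name] = {}
        if pe:
            surv = {rid for e in ledger["entries"].values()
                    for rid in e["sets"][set_name]["rnaser_read_ids"]}
            r1 = outdir / f"{set_name}_mock_R1.fastq"
            r2 = outdir / f"{set_name}_mock_R2.fastq"
            bio_io.write_fastq(((i, a) for i, a, _ in mock_pe), r1)
            bio_io.write_fastq(((i, b) for i, _, b in mock_pe), r2)
            t1 = outdir / f"{set_name}_rnaser_R1.fastq"
            t2 = outdir / f"{set_name}_rnaser_R2.fastq"
            bio_io.write_fastq(((i, a) for i, a, _ in mock_pe if i in surv), t1)
            bio_io.write_fastq(((i, b) for i, _, b in mock_pe if i in surv), t2)
            fastq[set_name]["mock"] = [r1, r2]
            fastq[set_name]["rnaser"] = [t1, t2]
        else:
            surv = {rid for e in ledger["entries"].values()
                    for rid in e["sets"][set_name]["rnaser_read_ids"]}
            mpath = outdir / f"{set_name}_mock.fastq"
            tpath = outdir / f"{set_name}_rnaser.fastq"
            bio_io.write_fastq(mock, mpath)
            bio_io.write_fastq(((i, s_) for i, s_ in mock if i in surv), tpath)
            fastq[set_name]["mock"] = [mpath]
            fastq[set_name]["rnaser"] = [tpath]
        ledger["libraries"][set_name] = {
            lib: [str(p) for p in paths] for lib, paths in fastq[set_name].items()
        }

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"config": asdict(config), **ledger}, fh, indent=1)
    return SimOutput(
        config=config,
        genome=genome,
        annotation=annotation,
        candidates=list(candidates),
        kinds=kinds,
        assignments=assignments,
        references=references,
        ledger=ledger,
        fastq=fastq,
        paths={"truth": truth_path},
    )


def simulate(config: SimConfig, outdir) -> SimOutput:
    """Full simulation: genome + annotation + candidates + read libraries.

    Writes genome.fa, annotation.gtf, candidates.bed, truth.json and the
    per-set FASTQ files under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation = make_toy_genome(config)
    candidates, kinds = plant_circles(annotation, config, genome=genome)
    out = generate_reads(annotation, genome, candidates, kinds, config, outdir)
    out.paths["genome"] = bio_io.write_genome_fasta(genome, outdir / "genome.fa")
    out.paths["gtf"] = bio_io.write_gtf(annotation, outdir / "annotation.gtf")
    out.paths["candidates"] = bio_io.write_candidates_bed(
        candidates, outdir / "candidates.bed"
    )
    return out


def truncate_reads(fastq_in, L: int, fastq_out) -> Path:
    """Clip every read (and its qualities) to its first L bases."""
    if L < 1:
        raise ValueError("truncation length must be >= 1")
    fastq_out = Path(fastq_out)
    with bio_io._open_text(fastq_in) as fin, bio_io._open_text(fastq_out, "wt") as fout:
        for title, seq, qual in FastqGeneralIterator(fin):
            fout.write(f"@{title}\n{seq[:L]}\n+\n{qual[:L]}\n")
    return fastq_out


def select_random_exon_transcripts(
    annotation: GenomeAnnotation,
    n: int,
    seed: int,
    genome: Optional[dict[str, str]] = None,
) -> tuple[list[Transcript], Optional[dict[str, str]]]:
    """Random background exon set for genomic-feature comparisons.

    The pool holds, for each gene, the starting exon of its first
    transcript (in transcript orientation); ``n`` of these are sampled
    without replacement, each becoming a single-exon background record.
    With a genome, the records' sequences are returned as well.
    """
    pool: list[Transcript] = []
    for gene in annotation.genes:
        tx = gene.transcripts[0]
        first = tx.exons[-1] if tx.strand == "-" else tx.exons[0]
        pool.append(
            Transcript(
                id=f"bg_{tx.id}",
                gene_id=gene.id,
                chrom=tx.chrom,
                strand=tx.strand,
                exons=(first,),
            )
        )
    if n > len(pool):
        raise ValueError(f"requested {n} exons but only {len(pool)} genes available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    chosen = [pool[i] for i in sorted(idx)]
    seqs = None
    if genome is not None:
        seqs = {}
        for t in chosen:
            s = fetch(genome, t.chrom, t.exons[0][0], t.exons[0][1])
            seqs[t.id] = reverse_complement(s) if t.strand == "-" else s
    return chosen, seqs
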