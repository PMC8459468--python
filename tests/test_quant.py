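"""Seed-anchored junction matching, exclusion filtering and counting."""

import numpy as np
import pytest

from backsplice.quant import (
    JunctionHit,
    JunctionMatcher,
    MismatchSearcher,
    ReadRecord,
    count_junctions,
    match_read_to_junction,
    quantify_library,
)
from backsplice.refbuild import JunctionReference, build_circular_window
from backsplice.simdata import SimConfig, simulate

from conftest import (
    oracle_has_linear_placement,
    oracle_junction_placements,
    random_seq,
    revcomp,
)


def make_ref(circle: str, W: int = 70, circ_id: str = "c1") -> JunctionReference:
    window, offset = build_circular_window(circle, W)
    return JunctionReference(
        circ_id=circ_id, strand="+", score=2, circle_length=len(circle),
        W=W, window=window, window_offset=offset,
    )


def read(seq, read_id="r1", mate=None):
    return ReadRecord(read_id=read_id, mate=mate, seq=seq)


class TestJunctionMatching:
    def setup_method(self):
        rng = np.random.default_rng(2024)
        self.circle = random_seq(rng, 300)
        self.ref = make_ref(self.circle)

    def test_exact_seed_read_hits(self):
        """A read equal to the 2j bases centred on the junction is a hit
        with zero mismatches."""
        o = self.ref.window_offset
        seed_read = self.ref.window[o - 4 : o + 6]
        hit = match_read_to_junction(read(seed_read), self.ref, "circular")
        assert hit is not None
        assert hit.mismatches_outside_seed == 0

    @pytest.mark.parametrize("side_bases,expect_hit", [(4, False), (5, True), (6, True)])
    def test_junction_overlap_requirement(self, side_bases, expect_hit):
        """Under the default seed of 5 bases per side, a junction-spanning
        read leaving only 4 bases on one side is rejected."""
        o = self.ref.window_offset
        start = o + 1 - side_bases
        r = self.ref.window[start : start + 40]
        hit = match_read_to_junction(read(r), self.ref, "circular")
        assert (hit is not None) == expect_hit

    def test_mismatch_inside_seed_rejected(self):
        o = self.ref.window_offset
        r = list(self.ref.window[o - 20 : o + 21])
        pos = 20  # junction base, inside the seed
        r[pos] = {"A": "C"}.get(r[pos], "A")
        assert match_read_to_junction(read("".join(r)), self.ref, "circular") is None

    def test_mismatch_budget_outside_seed(self):
        o = self.ref.window_offset
        r = list(self.ref.window[o - 30 : o + 31])
        for pos in (0, 1, 2):  # three mismatches outside the seed
            r[pos] = {"A": "C"}.get(r[pos], "A")
        assert match_read_to_junction(read("".join(r)), self.ref, "circular") is None
        assert match_read_to_junction(
            read("".join(r)), self.ref, "circular", m=3
        ) is not None

    def test_n_counts_as_mismatch_even_when_matching_n(self):
        o = self.ref.window_offset
        r = self.ref.window[o - 30 : o + 31]
        assert match_read_to_junction(
            read(r[:-3] + "NNN"), self.ref, "circular", m=2
        ) is None

    def test_short_read_cannot_span(self):
        assert match_read_to_junction(read("ACGTACGT"), self.ref, "circular") is None

    def test_unstranded_matches_reverse_complement(self):
        o = self.ref.window_offset
        r = self.ref.window[o - 30 : o + 31]
        assert match_read_to_junction(read(revcomp(r)), self.ref, "circular") is None
        hit = match_read_to_junction(
            read(revcomp(r)), self.ref, "circular", strandedness="unstranded"
        )
        assert hit is not None and hit.mismatches_outside_seed == 0

    @pytest.mark.parametrize("instance", range(20))
    def test_matches_sliding_window_oracle(self, instance):
        """The seed-indexed matcher returns exactly the best placement the
        exhaustive sliding-comparison oracle finds."""
        rng = np.random.default_rng(instance)
        circle = random_seq(rng, int(rng.integers(90, 250)))
        ref = make_ref(circle, W=70)
        j, m = 5, 2
        for _ in range(30):
            kind = rng.integers(3)
            if kind == 0:  # read drawn across the junction, with noise
                o = ref.window_offset
                u = int(rng.integers(max(0, o - 60), o + 1))
                r = list(ref.window[u : u + 70])
            elif kind == 1:  # read from inside the circle
                u = int(rng.integers(0, max(1, len(circle) - 70)))
                r = list((circle + circle)[u : u + 70])[:70]
            else:  # random read
                r = list(random_seq(rng, 70))
            for _mut in range(int(rng.integers(0, 4))):
                r[int(rng.integers(len(r)))] = "ACGT"[int(rng.integers(4))]
            r = "".join(r)
            hit = match_read_to_junction(read(r), ref, "circular", j=j, m=m)
            oracle = oracle_junction_placements(r, ref.window, ref.window_offset, j, m)
            if not oracle:
                assert hit is None
            else:
                assert hit is not None
                assert (hit.mismatches_outside_seed, hit.align_offset) == min(oracle)

    def test_hits_monotone_in_j_and_m(self):
        """A hit at seed half-width j survives at any smaller j, and a hit
        with budget m survives at any larger m."""
        rng = np.random.default_rng(77)
        circle = random_seq(rng, 200)
        ref = make_ref(circle)
        o = ref.window_offset
        for _ in range(50):
            u = int(rng.integers(o - 55, o))
            r = list(ref.window[u : u + 60])
            for _mut in range(int(rng.integers(0, 3))):
                r[int(rng.integers(len(r)))] = "ACGT"[int(rng.integers(4))]
            r = "".join(r)
            hits = {
                (j, m): match_read_to_junction(read(r), ref, "circular", j=j, m=m)
                for j in (3, 5, 8) for m in (0, 2, 4)
            }
            for j1, j2 in ((3, 5), (5, 8)):
                for m in (0, 2, 4):
                    if hits[(j2, m)] is not None:
                        assert hits[(j1, m)] is not None
            for m1, m2 in ((0, 2), (2, 4)):
                for j in (3, 5, 8):
                    if hits[(j, m1)] is not None:
                        assert hits[(j, m2)] is not None


class TestExclusion:
    def test_exonic_read_discarded_junction_read_kept(self):
        rng = np.random.default_rng(3)
        exon = random_seq(rng, 200)
        genome = {"chr1": random_seq(rng, 100) + exon + random_seq(rng, 100)}
        tx = {"t1": exon}
        searcher_g = MismatchSearcher(genome, m=2)
        searcher_t = MismatchSearcher(tx, m=2)
        exonic = exon[50:120]
        assert searcher_g.has_placement(exonic)
        assert searcher_t.has_placement(exonic)
        junction_read = exon[-35:] + exon[:35]  # backsplice over the exon
        assert not searcher_g.has_placement(junction_read)
        assert not searcher_t.has_placement(junction_read)

    def test_reverse_strand_placement_found(self):
        rng = np.random.default_rng(4)
        genome = {"chr1": random_seq(rng, 500)}
        probe = revcomp(genome["chr1"][100:170])
        assert MismatchSearcher(genome, m=0).has_placement(probe)

    def test_tandem_duplication_read_discarded(self):
        """A junction-like read from a tandem exon duplication does place
        on the genome and must be excluded (verified against exhaustive
        substring search)."""
        rng = np.random.default_rng(8)
        exon = random_seq(rng, 150)
        genome = {"chr1": random_seq(rng, 80) + exon + exon + random_seq(rng, 80)}
        dup_read = exon[-35:] + exon[:35]  # backsplice-like, but genome-colinear
        searcher = MismatchSearcher(genome, m=2)
        assert searcher.has_placement(dup_read)
        assert oracle_has_linear_placement(dup_read, genome, 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_searcher_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genome = {"chr1": random_seq(rng, 600), "chr2": random_seq(rng, 400)}
        searcher = MismatchSearcher(genome, m=2)
        for _ in range(25):
            mode = rng.integers(3)
            if mode == 0:
                chrom = "chr1" if rng.random() < 0.5 else "chr2"
                u = int(rng.integers(0, len(genome[chrom]) - 50))
                r = list(genome[chrom][u : u + 50])
                for _mut in range(int(rng.integers(0, 4))):
                    r[int(rng.integers(50))] = "ACGT"[int(rng.integers(4))]
                r = "".join(r)
            elif mode == 1:
                r = revcomp(genome["chr1"][100:150])
            else:
                r = random_seq(rng, 50)
            assert searcher.has_placement(r) == oracle_has_linear_placement(
                r, genome, 2
            )


class TestCounting:
    def _hit(self, rid, circ="c1", kind="circular", mate=None):
        return JunctionHit(read_id=rid, circ_id=circ, junction_kind=kind,
                           align_offset=0, mismatches_outside_seed=0, mate=mate)

    def test_se_additivity(self):
        hits = [self._hit(f"r{i}") for i in range(10)]
        t = count_junctions(hits, circ_ids=["c1"])
        assert t.counts.loc["c1", "circ_count"] == 10

    def test_pe_fragment_counted_once(self):
        hits = [self._hit("frag1", mate=1), self._hit("frag1", mate=2)]
        t = count_junctions(hits, pairing="PE", circ_ids=["c1"])
        assert t.counts.loc["c1", "circ_count"] == 1

    def test_ambiguous_fragment_dropped(self):
        hits = [self._hit("r1", circ="c1"), self._hit("r1", circ="c2")]
        t = count_junctions(hits, circ_ids=["c1", "c2"])
        assert t.counts["circ_count"].sum() == 0
        assert t.n_ambiguous == 1

    def test_ambiguity_from_shared_boundary_exons(self):
        """Two circles sharing their first and last exon have identical
        junction windows; a junction read matches both and is counted for
        neither."""
        rng = np.random.default_rng(12)
        first = random_seq(rng, 80)
        last = random_seq(rng, 80)
        c1 = first + random_seq(rng, 60) + last
        c2 = first + random_seq(rng, 90) + last
        ref1 = make_ref(c1, circ_id="c1")
        ref2 = make_ref(c2, circ_id="c2")
        assert ref1.window == ref2.window
        matcher = JunctionMatcher([ref1, ref2], j=5, m=2)
        o = ref1.window_offset
        r = ref1.window[o - 34 : o + 36]
        hits = matcher.match_sequence(r)
        assert {cid for cid, _k in hits} == {"c1", "c2"}
        t = count_junctions(
            [self._hit("r1", circ=cid) for (cid, _k) in hits],
            circ_ids=["c1", "c2"],
        )
        assert t.counts["circ_count"].sum() == 0
        assert t.n_ambiguous == 1

    def test_duplicate_mate_fatal_in_quantify(self, tmp_path):
        fq = tmp_path / "dup.fastq"
        fq.write_text("@r1\nACGT\n+\nIIII\n@r1\nACGT\n+\nIIII\n")
        rng = np.random.default_rng(0)
        ref = make_ref(random_seq(rng, 200))
        from backsplice.annotation import GenomeAnnotation
        ann = GenomeAnnotation([])
        with pytest.raises(ValueError, match="r1"):
            quantify_library([fq], [ref], ann, {"chr1": random_seq(rng, 300)},
                             library_id="dup")


@pytest.fixture(scope="module")
def sim(tmp_path_factory):
    cfg = SimConfig(seed=21, n_genes=40, n_true_circles=6, n_decoys=4,
                    reads_per_circle_set1=15, linear_reads_per_gene=10)
    return simulate(cfg, tmp_path_factory.mktemp("sim"))


class TestQuantifyLibrary:

    def test_exact_recovery_of_planted_reads(self, sim):
        """With depletion off (mock library), every planted backsplice read
        is counted: counts equal the truth ledger exactly."""
        table, _ = quantify_library(
            sim.fastq["set1"]["mock"], sim.references, sim.annotation,
            sim.genome, library_id="mock",
        )
        for circ_id, entry in sim.ledger["entries"].items():
            assert (
                int(table.counts.loc[circ_id, "circ_count"])
                == entry["sets"]["set1"]["n_bsj_reads"]
            )

    def test_antisense_reads_yield_zero_in_stranded_mode(self, sim, tmp_path):
        """In stranded mode only reads on the junction strand count."""
        from backsplice.io import read_fastq, write_fastq

        rc_path = tmp_path / "rc.fastq"
        write_fastq(
            ((rid, revcomp(seq)) for rid, seq in read_fastq(sim.fastq["set1"]["mock"][0])),
            rc_path,
        )
        stranded, _ = quantify_library(
            [rc_path], sim.references, sim.annotation, sim.genome,
            library_id="rc", strandedness="forward",
        )
        assert stranded.counts["circ_count"].sum() == 0
        unstranded, _ = quantify_library(
            [rc_path], sim.references, sim.annotation, sim.genome,
            library_id="rc-u", strandedness="unstranded",
        )
        forward, _ = quantify_library(
            sim.fastq["set1"]["mock"], sim.references, sim.annotation,
            sim.genome, library_id="fwd", strandedness="unstranded",
        )
        assert unstranded.counts.equals(forward.counts)

    def test_empty_fastq_gives_zero_table(self, sim, tmp_path, caplog):
        empty = tmp_path / "empty.fastq"
        empty.write_text("")
        with caplog.at_level("WARNING"):
            table, evidence = quantify_library(
                [empty], sim.references, sim.annotation, sim.genome,
                library_id="empty",
            )
        assert table.library_size == 0
        assert table.counts.values.sum() == 0
        assert len(evidence) == 0
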