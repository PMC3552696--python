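"""Exon calling, splice-site search, junction library and matching, assembly."""

import numpy as np
import pytest

from lincmir.assembly import (
    Junction,
    LibraryEntry,
    PutativeExon,
    SpliceSite,
    assemble_transcripts,
    build_junction_library,
    call_putative_exons,
    find_splice_sites,
    match_junction_reads,
)
from lincmir.intervals import GenomicInterval, SplicedAlignment
from lincmir.seq import revcomp

from oracles import exon_call_oracle, junction_match_oracle, junction_pairs_oracle


def read(rid, start, end, strand="+", chrom="chr1", sample="s0"):
    return SplicedAlignment(rid, sample, strand, [GenomicInterval(chrom, start, end, strand)])


REGION = GenomicInterval("chr1", 0, 1000, "+")


class TestExonCalling:
    def test_eight_identical_reads_make_one_exon(self):
        alns = [read(f"r{i}", 100, 135) for i in range(8)]
        exons = call_putative_exons(alns, REGION)
        assert len(exons) == 1
        assert (exons[0].interval.start, exons[0].interval.end) == (100, 135)
        assert exons[0].support == 8

    def test_seven_reads_insufficient(self):
        alns = [read(f"r{i}", 100, 135) for i in range(7)]
        assert call_putative_exons(alns, REGION) == []

    def test_small_gap_merges(self):
        alns = [read(f"a{i}", 100, 135) for i in range(8)]
        alns += [read(f"b{i}", 140, 175) for i in range(8)]
        exons = call_putative_exons(alns, REGION)
        assert len(exons) == 1
        assert (exons[0].interval.start, exons[0].interval.end) == (100, 175)
        assert exons[0].support == 16

    def test_gap_of_exactly_merge_gap_not_merged(self):
        alns = [read(f"a{i}", 100, 135) for i in range(8)]
        alns += [read(f"b{i}", 145, 180) for i in range(8)]
        exons = call_putative_exons(alns, REGION, merge_gap=10)
        assert len(exons) == 2

    def test_empty_input(self):
        assert call_putative_exons([], REGION) == []

    def test_order_independence(self, rng):
        alns = [
            read(f"r{i}", int(s), int(s) + 40)
            for i, s in enumerate(rng.integers(0, 900, size=60))
        ]
        ref = call_putative_exons(alns, REGION, min_reads=3)
        perm = [alns[i] for i in rng.permutation(len(alns))]
        got = call_putative_exons(perm, REGION, min_reads=3)
        assert [(e.interval.start, e.interval.end, e.support) for e in ref] == [
            (e.interval.start, e.interval.end, e.support) for e in got
        ]

    def test_matches_brute_force_coverage_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            blocks = []
            alns = []
            for i in range(n):
                s = int(rng.integers(0, 450))
                e = s + int(rng.integers(10, 60))
                blocks.append((s, e, f"r{i}"))
                alns.append(read(f"r{i}", s, e))
            region = GenomicInterval("chr1", 0, 500, "+")
            got = call_putative_exons(alns, region, min_reads=3, merge_gap=10)
            expected = exon_call_oracle(blocks, 0, 500, min_reads=3, merge_gap=10)
            assert [(e.interval.start, e.interval.end, e.support) for e in got] == expected


class TestSpliceSites:
    def test_planted_donor_found(self):
        seq = "A" * 200 + "GT" + "A" * 200
        exon = PutativeExon(GenomicInterval("chr1", 150, 200, "+"), 8)
        donors, _ = find_splice_sites(seq, exon, 0)
        assert any(d.pos == 200 and d.strand == "+" for d in donors)

    def test_no_motifs_no_sites(self):
        seq = "A" * 400
        exon = PutativeExon(GenomicInterval("chr1", 150, 200, "+"), 8)
        donors, acceptors = find_splice_sites(seq, exon, 0)
        assert donors == [] and acceptors == []

    def test_matches_dinucleotide_scan(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            exon = PutativeExon(GenomicInterval("chr1", 150, 250, "+"), 8)
            donors, acceptors = find_splice_sites(seq, exon, 0, search=25)
            exp_donors = [
                (p, {"GT": "+", "CT": "-"}[seq[p : p + 2]])
                for p in range(250 - 25, 250 + 26)
                if seq[p : p + 2] in ("GT", "CT")
            ]
            exp_acceptors = [
                (q, {"AG": "+", "AC": "-"}[seq[q - 1 : q + 1]])
                for q in range(149 - 25, 149 + 26)
                if seq[q - 1 : q + 1] in ("AG", "AC")
            ]
            assert [(d.pos, d.strand) for d in donors] == exp_donors
            assert [(a.pos, a.strand) for a in acceptors] == exp_acceptors


def make_sites(donor_positions, acceptor_positions, strand="+"):
    donors = [SpliceSite("donor", p, strand, 0) for p in donor_positions]
    acceptors = [SpliceSite("acceptor", p, strand, 1) for p in acceptor_positions]
    return donors, acceptors


class TestJunctionLibrary:
    GENOME = "ACGT" * 60_000  # 240 kb

    def test_combinatorial_count(self):
        donors, acceptors = make_sites([1000, 2000], [3000, 4000, 5000])
        lib = build_junction_library(donors, acceptors, self.GENOME, flank=20, min_intron=50)
        assert len(lib) == len(
            junction_pairs_oracle([1000, 2000], [3000, 4000, 5000], min_intron=50)
        ) == 6

    def test_min_intron_boundary(self):
        donors, acceptors = make_sites([1000], [1068, 1069])
        lib = build_junction_library(donors, acceptors, self.GENOME, flank=20)
        # intron lengths 69 and 70: only the 70 survives
        assert [e.junction.acceptor_pos for e in lib] == [1069]

    def test_max_span_boundary(self):
        donors, acceptors = make_sites([0], [100_000, 100_001])
        lib = build_junction_library(donors, acceptors, self.GENOME, flank=20)
        assert [e.junction.acceptor_pos for e in lib] == [100_000]

    def test_strand_mismatch_rejected(self):
        donors = [SpliceSite("donor", 1000, "+", 0)]
        acceptors = [SpliceSite("acceptor", 2000, "-", 1)]
        assert build_junction_library(donors, acceptors, self.GENOME, flank=20) == []

    def test_entry_sequence_spliced_at_junction(self):
        genome = "A" * 1000 + "GT" + "C" * 96 + "AG" + "G" * 1000
        donors, acceptors = make_sites([1000], [1099])
        (entry,) = build_junction_library(donors, acceptors, genome, flank=10)
        assert entry.seq == "A" * 10 + "G" * 10
        assert entry.junction_offset == 10

    def test_minus_strand_entry_in_transcript_sense(self):
        genome = "A" * 1000 + "CT" + "G" * 96 + "AC" + "C" * 1000
        donors, acceptors = make_sites([1000], [1099], strand="-")
        (entry,) = build_junction_library(donors, acceptors, genome, flank=10)
        # transcript sense = revcomp(left flank + right flank)
        assert entry.seq == revcomp("A" * 10 + "C" * 10)
        assert entry.junction_offset == 10

    def test_clipping_flagged(self):
        donors, acceptors = make_sites([30], [150])
        (entry,) = build_junction_library(
            donors, acceptors, self.GENOME[:400], flank=50, min_intron=50
        )
        assert entry.clipped

    def test_every_emitted_junction_respects_constraints(self, rng):
        dpos = sorted(int(x) for x in rng.integers(0, 150_000, 15))
        apos = sorted(int(x) for x in rng.integers(0, 150_000, 15))
        donors, acceptors = make_sites(dpos, apos)
        lib = build_junction_library(donors, acceptors, "ACGT" * 40_000, flank=20)
        for e in lib:
            assert e.junction.intron_length >= 70
            assert e.junction.acceptor_pos - e.junction.donor_pos <= 100_000
        assert len(lib) == len(junction_pairs_oracle(dpos, apos))


def entry(seq, joff, donor=0, acceptor=200, de=0, ae=1):
    return LibraryEntry(
        Junction(donor, acceptor, "+", "GT-AG", de, ae), seq, joff
    )


class TestJunctionMatching:
    def test_exact_central_read_supports(self, rng):
        lib_seq = "".join(rng.choice(list("ACGT"), size=98))
        e = entry(lib_seq, 49)
        read_seq = lib_seq[41:57]  # central 2*anchor bases
        support = match_junction_reads([("r1", read_seq)], [e], anchor=8)
        assert support == {e.junction: 1}

    def test_insufficient_overhang_rejected(self, rng):
        lib_seq = "".join(rng.choice(list("ACGT"), size=98))
        e = entry(lib_seq, 49)
        # overhangs junction by 7 on the left (offset 42 > 49 - 8)
        read_seq = lib_seq[42:70]
        assert match_junction_reads([("r1", read_seq)], [e], anchor=8) == {}

    def test_tie_between_junctions_dropped(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGT"  # 32 bases
        e1 = entry(seq, 16, donor=0, acceptor=200)
        e2 = entry(seq, 16, donor=500, acceptor=700)
        assert match_junction_reads([("r", seq)], [e1, e2], anchor=8) == {}

    def test_matches_exhaustive_scan(self, rng):
        for trial in range(60):
            entries = []
            for i in range(6):
                seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(70, 100))))
                entries.append(entry(seq, int(rng.integers(20, len(seq) - 20)),
                                     donor=i * 1000, acceptor=i * 1000 + 200))
            reads = []
            for j in range(25):
                src = entries[int(rng.integers(0, len(entries)))]
                L = int(rng.integers(36, 50))
                o = int(rng.integers(0, len(src.seq) - L + 1))
                bases = list(src.seq[o : o + L])
                for _ in range(int(rng.integers(0, 4))):  # up to 3 mutations
                    bases[int(rng.integers(0, L))] = str(rng.choice(list("ACGT")))
                reads.append((f"t{trial}r{j}", "".join(bases)))
            support = match_junction_reads(reads, entries, anchor=8, max_mismatch=2)
            expected: dict = {}
            oracle_entries = [(e.seq, e.junction_offset) for e in entries]
            for _, seq in reads:
                win = junction_match_oracle(seq, oracle_entries, anchor=8, max_mismatch=2)
                if win is not None:
                    j = entries[win].junction
                    expected[j] = expected.get(j, 0) + 1
            assert support == expected


class TestAssembly:
    def exon(self, s, e):
        return PutativeExon(GenomicInterval("chr1", s, e, "."), 8)

    def test_chain_of_junctions_one_transcript(self):
        exons = [self.exon(100, 200), self.exon(300, 400), self.exon(500, 600)]
        support = {
            Junction(200, 299, "+", "GT-AG", 0, 1): 5,
            Junction(400, 499, "+", "GT-AG", 1, 2): 4,
        }
        txs = assemble_transcripts(exons, support)
        assert len(txs) == 1
        assert [(e.start, e.end) for e in txs[0].exons] == [(100, 200), (300, 400), (500, 600)]
        assert txs[0].strand == "+"
        assert txs[0].spliced_length == 300

    def test_no_junctions_single_exon_transcripts(self):
        txs = assemble_transcripts([self.exon(100, 200), self.exon(500, 600)], {})
        assert len(txs) == 2
        assert all(len(t.exons) == 1 for t in txs)

    def test_boundary_refinement_to_best_supported_site(self):
        exons = [self.exon(100, 205), self.exon(295, 400)]
        support = {
            Junction(200, 299, "+", "GT-AG", 0, 1): 9,
            Junction(202, 299, "+", "GT-AG", 0, 1): 2,
        }
        (tx,) = assemble_transcripts(exons, support)
        assert [(e.start, e.end) for e in tx.exons] == [(100, 200), (300, 400)]

    def test_minus_motif_sets_strand(self):
        exons = [self.exon(100, 200), self.exon(300, 400)]
        support = {Junction(200, 299, "-", "CT-AC", 0, 1): 3}
        (tx,) = assemble_transcripts(exons, support)
        assert tx.strand == "-"
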