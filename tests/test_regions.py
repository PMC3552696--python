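"""Candidate-region filters: merging, gene exclusion, occupancy, CSF."""

import numpy as np
import pytest

from lincmir.intervals import GenomicInterval
from lincmir.regions import (
    CandidateRegion,
    csf_filter,
    csf_score,
    merge_and_exclude,
    rpolii_filter,
    rpolii_rpkm,
)
from lincmir.simulate import make_csf_matrix

from oracles import csf_oracle

import pandas as pd


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


class TestMergeAndExclude:
    def test_overlapping_sources_union(self):
        out = merge_and_exclude([iv(100, 200)], [iv(150, 250)], [], 5000)
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (100, 250)
        assert out[0].source == "human"

    def test_gene_overlap_removes_region(self):
        out = merge_and_exclude([iv(100, 200)], [], [iv(150, 300)], 5000)
        assert out == []

    def test_distance_boundary(self):
        # gap of exactly min_gene_distance keeps the region; one bp less removes it
        gene_kept = [iv(200 + 5000, 200 + 5000 + 100)]
        gene_removed = [iv(200 + 4999, 200 + 4999 + 100)]
        assert len(merge_and_exclude([iv(100, 200)], [], gene_kept, 5000)) == 1
        assert len(merge_and_exclude([iv(100, 200)], [], gene_removed, 5000)) == 0

    def test_mouse_only_region_tagged(self):
        out = merge_and_exclude([], [iv(100, 200)], [], 5000)
        assert out[0].source == "mouse_lifted"

    def test_output_disjoint_and_far_from_genes(self, rng):
        for _ in range(50):
            human = [iv(int(s), int(s) + int(l)) for s, l in
                     zip(rng.integers(0, 50_000, 20), rng.integers(100, 2000, 20))]
            mouse = [iv(int(s), int(s) + int(l)) for s, l in
                     zip(rng.integers(0, 50_000, 10), rng.integers(100, 2000, 10))]
            genes = [iv(int(s), int(s) + 500) for s in rng.integers(0, 50_000, 5)]
            out = merge_and_exclude(human, mouse, genes, 1000)
            spans = sorted((r.interval.start, r.interval.end) for r in out)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
            for r in out:
                for g in genes:
                    assert not r.interval.overlaps(g)
                    assert r.interval.distance(g) >= 1000


class TestRpolii:
    def test_closed_form(self):
        region = iv(0, 2000)
        tags = [iv(int(p), int(p) + 25, strand="+") for p in np.linspace(10, 1900, 20)]
        assert rpolii_rpkm(region, tags, 10_000_000) == pytest.approx(1.0)

    def test_exact_threshold_removed(self):
        # density exactly at the threshold fails the strictly-greater rule
        region = CandidateRegion(iv(0, 1000))
        tags = [iv(10, 35, strand="+")]  # 1 tag / 1 kb / 10M total = 0.1 RPKM
        assert rpolii_filter([region], tags, total_tags=10_000_000, threshold=0.1) == []
        assert region.rpolii_rpkm == pytest.approx(0.1)

    def test_zero_tags_removed(self):
        region = CandidateRegion(iv(0, 1000))
        assert rpolii_filter([region], [], total_tags=100) == []
        assert region.rpolii_rpkm == 0.0

    def test_zero_total_tags_is_error(self):
        with pytest.raises(ValueError):
            rpolii_filter([CandidateRegion(iv(0, 1000))], [], total_tags=0)

    def test_minus_strand_tag_assigned_by_five_prime_end(self):
        region = iv(100, 200)
        inside = iv(80, 150, strand="-")  # 5' end at 149, inside
        outside = iv(150, 220, strand="-")  # 5' end at 219, outside
        assert rpolii_rpkm(region, [inside], 1_000_000) > 0
        assert rpolii_rpkm(region, [outside], 1_000_000) == 0.0


def uniform_matrix(score_same=0.5, score_diff=0.5):
    codons = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    mat = pd.DataFrame(score_diff, index=codons, columns=codons + ["---"])
    for c in codons:
        mat.at[c, c] = score_same
    return mat


class TestCsf:
    def test_identical_alignment_closed_form(self):
        # 30 identical codon columns at +0.5 each
        seq = "ACG" * 30
        score, short = csf_score(seq, [seq], uniform_matrix(0.5, 0.0))
        assert score == pytest.approx(15.0)
        assert not short

    def test_zero_matrix_scores_zero(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        other = "".join(rng.choice(list("ACGT"), size=120))
        score, _ = csf_score(seq, [other], uniform_matrix(0.0, 0.0))
        assert score == 0.0

    def test_short_region_flagged(self):
        seq = "ACG" * 10  # 30 bases < 90
        score, short = csf_score(seq, [seq], uniform_matrix(1.0, 0.0))
        assert short and score == pytest.approx(10.0)

    def test_matches_window_enumeration_oracle(self, rng):
        mat = make_csf_matrix()
        for _ in range(25):
            n = int(rng.integers(95, 200))
            ref = "".join(rng.choice(list("ACGT"), size=n))
            other = "".join(
                b if rng.random() > 0.3 else str(rng.choice(list("ACGT")))
                for b in ref
            )
            got, _ = csf_score(ref, [other], mat)
            assert got == pytest.approx(csf_oracle(ref, [other], mat))

    def test_strand_symmetry(self, rng):
        from lincmir.seq import revcomp

        mat = make_csf_matrix()
        ref = "".join(rng.choice(list("ACGT"), size=150))
        other = "".join(rng.choice(list("ACGT"), size=150))
        fwd, _ = csf_score(ref, [other], mat)
        rev, _ = csf_score(revcomp(ref), [revcomp(other)], mat)
        assert fwd == pytest.approx(rev)

    def test_filter_strict_cutoff(self):
        regions = [
            CandidateRegion(iv(0, 100), csf_score=20.0),
            CandidateRegion(iv(200, 300), csf_score=20.0001),
        ]
        kept = csf_filter(regions, cutoff=20.0)
        assert [r.csf_score for r in kept] == [20.0]

    def test_filter_empty(self):
        assert csf_filter([], cutoff=20.0) == []


def test_planted_coding_regions_score_above_cutoff(small_truth):
    """The generator's synonymous-substitution pattern forces exclusion at
    the default cutoff, while noncoding regions stay below it."""
    mat = small_truth.csf_matrix
    for _, klass, name in small_truth.candidate_regions:
        ref, inf = small_truth.region_alignments[name]
        score, _ = csf_score(ref, [inf], mat)
        if klass == "coding":
            assert score > 20.0
        else:
            assert score <= 20.0
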