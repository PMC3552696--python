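"""Read counting and RPKM quantification per feature and sample.

A read counts toward a feature when any of its aligned blocks overlaps the
feature's exonic bases on the same strand; each read counts at most once
per feature, and a read overlapping two features counts for both (no
multi-mapping rescue).  RPKM divides the raw count by exonic length in kb
and library size in millions; the miRNA covariate used downstream is the
natural log of reads-per-million.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, SplicedAlignment, TranscriptModel

Feature = TranscriptModel | GenomicInterval


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    condition: int  # 0 = normal, 1 = tumor
    total_mapped: int

    def __post_init__(self) -> None:
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be positive")
        if self.condition not in (0, 1):
            raise ValueError("condition must be 0 (normal) or 1 (tumor)")


def _feature_exons(feature: Feature) -> tuple[str, str, list[GenomicInterval]]:
    if isinstance(feature, TranscriptModel):
        return feature.chrom, feature.strand, feature.exons
    return feature.chrom, feature.strand, [feature]


def exonic_length(feature: Feature) -> int:
    return sum(len(e) for e in _feature_exons(feature)[2])


def count_reads(alignments: list[SplicedAlignment], feature: Feature) -> int:
    """Reads whose blocks overlap the feature's exonic bases, same strand."""
    chrom, strand, exons = _feature_exons(feature)
    n = 0
    for aln in alignments:
        if aln.chrom != chrom:
            continue
        if strand in "+-" and aln.strand != strand:
            continue
        if any(b.start < e.end and e.start < b.end for b in aln.blocks for e in exons):
            n += 1
    return n


def count_matrix(
    alignments_by_sample: dict[str, list[SplicedAlignment]],
    features: dict[str, Feature],
) -> pd.DataFrame:
    """Raw count matrix (features x samples), strand-specific."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for fid, feature in features.items():
        chrom, strand, exons = _feature_exons(feature)
        key = (chrom, strand)
        tree = trees.setdefault(key, IntervalTree())
        for e in exons:
            tree.addi(e.start, e.end, fid)

    samples = list(alignments_by_sample)
    row = {fid: i for i, fid in enumerate(features)}
    mat = np.zeros((len(features), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        for aln in alignments_by_sample[sample]:
            hit: set[str] = set()
            for key in ((aln.chrom, aln.strand), (aln.chrom, ".")):
                tree = trees.get(key)
                if tree is None:
                    continue
                for b in aln.blocks:
                    for iv in tree.overlap(b.start, b.end):
                        hit.add(iv.data)
            for fid in hit:
                mat[row[fid], j] += 1
    return pd.DataFrame(mat, index=list(features), columns=samples)


def rpkm(raw_count: float, exonic_length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exonic_length_bp <= 0 or total_mapped <= 0:
        raise ValueError("exonic length and library size must be positive")
    return raw_count / (exonic_length_bp / 1000.0) / (total_mapped / 1e6)


def rpkm_matrix(
    counts: pd.DataFrame,
    features: dict[str, Feature],
    samples: list[SampleInfo],
) -> pd.DataFrame:
    lengths = pd.Series({fid: exonic_length(f) for fid, f in features.items()})
    totals = pd.Series({s.sample_id: s.total_mapped for s in samples})
    return counts.div(lengths / 1000.0, axis=0).div(totals[counts.columns] / 1e6, axis=1)


def ln_rpm(count: float, total_mapped: int) -> float:
    """Natural log of reads per million; requires a positive count."""
    if count <= 0:
        raise ValueError("ln RPM undefined for zero counts")
    return float(np.log(count / total_mapped * 1e6))


def detectability_filter(
    rpkm_df: pd.DataFrame,
    min_rpkm: float = 0.5,
    min_samples: int = 15,
) -> list[str]:
    """Features expressed above ``min_rpkm`` in strictly more than
    ``min_samples`` samples (both thresholds strict, matching the
    "more than 0.5 RPKM in more than 15 samples" rule)."""
    n_detected = (rpkm_df > min_rpkm).sum(axis=1)
    return list(rpkm_df.index[n_detected > min_samples])
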