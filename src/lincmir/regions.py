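"""Candidate lincRNA regions.

Chromatin-signature (K4-K36) regions from two genomes are merged, regions
near or overlapping known genes are dropped, and the survivors are filtered
by RNA-polymerase-II occupancy (RPKM of ChIP tags) and by coding potential
(codon-substitution-frequency score, a log-odds measure of protein-coding
evolutionary signature computed over 90-base windows in all six reading
frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, merge_intervals
from .seq import revcomp

GAP_CODON = "---"


@dataclass
class CandidateRegion:
    interval: GenomicInterval
    source: str = "human"  # {"human", "mouse_lifted"}
    rpolii_rpkm: float | None = None
    csf_score: float | None = None
    name: str = ""


# ---------------------------------------------------------------------------
# merge + gene exclusion


def merge_and_exclude(
    human: list[GenomicInterval],
    mouse_lifted: list[GenomicInterval],
    known_genes: list[GenomicInterval],
    min_gene_distance: int = 5000,
) -> list[CandidateRegion]:
    """Union of the two region sources minus anything near a known gene.

    A merged region is removed if it overlaps a gene or lies strictly closer
    than ``min_gene_distance`` bp to one; a gap of exactly
    ``min_gene_distance`` keeps the region.  Merged regions touching any
    human-source interval are tagged ``human``.
    """
    tagged = [(iv, "human") for iv in human] + [(iv, "mouse_lifted") for iv in mouse_lifted]
    merged = merge_intervals([iv for iv, _ in tagged])

    gene_trees: dict[str, IntervalTree] = {}
    for g in known_genes:
        # expand by the distance so half-open overlap == (gap < min_gene_distance)
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, g.start - min_gene_distance), g.end + min_gene_distance
        )

    human_trees: dict[str, IntervalTree] = {}
    for iv in human:
        human_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    out: list[CandidateRegion] = []
    for i, region in enumerate(merged):
        tree = gene_trees.get(region.chrom)
        if tree is not None and tree.overlap(region.start, region.end):
            continue
        htree = human_trees.get(region.chrom)
        source = "human" if htree is not None and htree.overlap(region.start, region.end) else "mouse_lifted"
        out.append(CandidateRegion(interval=region, source=source, name=f"region_{i}"))
    return out


# ---------------------------------------------------------------------------
# RPolII occupancy filter


def rpolii_rpkm(
    region: GenomicInterval, chip_tags: list[GenomicInterval], total_tags: int
) -> float:
    """ChIP tag density in RPKM; a tag is assigned by its 5' position."""
    if total_tags <= 0:
        raise ValueError("total_tags must be positive")
    n = 0
    for tag in chip_tags:
        five_prime = tag.end - 1 if tag.strand == "-" else tag.start
        if tag.chrom == region.chrom and region.start <= five_prime < region.end:
            n += 1
    return n / (len(region) / 1000.0) / (total_tags / 1e6)


def rpolii_filter(
    regions: list[CandidateRegion],
    chip_tags: list[GenomicInterval],
    total_tags: int,
    threshold: float = 0.1,
) -> list[CandidateRegion]:
    """Keep regions with tag density strictly above ``threshold`` RPKM."""
    # bucket tag 5' positions per chromosome once, then count per region
    positions: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[int]] = {}
    for tag in chip_tags:
        p = tag.end - 1 if tag.strand == "-" else tag.start
        by_chrom.setdefault(tag.chrom, []).append(p)
    for chrom, pos in by_chrom.items():
        positions[chrom] = np.sort(np.asarray(pos))
    if total_tags <= 0:
        raise ValueError("total_tags must be positive")

    kept = []
    for region in regions:
        pos = positions.get(region.interval.chrom)
        n = 0
        if pos is not None:
            n = int(
                np.searchsorted(pos, region.interval.end, "left")
                - np.searchsorted(pos, region.interval.start, "left")
            )
        region.rpolii_rpkm = n / (len(region.interval) / 1000.0) / (total_tags / 1e6)
        if region.rpolii_rpkm > threshold:
            kept.append(region)
    return kept


# ---------------------------------------------------------------------------
# CSF coding-potential score


def read_csf_matrix(path: str) -> pd.DataFrame:
    """Log-odds table indexed by reference codon, columns codon-or-gap."""
    return pd.read_csv(path, sep="\t", index_col=0)


def _frame_score_max(
    ref: str, others: list[str], matrix: pd.DataFrame, codons_per_window: int
) -> float:
    """Best window sum over the 3 forward frames of one orientation."""
    lut = {
        (r, c): float(matrix.at[r, c]) for r in matrix.index for c in matrix.columns
    }
    best = -np.inf
    L = len(ref)
    for offset in range(3):
        n_codons = (L - offset) // 3
        if n_codons < 1:
            continue
        col_scores = np.zeros(n_codons)
        for k in range(n_codons):
            i = offset + 3 * k
            rc = ref[i : i + 3]
            if "-" in rc:
                continue  # reference gap column carries no codon information
            total = 0.0
            for other in others:
                oc = other[i : i + 3]
                key = (rc, GAP_CODON if "-" in oc else oc)
                total += lut.get(key, 0.0)
            col_scores[k] = total / len(others)
        w = min(codons_per_window, n_codons)
        csum = np.concatenate([[0.0], np.cumsum(col_scores)])
        window_sums = csum[w:] - csum[:-w]
        best = max(best, float(window_sums.max()))
    return best


def csf_score(
    ref_aligned: str,
    others_aligned: list[str],
    matrix: pd.DataFrame,
    window: int = 90,
) -> tuple[float, bool]:
    """Maximum codon-substitution log-odds over all windows and six frames.

    ``ref_aligned``/``others_aligned`` are equal-length rows of a
    codon-resolved alignment (gaps as ``-``); scores are looked up as
    ``matrix[ref_codon, aligned_codon]`` and averaged over informant rows.
    A 90-base window slides in 3-base steps in each of 3 frame offsets x 2
    strands; the maximum window sum is the score.  Returns
    ``(score, short_flag)`` where ``short_flag`` marks regions shorter than
    one full window, scored over the single maximal in-frame stretch.
    """
    if any(len(o) != len(ref_aligned) for o in others_aligned):
        raise ValueError("alignment rows differ in length")
    if not others_aligned:
        raise ValueError("need at least one informant row")
    codons_per_window = window // 3
    short = len(ref_aligned) < window
    fwd = _frame_score_max(ref_aligned, others_aligned, matrix, codons_per_window)
    rev = _frame_score_max(
        revcomp(ref_aligned), [revcomp(o) for o in others_aligned], matrix, codons_per_window
    )
    return max(fwd, rev), short


def csf_filter(
    regions: list[CandidateRegion], cutoff: float = 20.0
) -> list[CandidateRegion]:
    """Drop regions whose CSF score is strictly above ``cutoff``."""
    return [
        r for r in regions if r.csf_score is None or not (r.csf_score > cutoff)
    ]
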