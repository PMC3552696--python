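"""Genomic coordinate primitives shared by every pipeline stage.

All coordinates are 0-based, half-open (``[start, end)``) in memory; BED
conventions apply only at file boundaries (see :mod:`lincmir.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contiguous genomic span.

    Parameters
    ----------
    chrom : str
        Reference sequence name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Gap between two intervals on the same chromosome (0 if they overlap)."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class SplicedAlignment:
    """One read's aligned blocks on the reference, as in a BED12 record."""

    read_id: str
    sample_id: str
    strand: str
    blocks: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("alignment needs at least one block")
        chroms = {b.chrom for b in self.blocks}
        if len(chroms) != 1:
            raise ValueError("alignment blocks span multiple chromosomes")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.end > b.start:
                raise ValueError("alignment blocks overlap or are unsorted")

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end


@dataclass
class TranscriptModel:
    """A spliced transcript: ordered, non-overlapping exons on one strand."""

    id: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.exons, self.exons[1:]):
            if a.chrom != b.chrom:
                raise ValueError("exons span multiple chromosomes")
            if a.end > b.start:
                raise ValueError("exons overlap or are unsorted")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def transcript_to_genomic(self, pos: int, length: int) -> list[GenomicInterval]:
        """Back-project a spliced-coordinate span onto genomic blocks.

        ``pos`` is a 0-based offset on the spliced *sense-strand* sequence;
        the projected span may cross exon junctions, in which case more than
        one block is returned (in genomic coordinate order).
        """
        if pos < 0 or length <= 0 or pos + length > self.spliced_length:
            raise ValueError("span outside transcript")
        # Sense coordinates run along genomic order on "+", reversed on "-".
        exons = self.exons if self.strand != "-" else list(reversed(self.exons))
        blocks: list[GenomicInterval] = []
        offset = 0
        remaining = length
        for exon in exons:
            elen = len(exon)
            if pos < offset + elen and remaining > 0:
                within = max(0, pos - offset)
                take = min(elen - within, remaining)
                if self.strand != "-":
                    g0 = exon.start + within
                    blocks.append(GenomicInterval(exon.chrom, g0, g0 + take, self.strand))
                else:
                    g1 = exon.end - within
                    blocks.append(GenomicInterval(exon.chrom, g1 - take, g1, self.strand))
                remaining -= take
                pos += take
            offset += elen
            if remaining == 0:
                break
        return sorted(blocks, key=lambda b: b.start)

    def spliced_sequence(self, genome: dict[str, str] | "object") -> str:
        """Sense-strand spliced sequence given a genome mapping chrom -> str."""
        from .seq import revcomp

        seq = "".join(str(genome[e.chrom][e.start : e.end]) for e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: merge all overlapping/adjacent spans per chromosome."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out.pop()
            out.append(
                GenomicInterval(last.chrom, last.start, max(last.end, iv.end), last.strand)
            )
        else:
            out.append(iv)
    return out
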