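"""Readers and writers for the on-disk formats the pipeline exchanges.

FASTA/FASTQ go through Biopython's SeqIO; newick trees through Bio.Phylo;
MAF blocks through Bio.AlignIO for reading.  BED6/BED12 are handled with
small pandas-backed helpers because no installed library round-trips the
BED12 block columns losslessly.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from Bio import AlignIO, Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, SplicedAlignment, TranscriptModel

# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in items),
        str(path),
        "fasta",
    )


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, bases, Sanger-scaled integer qualities) per read."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"])


def write_fastq(path: str | os.PathLike, reads: Iterable[tuple[str, str, list[int]]]) -> None:
    def _records():
        for rid, bases, quals in reads:
            rec = SeqRecord(Seq(bases), id=rid, description="")
            rec.letter_annotations["phred_quality"] = list(quals)
            yield rec

    SeqIO.write(_records(), str(path), "fastq")


# ---------------------------------------------------------------------------
# BED

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]
BED12_COLS = BED6_COLS + [
    "thickStart",
    "thickEnd",
    "itemRgb",
    "blockCount",
    "blockSizes",
    "blockStarts",
]


def read_bed6(path: str | os.PathLike) -> list[GenomicInterval]:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        strand = str(row[5]) if len(row) > 5 and str(row[5]) in "+-" else "."
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
    return out


def write_bed6(
    path: str | os.PathLike,
    intervals: Iterable[GenomicInterval],
    names: Iterable[str] | None = None,
) -> None:
    ivs = list(intervals)
    names = list(names) if names is not None else [f"iv{i}" for i in range(len(ivs))]
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ivs],
            "start": [iv.start for iv in ivs],
            "end": [iv.end for iv in ivs],
            "name": names,
            "score": 0,
            "strand": [iv.strand if iv.strand != "." else "." for iv in ivs],
        }
    )
    df.to_csv(str(path), sep="\t", header=False, index=False)


def _blocks_to_bed12(name: str, strand: str, blocks: list[GenomicInterval]) -> list:
    start = blocks[0].start
    end = blocks[-1].end
    sizes = ",".join(str(len(b)) for b in blocks)
    starts = ",".join(str(b.start - start) for b in blocks)
    return [blocks[0].chrom, start, end, name, 0, strand, start, end, "0", len(blocks), sizes, starts]


def _bed12_to_blocks(row) -> list[GenomicInterval]:
    chrom, start, strand = str(row[0]), int(row[1]), str(row[5])
    sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
    offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
    return [
        GenomicInterval(chrom, start + off, start + off + size, strand)
        for off, size in zip(offsets, sizes)
    ]


def write_alignments_bed12(path: str | os.PathLike, alignments: Iterable[SplicedAlignment]) -> None:
    rows = [
        _blocks_to_bed12(f"{a.sample_id}|{a.read_id}", a.strand, a.blocks) for a in alignments
    ]
    pd.DataFrame(rows, columns=BED12_COLS).to_csv(str(path), sep="\t", header=False, index=False)


def read_alignments_bed12(path: str | os.PathLike) -> list[SplicedAlignment]:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        name = str(row[3])
        sample_id, _, read_id = name.partition("|")
        out.append(
            SplicedAlignment(
                read_id=read_id or name,
                sample_id=sample_id if read_id else "",
                strand=str(row[5]),
                blocks=_bed12_to_blocks(row),
            )
        )
    return out


def write_transcripts_bed12(path: str | os.PathLike, transcripts: Iterable[TranscriptModel]) -> None:
    rows = [_blocks_to_bed12(t.id, t.strand, t.exons) for t in transcripts]
    pd.DataFrame(rows, columns=BED12_COLS).to_csv(str(path), sep="\t", header=False, index=False)


def read_transcripts_bed12(path: str | os.PathLike) -> list[TranscriptModel]:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    return [
        TranscriptModel(id=str(row[3]), strand=str(row[5]), exons=_bed12_to_blocks(row))
        for row in df.itertuples(index=False)
    ]


def write_transcripts_gtf(path: str | os.PathLike, transcripts: Iterable[TranscriptModel], source: str = "lincmir") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.id}"; transcript_id "{t.id}";'
            fh.write(
                "\t".join(
                    [t.chrom, source, "transcript", str(t.start + 1), str(t.end), ".", t.strand, ".", attrs]
                )
                + "\n"
            )
            for i, e in enumerate(t.exons, 1):
                fh.write(
                    "\t".join(
                        [t.chrom, source, "exon", str(e.start + 1), str(e.end), ".", t.strand, ".", attrs + f' exon_number "{i}";']
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# MAF + newick


def write_maf(
    path: str | os.PathLike,
    blocks: Iterable[tuple[int, dict[str, str]]],
    chrom: str,
    chrom_size: int,
    ref_taxon: str,
) -> None:
    """Write alignment blocks as MAF.

    Each block is ``(ref_start, {taxon: aligned_seq})``; the reference taxon
    row carries genome coordinates, other taxa are written with their own
    sequence as coordinate span (gapless simulation makes them congruent).
    """
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for ref_start, rows in blocks:
            fh.write("\na score=0.0\n")
            for taxon, seq in rows.items():
                ungapped = len(seq) - seq.count("-")
                start = ref_start if taxon == ref_taxon else 0
                src_size = chrom_size if taxon == ref_taxon else ungapped
                fh.write(
                    f"s {taxon}.{chrom} {start} {ungapped} + {src_size} {seq}\n"
                )


def read_maf(path: str | os.PathLike) -> list[tuple[int, dict[str, str]]]:
    """Read MAF blocks as ``(ref_start, {taxon: aligned_seq})``.

    The first row of each block is taken as the reference; taxon names are
    the MAF src with the trailing ``.chrom`` stripped.
    """
    blocks = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows: dict[str, str] = {}
        ref_start = None
        for rec in aln:
            taxon = rec.id.rsplit(".", 1)[0]
            rows[taxon] = str(rec.seq).upper()
            if ref_start is None:
                ref_start = int(rec.annotations["start"])
        blocks.append((ref_start, rows))
    return blocks


def read_tree(path: str | os.PathLike):
    return Phylo.read(str(path), "newick")


def write_tree(path: str | os.PathLike, tree) -> None:
    Phylo.write(tree, str(path), "newick")
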