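"""miRNA seed-match target prediction on spliced transcript sequences.

Canonical seed sites are searched anywhere on the mature (sense-strand)
transcript sequence:

* ``7mer-m8`` — the transcript carries the reverse complement of miRNA
  positions 2-8;
* ``7mer-A1`` — the reverse complement of positions 2-7, followed by an A
  on the transcript (opposite miRNA position 1);
* ``8mer`` — both at once.

Every occurrence is reported once with its most specific type (an 8mer is
not additionally counted as either 7mer).  All matching is done in the DNA
alphabet; U is normalized to T on input.  Sites are back-projected to
genomic blocks through the transcript's exon map and may cross junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval, TranscriptModel
from .seq import revcomp, rna_to_dna


@dataclass(frozen=True)
class MirnaRecord:
    id: str
    mature_seq: str  # DNA alphabet, 5'->3'

    def __post_init__(self) -> None:
        object.__setattr__(self, "mature_seq", rna_to_dna(self.mature_seq))
        if len(self.mature_seq) < 8:
            raise ValueError(f"mature miRNA {self.id} shorter than 8 nt")

    @property
    def seed(self) -> str:
        """Positions 2-7 (1-based) of the mature sequence."""
        return self.mature_seq[1:7]

    @property
    def extended_seed(self) -> str:
        """Positions 2-8 (1-based)."""
        return self.mature_seq[1:8]


@dataclass(frozen=True)
class SeedMatch:
    mirna_id: str
    lincrna_id: str
    site_type: str  # {"7mer-A1", "7mer-m8", "8mer"}
    transcript_pos: int
    length: int
    genomic_blocks: tuple[GenomicInterval, ...]


def _occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def predict_seed_matches(
    transcript: TranscriptModel,
    spliced_seq: str,
    mirnas: list[MirnaRecord],
) -> list[SeedMatch]:
    """All seed sites of every miRNA on one transcript's spliced sequence."""
    seq = rna_to_dna(spliced_seq)
    if len(seq) < 8:
        return []
    matches: list[SeedMatch] = []
    for mir in mirnas:
        m8_site = revcomp(mir.extended_seed)  # 7 nt
        a1_core = revcomp(mir.seed)  # 6 nt
        eightmer_starts = set()
        for p in _occurrences(seq, m8_site):
            if p + 7 < len(seq) and seq[p + 7] == "A":
                eightmer_starts.add(p)
                matches.append(_make(mir, transcript, "8mer", p, 8))
            else:
                matches.append(_make(mir, transcript, "7mer-m8", p, 7))
        for q in _occurrences(seq, a1_core + "A"):
            # a 7mer-A1 immediately 3' of a matched m8 base is the tail of
            # an 8mer; the most specific type already reported it
            if q - 1 in eightmer_starts:
                continue
            matches.append(_make(mir, transcript, "7mer-A1", q, 7))
    matches.sort(key=lambda m: (m.mirna_id, m.transcript_pos))
    return matches


def _make(mir, transcript, site_type, pos, length) -> SeedMatch:
    return SeedMatch(
        mirna_id=mir.id,
        lincrna_id=transcript.id,
        site_type=site_type,
        transcript_pos=pos,
        length=length,
        genomic_blocks=tuple(transcript.transcript_to_genomic(pos, length)),
    )


def upstream_control_sites(
    matches: list[SeedMatch],
    transcripts: dict[str, TranscriptModel],
    offset: int = 100,
) -> tuple[list[tuple[SeedMatch, tuple[GenomicInterval, ...]]], int]:
    """Length-matched control intervals ``offset`` bp 5' of each site.

    Controls are taken on the spliced transcript and back-projected to the
    genome; matches whose control would start before the transcript's 5'
    end are dropped, and the number dropped is returned alongside.
    """
    controls = []
    dropped = 0
    for m in matches:
        start = m.transcript_pos - offset
        if start < 0:
            dropped += 1
            continue
        tx = transcripts[m.lincrna_id]
        controls.append((m, tuple(tx.transcript_to_genomic(start, m.length))))
    return controls, dropped
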