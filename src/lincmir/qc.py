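"""Read-level quality control.

Three rules, applied in order to every raw read:

1. reads with more than ``n_max`` ambiguous bases (N/wildcards) are discarded;
2. scanning 5'->3', at the first ``window``-base window whose mean quality is
   strictly below ``min_avg_q`` the read is truncated at the window's first
   base (that base and everything 3' of it is removed);
3. reads shorter than ``min_len`` after truncation are discarded.

The window mean is compared with exact integer arithmetic
(``sum(quals) < min_avg_q * window``), so there is no floating-point
ambiguity at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

from . import io


@dataclass
class RawRead:
    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: bases/quals length mismatch")
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id}: negative quality")


class QcFate(str, Enum):
    KEPT = "kept"
    TRUNCATED = "truncated"
    DISCARDED_N = "discarded_n"
    DISCARDED_SHORT = "discarded_short"


def qc_filter(
    read: RawRead,
    n_max: int = 2,
    window: int = 5,
    min_avg_q: float = 20,
    min_len: int = 35,
) -> tuple[RawRead | None, QcFate]:
    """Apply the three QC rules; returns (surviving read or None, fate).

    A read shorter than ``window`` passes the sliding-window scan untruncated
    (there is no complete window to evaluate).
    """
    n_count = sum(1 for b in read.bases if b not in "ACGTacgt")
    if n_count > n_max:
        return None, QcFate.DISCARDED_N

    cut = len(read.bases)
    if len(read.quals) >= window:
        running = sum(read.quals[:window])
        threshold = min_avg_q * window
        for start in range(len(read.quals) - window + 1):
            if start > 0:
                running += read.quals[start + window - 1] - read.quals[start - 1]
            if running < threshold:
                cut = start
                break

    if cut < min_len:
        return None, QcFate.DISCARDED_SHORT
    if cut == len(read.bases):
        return read, QcFate.KEPT
    return RawRead(read.id, read.bases[:cut], read.quals[:cut]), QcFate.TRUNCATED


def qc_filter_file(
    fastq_in: str,
    fastq_out: str,
    tally_out: str | None = None,
    **params,
) -> dict[str, int]:
    """Filter a FASTQ file; returns (and optionally writes) the fate tally."""
    tally = {fate.value: 0 for fate in QcFate}

    def _survivors() -> Iterator[tuple[str, str, list[int]]]:
        for rid, bases, quals in io.read_fastq(fastq_in):
            kept, fate = qc_filter(RawRead(rid, bases, quals), **params)
            tally[fate.value] += 1
            if kept is not None:
                yield kept.id, kept.bases, kept.quals

    io.write_fastq(fastq_out, _survivors())
    if tally_out:
        with open(tally_out, "w") as fh:
            fh.write("fate\tcount\n")
            for fate, count in tally.items():
                fh.write(f"{fate}\t{count}\n")
    return tally


def qc_filter_reads(
    reads: Iterable[RawRead], **params
) -> tuple[list[RawRead], dict[str, int]]:
    """In-memory counterpart of :func:`qc_filter_file`."""
    tally = {fate.value: 0 for fate in QcFate}
    kept_reads: list[RawRead] = []
    for read in reads:
        kept, fate = qc_filter(read, **params)
        tally[fate.value] += 1
        if kept is not None:
            kept_reads.append(kept)
    return kept_reads, tally
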