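"""Independent brute-force oracles used to validate the optimized paths.

Each oracle restates its operation's contract as the most literal possible
enumeration, with no shared code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def qc_oracle(bases, quals, n_max=2, window=5, min_avg_q=20, min_len=35):
    """Literal restatement of the three read QC rules; returns kept prefix
    length, or None for a discarded read."""
    if sum(1 for b in bases if b.upper() not in "ACGT") > n_max:
        return None
    cut = len(bases)
    for start in range(len(quals) - window + 1):
        mean = Fraction(sum(quals[start : start + window]), window)
        if mean < min_avg_q:
            cut = start
            break
    if cut < min_len:
        return None
    return cut


def exon_call_oracle(block_list, region_start, region_end, min_reads=8, merge_gap=10):
    """Coverage scan by explicit per-base marking, then literal merging.

    ``block_list`` is [(start, end, read_id)] in genomic coordinates.
    Returns [(start, end, support)] in genomic coordinates.
    """
    length = region_end - region_start
    covered = [False] * length
    for s, e, _ in block_list:
        for p in range(max(s, region_start), min(e, region_end)):
            covered[p - region_start] = True
    runs = []
    i = 0
    while i < length:
        if covered[i]:
            j = i
            while j < length and covered[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    changed = True
    while changed:
        changed = False
        for k in range(len(runs) - 1):
            if runs[k + 1][0] - runs[k][1] < merge_gap:
                runs[k][1] = runs[k + 1][1]
                del runs[k + 1]
                changed = True
                break
    out = []
    for s, e in runs:
        gs, ge = s + region_start, e + region_start
        readers = {
            rid for (bs, be, rid) in block_list if max(bs, region_start) < ge and min(be, region_end) > gs
        }
        if len(readers) >= min_reads:
            out.append((gs, ge, len(readers)))
    return out


def junction_pairs_oracle(donor_positions, acceptor_positions, max_span=100_000, min_intron=70):
    """Every (donor, acceptor) pair satisfying both distance constraints."""
    return [
        (d, a)
        for d, a in itertools.product(donor_positions, acceptor_positions)
        if (a - d + 1) >= min_intron and (a - d) <= max_span
    ]


def junction_match_oracle(read_seq, entries, anchor=8, max_mismatch=2):
    """Exhaustive scan over entries and offsets; returns the winning
    junction index or None (no hit / ambiguous best)."""
    L = len(read_seq)
    hits = []
    for idx, (seq, joff) in enumerate(entries):
        for o in range(len(seq) - L + 1):
            if o > joff - anchor or o + L < joff + anchor:
                continue
            mm = sum(a != b for a, b in zip(read_seq, seq[o : o + L]))
            if mm <= max_mismatch:
                hits.append((idx, mm))
    if not hits:
        return None
    best = min(mm for _, mm in hits)
    winners = {idx for idx, mm in hits if mm == best}
    return winners.pop() if len(winners) == 1 else None


def seed_match_oracle(transcript_seq, mature_seq):
    """Naive O(L*len) substring scan for the three canonical site classes.

    Returns [(pos, type)] with the most specific type per occurrence.
    """
    seq = transcript_seq.upper().replace("U", "T")
    mat = mature_seq.upper().replace("U", "T")
    if len(seq) < 8:
        return []
    m8 = revcomp(mat[1:8])
    a1 = revcomp(mat[1:7]) + "A"
    out = []
    for p in range(len(seq) - 7 + 1):
        if seq[p : p + 7] == m8:
            if p + 8 <= len(seq) and seq[p + 7] == "A":
                out.append((p, "8mer"))
            else:
                out.append((p, "7mer-m8"))
    for p in range(len(seq) - 7 + 1):
        if seq[p : p + 7] == a1:
            if not (p >= 1 and (p - 1, "8mer") in out):
                out.append((p, "7mer-A1"))
    return sorted(out)


def bh_oracle(pvalues):
    """Textbook step-up adjusted p-values: q_(i) = min_{j>=i} m p_(j) / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        q[i] = running
    return q


def csf_oracle(ref, others, matrix, window=90):
    """Enumerate every window of every frame on both orientations."""

    def orient_score(r, os_):
        best = None
        n_codons_window = window // 3
        for offset in range(3):
            codons = [
                (r[i : i + 3], [o[i : i + 3] for o in os_])
                for i in range(offset, len(r) - 2, 3)
            ]
            if not codons:
                continue
            scores = []
            for rc, ocs in codons:
                if "-" in rc:
                    scores.append(0.0)
                    continue
                total = 0.0
                for oc in ocs:
                    col = "---" if "-" in oc else oc
                    total += float(matrix.at[rc, col])
                scores.append(total / len(ocs))
            w = min(n_codons_window, len(scores))
            for s in range(len(scores) - w + 1):
                val = sum(scores[s : s + w])
                best = val if best is None else max(best, val)
        return best

    rc_ref = revcomp_gapped(ref)
    rc_others = [revcomp_gapped(o) for o in others]
    cands = [orient_score(ref, others), orient_score(rc_ref, rc_others)]
    return max(c for c in cands if c is not None)


def revcomp_gapped(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "-": "-", "N": "N"}
    return "".join(comp[b] for b in reversed(seq.upper()))
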