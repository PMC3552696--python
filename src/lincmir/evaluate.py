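"""Truth-based evaluation of the discovery pipeline on simulated studies.

The generator's truth tables identify every planted object, so recovery can
be scored exactly: structure recovery compares assembled exon coordinates
with the planted transcripts; pair recovery scores the reverse-correlation
calls against the planted (lincRNA, miRNA) regulator pairs, counting a call
as true only when it names a planted pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import glm, quantify, simulate, targets
from .intervals import TranscriptModel


def structure_recovery(
    truth: simulate.SimulatedTruth, assembled: list[TranscriptModel]
) -> dict:
    """Fraction of planted multi-exon transcripts recovered exactly
    (identical exon coordinates and strand)."""
    asm = {tuple((e.start, e.end) for e in t.exons): t.strand for t in assembled}
    total = exact = 0
    for t in truth.lincrnas:
        if len(t.exons) < 2:
            continue
        total += 1
        key = tuple((e.start, e.end) for e in t.exons)
        if key in asm and asm[key] == t.strand:
            exact += 1
    return {"n_planted_multiexon": total, "n_recovered_exact": exact,
            "recovery_rate": exact / total if total else float("nan")}


def planted_site_recall(truth: simulate.SimulatedTruth) -> float:
    """Fraction of planted 8mer sites found by seed matching on the planted
    transcripts (sites are planted verbatim, so this should be 1.0)."""
    tx_by_id = {t.id: t for t in truth.lincrnas}
    mir_by_id = {m.id: m for m in truth.mirnas}
    found = 0
    for linc, mir, tpos, _ in truth.planted_sites:
        tx = tx_by_id[linc]
        seq = tx.spliced_sequence(truth.genome)
        hits = targets.predict_seed_matches(tx, seq, [mir_by_id[mir]])
        if any(h.site_type == "8mer" and h.transcript_pos == tpos for h in hits):
            found += 1
    return found / len(truth.planted_sites) if truth.planted_sites else float("nan")


def truth_pairs(truth: simulate.SimulatedTruth) -> list[tuple[str, str, str]]:
    """All candidate (target, miRNA) pairs from seed matching the planted
    transcripts and genes directly (bypassing assembly)."""
    pairs: set[tuple[str, str, str]] = set()
    for tx in truth.lincrnas:
        seq = tx.spliced_sequence(truth.genome)
        for m in targets.predict_seed_matches(tx, seq, truth.mirnas):
            pairs.add((m.lincrna_id, m.mirna_id, "lincrna"))
    for g in truth.known_genes:
        seq = g.spliced_sequence(truth.genome)
        for m in targets.predict_seed_matches(g, seq, truth.mirnas):
            pairs.add((m.lincrna_id, m.mirna_id, "gene"))
    return sorted(pairs)


def reverse_correlation_run(
    truth: simulate.SimulatedTruth,
    rng: np.random.Generator,
    pairs: list[tuple[str, str, str]] | None = None,
    fdr_cutoff: float = 0.2,
    alpha_interaction: float = 0.05,
) -> dict:
    """One expression replicate: simulate counts, fit all pairs, score calls.

    Works at the count level on the planted truth (no read placement), so
    replicates are cheap; measurement noise on the miRNA covariate is
    retained by recomputing ln RPM from the simulated pre-miRNA counts.
    """
    cfg = truth.cfg
    if pairs is None:
        pairs = truth_pairs(truth)
    counts, x1_true, _ = simulate.simulate_counts(cfg, truth, rng)
    samples = [
        quantify.SampleInfo(s, int(c), int(max(1, counts[s].sum())))
        for s, c in zip(truth.sample_ids, truth.conditions)
    ]
    totals = pd.Series({s.sample_id: s.total_mapped for s in samples})
    mir_ids = [m.id for m in truth.mirnas]
    mir_counts = counts.loc[mir_ids]
    usable = mir_counts.index[(mir_counts > 0).all(axis=1)]
    ln_rpm = np.log(mir_counts.loc[usable].div(totals[counts.columns], axis=1) * 1e6)
    pairs = [p for p in pairs if p[1] in set(usable)]

    table = glm.call_pairs(
        pairs, counts, ln_rpm, samples,
        alpha_interaction=alpha_interaction, fdr_cutoff=fdr_cutoff,
    )
    planted = set(truth.planted_pairs)
    table["is_planted"] = [
        (t, m) in planted for t, m in zip(table["target_id"], table["mirna_id"])
    ]
    called = table[table["reverse_correlated"]]
    tp = int(called["is_planted"].sum())
    fp = len(called) - tp
    return {
        "n_pairs": len(table),
        "n_called": len(called),
        "true_positives": tp,
        "false_positives": fp,
        "n_planted": len(planted),
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "empirical_fdr": fp / len(called) if len(called) else 0.0,
        "table": table,
    }


def reverse_correlation_benchmark(
    truth: simulate.SimulatedTruth,
    n_runs: int = 20,
    seed: int = 0,
    fdr_cutoff: float = 0.2,
) -> dict:
    """Pooled sensitivity and empirical FDR over seeded expression replicates."""
    pairs = truth_pairs(truth)
    tp = fp = planted = 0
    per_run = []
    for r in range(n_runs):
        rng = np.random.default_rng(seed + 1000 + r)
        res = reverse_correlation_run(truth, rng, pairs=pairs, fdr_cutoff=fdr_cutoff)
        tp += res["true_positives"]
        fp += res["false_positives"]
        planted += res["n_planted"]
        per_run.append({k: res[k] for k in ("sensitivity", "empirical_fdr", "n_called")})
    n_called = tp + fp
    return {
        "n_runs": n_runs,
        "pooled_sensitivity": tp / planted if planted else float("nan"),
        "pooled_empirical_fdr": fp / n_called if n_called else 0.0,
        "per_run": per_run,
    }
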