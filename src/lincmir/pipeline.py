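"""End-to-end orchestration of the discovery pipeline over a work directory.

Each stage reads only the files earlier stages wrote and writes only its
own declared outputs, so stages are independently runnable (and are exposed
one-to-one as CLI subcommands).  The final report's funnel counts are all
recomputable from the persisted stage outputs.

Work directory layout::

    inputs/          simulated study inputs (genome, annotations, reads, MAF)
    qc/              filtered junction-read pool + per-sample tally
    regions/         candidate regions surviving each filter + scores
    assembly/        assembled lincRNA models + junction table
    targets/         predicted seed sites, pairs, upstream controls
    quantify/        count and RPKM matrices, detectable feature list
    glm/             per-pair fits and calls
    conservation/    per-site omega estimates and rank-test report
    report.json      the funnel
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, conservation, glm, io, qc, quantify, regions, simulate, targets
from .intervals import GenomicInterval, TranscriptModel


@dataclass
class PipelineParams:
    """Every stage threshold, with the published defaults."""

    min_gene_distance: int = 5000
    rpolii_threshold: float = 0.1
    csf_cutoff: float = 20.0
    csf_window: int = 90
    min_reads: int = 8
    merge_gap: int = 10
    splice_search: int = 25
    max_span: int = 100_000
    min_intron: int = 70
    junction_anchor: int = 8
    junction_max_mismatch: int = 2
    min_lincrna_length: int = 200
    min_rpkm: float = 0.5
    min_samples: int = 15
    alpha_interaction: float = 0.05
    fdr_cutoff: float = 0.2

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")


def _inputs(workdir: Path) -> Path:
    return Path(workdir) / "inputs"


# ---------------------------------------------------------------------------
# stages


def stage_simulate(workdir: str | Path, cfg: simulate.SimulationConfig) -> simulate.SimulatedTruth:
    work = Path(workdir)
    indir = _inputs(work)
    truth = simulate.simulate_genome(cfg)
    reads = simulate.simulate_reads(cfg, truth)
    maf_blocks, newick = simulate.simulate_maf(cfg, truth)
    simulate.write_truth(truth, indir)
    simulate.write_reads(reads, indir / "reads")
    io.write_maf(
        indir / "alignment.maf", maf_blocks, cfg.chrom, cfg.genome_length, ref_taxon="ref"
    )
    (indir / "tree.nwk").write_text(newick + "\n")
    return truth


def stage_qc(workdir: str | Path, params: PipelineParams | None = None) -> dict:
    work = Path(workdir)
    outdir = work / "qc"
    outdir.mkdir(parents=True, exist_ok=True)
    samples = pd.read_csv(_inputs(work) / "reads" / "samples.tsv", sep="\t")
    totals = {}
    for sample in samples["sample_id"]:
        tally = qc.qc_filter_file(
            str(_inputs(work) / "reads" / f"{sample}.unmapped.fastq"),
            str(outdir / f"{sample}.filtered.fastq"),
            str(outdir / f"{sample}.tally.tsv"),
        )
        totals[sample] = tally
    summary = pd.DataFrame(totals).T
    summary.index.name = "sample_id"
    summary.to_csv(outdir / "tally.tsv", sep="\t")
    return totals


def stage_regions(workdir: str | Path, params: PipelineParams) -> dict:
    work = Path(workdir)
    indir = _inputs(work)
    outdir = work / "regions"
    outdir.mkdir(parents=True, exist_ok=True)

    cand = pd.read_csv(indir / "candidate_regions.bed", sep="\t", header=None)
    intervals = [
        (GenomicInterval(r[0], int(r[1]), int(r[2])), str(r[3]))
        for r in cand.itertuples(index=False)
    ]
    # the two K4-K36 sources arrive pre-merged in the simulated input; split
    # them alternately so the union step is exercised end to end
    human = [iv for i, (iv, _) in enumerate(intervals) if i % 2 == 0]
    mouse = [iv for i, (iv, _) in enumerate(intervals) if i % 2 == 1]
    name_of = {(iv.chrom, iv.start, iv.end): name for iv, name in intervals}
    genes = io.read_bed6(indir / "known_genes.bed")

    merged = regions.merge_and_exclude(human, mouse, genes, params.min_gene_distance)
    for region in merged:
        key = (region.interval.chrom, region.interval.start, region.interval.end)
        region.name = name_of.get(key, region.name)
    n_after_genes = len(merged)

    chip = io.read_bed6(indir / "chip_tags.bed")
    occupied = regions.rpolii_filter(
        merged, chip, total_tags=len(chip), threshold=params.rpolii_threshold
    )
    n_after_rpolii = len(occupied)

    matrix = regions.read_csf_matrix(str(indir / "csf_matrix.tsv"))
    aln = io.read_fasta(indir / "region_alignments.fa")
    scores = []
    for region in occupied:
        ref = aln.get(f"{region.name}|ref")
        inf = aln.get(f"{region.name}|informant")
        if ref is None or inf is None:
            region.csf_score = None
            continue
        score, short = regions.csf_score(ref, [inf], matrix, window=params.csf_window)
        region.csf_score = score
        scores.append((region.name, score, short))
    kept = regions.csf_filter(occupied, cutoff=params.csf_cutoff)

    pd.DataFrame(scores, columns=["region", "csf_score", "short_flag"]).to_csv(
        outdir / "csf_scores.tsv", sep="\t", index=False
    )
    io.write_bed6(
        outdir / "kept_regions.bed",
        [r.interval for r in kept],
        [r.name for r in kept],
    )
    pd.DataFrame(
        [(r.name, r.source, r.rpolii_rpkm, r.csf_score) for r in kept],
        columns=["region", "source", "rpolii_rpkm", "csf_score"],
    ).to_csv(outdir / "kept_regions.tsv", sep="\t", index=False)
    return {
        "n_candidate_regions": len(intervals),
        "n_after_gene_exclusion": n_after_genes,
        "n_after_rpolii": n_after_rpolii,
        "n_after_csf": len(kept),
    }


def _load_alignments(workdir: Path) -> dict[str, list]:
    samples = pd.read_csv(_inputs(workdir) / "reads" / "samples.tsv", sep="\t")
    return {
        s: io.read_alignments_bed12(_inputs(workdir) / "reads" / f"{s}.aligned.bed12")
        for s in samples["sample_id"]
    }


def stage_assembly(workdir: str | Path, params: PipelineParams) -> dict:
    work = Path(workdir)
    outdir = work / "assembly"
    outdir.mkdir(parents=True, exist_ok=True)
    genome = io.read_fasta(_inputs(work) / "genome.fa")
    kept = io.read_bed6(work / "regions" / "kept_regions.bed")
    kept_names = pd.read_csv(
        work / "regions" / "kept_regions.bed", sep="\t", header=None
    )[3].astype(str).tolist()

    alignments_by_sample = _load_alignments(work)
    pooled = [a for alns in alignments_by_sample.values() for a in alns]
    # index pooled alignments by start for fast per-region slicing
    pooled.sort(key=lambda a: (a.chrom, a.start))
    starts = np.array([a.start for a in pooled])

    qc_dir = work / "qc"
    junction_pool: list[tuple[str, str]] = []
    for f in sorted(qc_dir.glob("*.filtered.fastq")):
        for rid, bases, _ in io.read_fastq(f):
            junction_pool.append((rid, bases))

    read_len = max((len(b) for _, b in junction_pool), default=50)
    flank = read_len - 1

    transcripts: list[TranscriptModel] = []
    junction_rows = []
    for region, rname in zip(kept, kept_names):
        lo = int(np.searchsorted(starts, region.start - 10000))
        hi = int(np.searchsorted(starts, region.end))
        local = [a for a in pooled[lo:hi] if a.end > region.start and a.start < region.end]
        exons = assembly.call_putative_exons(
            local, region, min_reads=params.min_reads, merge_gap=params.merge_gap
        )
        if not exons:
            continue
        chrom_seq = genome[region.chrom]
        donors, acceptors = [], []
        for i, exon in enumerate(exons):
            d, a = assembly.find_splice_sites(chrom_seq, exon, i, search=params.splice_search)
            donors.extend(d)
            acceptors.extend(a)
        library = assembly.build_junction_library(
            donors, acceptors, chrom_seq, flank=flank,
            max_span=params.max_span, min_intron=params.min_intron,
        )
        support = assembly.match_junction_reads(
            junction_pool, library,
            anchor=params.junction_anchor, max_mismatch=params.junction_max_mismatch,
        )
        models = assembly.assemble_transcripts(
            exons, support, id_prefix=f"cand_{rname}"
        )
        for m in models:
            if m.spliced_length >= params.min_lincrna_length:
                m.id = f"linc.{rname}.{len(transcripts)}"
                transcripts.append(m)
        for j, s in support.items():
            junction_rows.append(
                (rname, j.donor_pos, j.acceptor_pos, j.strand, j.motif, s)
            )

    io.write_transcripts_bed12(outdir / "lincrnas.bed12", transcripts)
    io.write_transcripts_gtf(outdir / "lincrnas.gtf", transcripts)
    pd.DataFrame(
        junction_rows,
        columns=["region", "donor_pos", "acceptor_pos", "strand", "motif", "support"],
    ).to_csv(outdir / "junctions.tsv", sep="\t", index=False)
    return {
        "n_assembled_lincrnas": len(transcripts),
        "n_multi_exon": sum(1 for t in transcripts if len(t.exons) > 1),
    }


def stage_targets(workdir: str | Path, params: PipelineParams) -> dict:
    work = Path(workdir)
    outdir = work / "targets"
    outdir.mkdir(parents=True, exist_ok=True)
    genome = io.read_fasta(_inputs(work) / "genome.fa")
    lincs = io.read_transcripts_bed12(work / "assembly" / "lincrnas.bed12")
    genes_bed = pd.read_csv(_inputs(work) / "known_genes.bed", sep="\t", header=None)
    genes = [
        TranscriptModel(
            id=str(r[3]),
            strand=str(r[5]),
            exons=[GenomicInterval(str(r[0]), int(r[1]), int(r[2]), str(r[5]))],
        )
        for r in genes_bed.itertuples(index=False)
    ]
    mirnas = [
        targets.MirnaRecord(id=name, mature_seq=seq)
        for name, seq in io.read_fasta(_inputs(work) / "mirnas_mature.fa").items()
    ]

    rows = []
    all_transcripts = {t.id: t for t in lincs + genes}
    linc_matches = []
    for family, txs in (("lincrna", lincs), ("gene", genes)):
        for tx in txs:
            seq = tx.spliced_sequence(genome)
            matches = targets.predict_seed_matches(tx, seq, mirnas)
            if family == "lincrna":
                linc_matches.extend(matches)
            for m in matches:
                blocks = ";".join(f"{b.start}-{b.end}" for b in m.genomic_blocks)
                rows.append(
                    (m.mirna_id, m.lincrna_id, family, m.site_type, m.transcript_pos,
                     m.genomic_blocks[0].chrom, blocks, m.genomic_blocks[0].strand)
                )
    sites = pd.DataFrame(
        rows,
        columns=["mirna", "target", "family", "type", "transcript_pos", "chrom", "blocks", "strand"],
    )
    sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)

    pairs = sites[["target", "mirna", "family"]].drop_duplicates()
    pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)

    controls, dropped = targets.upstream_control_sites(
        linc_matches, {t.id: t for t in lincs}
    )
    ctrl_rows = [
        (m.mirna_id, m.lincrna_id, m.transcript_pos,
         blocks[0].chrom, ";".join(f"{b.start}-{b.end}" for b in blocks), blocks[0].strand)
        for m, blocks in controls
    ]
    pd.DataFrame(
        ctrl_rows,
        columns=["mirna", "target", "site_transcript_pos", "chrom", "blocks", "strand"],
    ).to_csv(outdir / "upstream_controls.tsv", sep="\t", index=False)
    return {
        "n_predicted_sites": len(sites),
        "n_lincrna_sites": int((sites["family"] == "lincrna").sum()),
        "n_predicted_pairs": len(pairs),
        "n_lincrna_pairs": int((pairs["family"] == "lincrna").sum()),
        "n_controls_dropped": dropped,
    }


def stage_quantify(workdir: str | Path, params: PipelineParams) -> dict:
    work = Path(workdir)
    outdir = work / "quantify"
    outdir.mkdir(parents=True, exist_ok=True)

    lincs = io.read_transcripts_bed12(work / "assembly" / "lincrnas.bed12")
    genes_bed = pd.read_csv(_inputs(work) / "known_genes.bed", sep="\t", header=None)
    premir_bed = pd.read_csv(_inputs(work) / "pre_mirnas.bed", sep="\t", header=None)
    features: dict[str, quantify.Feature] = {}
    for r in genes_bed.itertuples(index=False):
        features[str(r[3])] = GenomicInterval(str(r[0]), int(r[1]), int(r[2]), str(r[5]))
    for t in lincs:
        features[t.id] = t
    for r in premir_bed.itertuples(index=False):
        features[str(r[3])] = GenomicInterval(str(r[0]), int(r[1]), int(r[2]), str(r[5]))

    alignments_by_sample = _load_alignments(work)
    sheet = pd.read_csv(_inputs(work) / "reads" / "samples.tsv", sep="\t")
    samples = [
        quantify.SampleInfo(str(r.sample_id), int(r.condition), int(r.total_mapped))
        for r in sheet.itertuples(index=False)
    ]

    counts = quantify.count_matrix(alignments_by_sample, features)
    rpkms = quantify.rpkm_matrix(counts, features, samples)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    rpkms.to_csv(outdir / "rpkm.tsv", sep="\t")

    detectable = quantify.detectability_filter(
        rpkms, min_rpkm=params.min_rpkm, min_samples=params.min_samples
    )
    (outdir / "detectable.txt").write_text("\n".join(detectable) + "\n")

    premir_ids = [str(r[3]) for r in premir_bed.itertuples(index=False)]
    linc_ids = [t.id for t in lincs]
    return {
        "n_detectable_lincrnas": sum(1 for f in detectable if f in set(linc_ids)),
        "n_detectable_mirnas": sum(1 for f in detectable if f in set(premir_ids)),
        "n_detectable_total": len(detectable),
    }


def stage_glm(workdir: str | Path, params: PipelineParams) -> dict:
    work = Path(workdir)
    outdir = work / "glm"
    outdir.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(work / "quantify" / "counts.tsv", sep="\t", index_col=0)
    detectable = set(
        (work / "quantify" / "detectable.txt").read_text().split()
    )
    pairs_df = pd.read_csv(work / "targets" / "pairs.tsv", sep="\t")
    sheet = pd.read_csv(_inputs(work) / "reads" / "samples.tsv", sep="\t")
    samples = [
        quantify.SampleInfo(str(r.sample_id), int(r.condition), int(r.total_mapped))
        for r in sheet.itertuples(index=False)
    ]
    sample_ids = [s.sample_id for s in samples]

    # miRNA ln RPM covariate from the quantified pre-miRNA counts
    premir_bed = pd.read_csv(_inputs(work) / "pre_mirnas.bed", sep="\t", header=None)
    premir_ids = [str(r[3]) for r in premir_bed.itertuples(index=False)]
    totals = pd.Series({s.sample_id: s.total_mapped for s in samples})
    mir_counts = counts.loc[[m for m in premir_ids if m in counts.index], sample_ids]
    usable_mirs = mir_counts.index[(mir_counts > 0).all(axis=1)]
    ln_rpm = np.log(mir_counts.loc[usable_mirs].div(totals[sample_ids], axis=1) * 1e6)

    eligible = []
    for r in pairs_df.itertuples(index=False):
        if (
            r.target in detectable
            and r.mirna in detectable
            and r.mirna in set(usable_mirs)
            and r.target in counts.index
        ):
            eligible.append((str(r.target), str(r.mirna), str(r.family)))

    table = glm.call_pairs(
        eligible, counts, ln_rpm, samples,
        alpha_interaction=params.alpha_interaction,
        fdr_cutoff=params.fdr_cutoff,
    )
    table.to_csv(outdir / "pair_calls.tsv", sep="\t", index=False)
    if table.empty:
        return {"n_eligible_pairs": 0, "n_reverse_correlated_lincrna": 0,
                "n_reverse_correlated_gene": 0, "n_condition_specific": 0}
    linc_mask = table["family"] == "lincrna"
    return {
        "n_eligible_pairs": len(table),
        "n_reverse_correlated_lincrna": int(table.loc[linc_mask, "reverse_correlated"].sum()),
        "n_reverse_correlated_gene": int(table.loc[~linc_mask, "reverse_correlated"].sum()),
        "n_condition_specific": int(table["condition_specific"].sum()),
    }


def stage_conservation(workdir: str | Path, params: PipelineParams) -> dict:
    work = Path(workdir)
    outdir = work / "conservation"
    outdir.mkdir(parents=True, exist_ok=True)

    maf_blocks = io.read_maf(_inputs(work) / "alignment.maf")
    tree = io.read_tree(_inputs(work) / "tree.nwk")
    sites = pd.read_csv(work / "targets" / "sites.tsv", sep="\t")
    controls = pd.read_csv(work / "targets" / "upstream_controls.tsv", sep="\t")
    calls = pd.read_csv(work / "glm" / "pair_calls.tsv", sep="\t")

    called = set(
        calls.loc[calls["reverse_correlated"] == True, "pair_id"]  # noqa: E712
    )

    def site_omega(blocks_str: str) -> float:
        rows_parts: dict[str, list[str]] = {}
        for part in blocks_str.split(";"):
            s, e = part.split("-")
            rows = simulate.extract_alignment(maf_blocks, int(s), int(e))
            for t, seq in rows.items():
                rows_parts.setdefault(t, []).append(seq)
        merged = {t: "".join(p) for t, p in rows_parts.items()}
        return conservation.estimate_omega(merged, tree).omega

    linc_sites = sites[sites["family"] == "lincrna"].copy()
    linc_sites["pair_id"] = linc_sites["target"] + "|" + linc_sites["mirna"]
    linc_sites["omega"] = [site_omega(b) for b in linc_sites["blocks"]]
    linc_sites["correlated"] = linc_sites["pair_id"].isin(called)
    linc_sites.to_csv(outdir / "site_omega.tsv", sep="\t", index=False)

    ctrl_key = controls.set_index(
        ["target", "mirna", "site_transcript_pos"]
    )["blocks"]
    corr = linc_sites[linc_sites["correlated"]]
    paired_site, paired_up = [], []
    for r in corr.itertuples(index=False):
        key = (r.target, r.mirna, r.transcript_pos)
        if key in ctrl_key.index:
            paired_site.append(r.omega)
            paired_up.append(site_omega(ctrl_key.loc[key]))

    report = conservation.compare_site_conservation(
        corr["omega"].tolist(),
        linc_sites.loc[~linc_sites["correlated"], "omega"].tolist(),
        paired_up if paired_up else None,
        omega_correlated_paired=paired_site if paired_up else None,
    )
    if paired_up:
        report["n_paired_upstream"] = len(paired_up)

    # polymerase occupancy vs expression, Spearman (generic correlation op)
    kept = pd.read_csv(work / "regions" / "kept_regions.tsv", sep="\t")
    rpkms = pd.read_csv(work / "quantify" / "rpkm.tsv", sep="\t", index_col=0)
    lincs = io.read_transcripts_bed12(work / "assembly" / "lincrnas.bed12")
    region_of = {t.id: t.id.split(".")[1] for t in lincs}
    occ = kept.set_index("region")["rpolii_rpkm"]
    xs, ys = [], []
    for t in lincs:
        rname = region_of[t.id]
        if rname in occ.index and t.id in rpkms.index:
            xs.append(float(occ.loc[rname]))
            ys.append(float(rpkms.loc[t.id].mean()))
    if len(xs) >= 5:
        rho, p = conservation.rank_correlation(xs, ys)
        report["rpolii_expression_spearman_rho"] = rho
        report["rpolii_expression_spearman_p"] = p

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_pipeline(
    workdir: str | Path,
    sim_cfg: simulate.SimulationConfig | None = None,
    params: PipelineParams | None = None,
) -> dict:
    """Run every stage in order; returns the funnel report (also persisted)."""
    work = Path(workdir)
    work.mkdir(parents=True, exist_ok=True)
    sim_cfg = sim_cfg or simulate.SimulationConfig()
    params = params or PipelineParams()
    params.validate()

    report: dict = {"seed": sim_cfg.seed, "params": dataclasses.asdict(params)}
    stage_simulate(work, sim_cfg)
    report["qc"] = {
        fate: int(sum(t[fate] for t in stage_qc(work).values()))
        for fate in ("kept", "truncated", "discarded_n", "discarded_short")
    }
    report.update(stage_regions(work, params))
    report.update(stage_assembly(work, params))
    report.update(stage_targets(work, params))
    report.update(stage_quantify(work, params))
    report.update(stage_glm(work, params))
    report["conservation"] = stage_conservation(work, params)

    with open(work / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
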