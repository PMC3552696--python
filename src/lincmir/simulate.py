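"""Synthetic study generator.

Emits every input the discovery pipeline consumes — a toy genome, known
genes, chromatin-signature candidate regions, strand-specific spliced read
alignments for a normal/tumor cohort, pre-miRNA counts and mature miRNA
sequences, polymerase ChIP tags, codon-alignment material for coding-
potential scoring, and a multi-species alignment with its tree — with the
statistical structure the downstream analysis assumes:

* planted multi-exon lincRNA transcripts inside truly intergenic candidate
  regions, with canonical splice motifs (GT..AG / CT..AC on the reference);
* candidate regions to be removed downstream: near known genes, with a
  planted protein-coding substitution pattern, or transcriptionally silent;
* miRNA -> lincRNA repression for a configurable set of planted pairs: the
  target's counts follow the log-link count model
  ln E[y] = b0 + b1*x1 + b2*x2 + b3*x1*x2 + ln(depth factor)
  with negative-binomial noise of variance phi*mu (the moment-matched
  realization of quasi-Poisson overdispersion), where x1 is the miRNA's
  per-sample ln RPM (shared across all of that miRNA's targets) and x2 the
  tumor indicator; an 8mer seed site of the miRNA is planted verbatim in
  the target's exonic sequence;
* elevated conservation (rate multiplier ``omega_conserved`` < 1) at the
  planted seed sites in the multi-species alignment, neutral elsewhere.

Everything is deterministic under a fixed seed.  Truth tables record every
planted object so downstream sensitivity/FDR can be computed exactly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Phylo
from Bio.Data import CodonTable

from . import io
from .intervals import GenomicInterval, SplicedAlignment, TranscriptModel
from .qc import RawRead
from .seq import revcomp
from .targets import MirnaRecord

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    seed: int = 0
    n_normal: int = 10
    n_tumor: int = 10
    genome_length: int = 600_000
    n_known_genes: int = 8
    n_candidate_regions: int = 50
    n_true_lincrnas: int = 30
    n_near_gene_regions: int = 8
    n_coding_regions: int = 5
    n_mirnas: int = 12
    n_planted_pairs: int = 10
    beta: tuple[float, float, float, float] = (2.0, -0.8, 0.3, 0.0)
    dispersion: float = 1.5
    read_length: int = 50
    mean_depth: int = 15_000
    n_species: int = 5
    omega_conserved: float = 0.2
    omega_background: float = 1.0
    x1_mu_range: tuple[float, float] = (8.0, 9.5)
    x1_sigma: float = 1.0
    beta2_sd: float = 0.2
    qc_defect_fraction: float = 0.02
    informant_sub_rate: float = 0.4
    min_gene_distance: int = 5000
    chrom: str = "chr1"

    def validate(self) -> None:
        if self.n_normal + self.n_tumor < 4:
            raise ValueError("need at least 4 samples")
        if self.n_true_lincrnas + self.n_near_gene_regions + self.n_coding_regions > self.n_candidate_regions:
            raise ValueError("candidate region classes exceed n_candidate_regions")
        if self.n_true_lincrnas > self.n_candidate_regions:
            raise ValueError("more planted lincRNAs than candidate regions")
        if self.n_planted_pairs > self.n_true_lincrnas:
            raise ValueError("more planted pairs than planted lincRNAs")
        if self.dispersion < 1:
            raise ValueError("dispersion must be >= 1 (quasi-Poisson)")
        if not (self.omega_conserved < self.omega_background):
            raise ValueError("omega_conserved must be < omega_background")
        if self.n_species < 2:
            raise ValueError("need at least 2 species for an alignment")


@dataclass
class SimulatedTruth:
    cfg: SimulationConfig
    genome: dict[str, str]
    known_genes: list[TranscriptModel]
    candidate_regions: list[tuple[GenomicInterval, str, str]]  # (iv, class, name)
    lincrnas: list[TranscriptModel]
    lincrna_region: dict[str, str]  # lincrna id -> region name
    pre_mirnas: dict[str, GenomicInterval]
    mirnas: list[MirnaRecord]
    planted_pairs: list[tuple[str, str]]  # (lincrna_id, mirna_id)
    planted_sites: list[tuple[str, str, int, tuple[GenomicInterval, ...]]]
    chip_tags: list[GenomicInterval]
    region_alignments: dict[str, tuple[str, str]]  # region -> (ref, informant)
    csf_matrix: pd.DataFrame
    x1_mu: np.ndarray
    gene_beta2: dict[str, float]
    baselines: dict[str, float]

    @property
    def sample_ids(self) -> list[str]:
        return [f"normal_{i}" for i in range(self.cfg.n_normal)] + [
            f"tumor_{i}" for i in range(self.cfg.n_tumor)
        ]

    @property
    def conditions(self) -> np.ndarray:
        return np.array([0] * self.cfg.n_normal + [1] * self.cfg.n_tumor)

    def features(self) -> dict[str, TranscriptModel | GenomicInterval]:
        out: dict[str, TranscriptModel | GenomicInterval] = {}
        for g in self.known_genes:
            out[g.id] = g
        for t in self.lincrnas:
            out[t.id] = t
        for mid, iv in self.pre_mirnas.items():
            out[mid] = iv
        return out

    def mirna_of_lincrna(self) -> dict[str, str]:
        return {linc: mir for linc, mir in self.planted_pairs}


# ---------------------------------------------------------------------------
# CSF scoring material


def make_csf_matrix() -> pd.DataFrame:
    """Synonymous-substitution log-odds table: +1 for codon pairs encoding
    the same amino acid (identity included), -1 otherwise and for gaps."""
    table = CodonTable.unambiguous_dna_by_id[1]
    codons = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]

    def aa(codon: str) -> str:
        return "*" if codon in table.stop_codons else table.forward_table[codon]

    cols = codons + ["---"]
    mat = pd.DataFrame(-1.0, index=codons, columns=cols)
    for r in codons:
        for c in codons:
            if aa(r) == aa(c):
                mat.at[r, c] = 1.0
    return mat


_SYNONYMS: dict[str, list[str]] = {}


def _synonyms(codon: str) -> list[str]:
    if not _SYNONYMS:
        table = CodonTable.unambiguous_dna_by_id[1]
        by_aa: dict[str, list[str]] = {}
        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    cod = a + b + c
                    key = "*" if cod in table.stop_codons else table.forward_table[cod]
                    by_aa.setdefault(key, []).append(cod)
        for cods in by_aa.values():
            for cod in cods:
                _SYNONYMS[cod] = [x for x in cods if x != cod]
    return _SYNONYMS[codon]


# ---------------------------------------------------------------------------
# genome and annotation


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def simulate_genome(cfg: SimulationConfig) -> SimulatedTruth:
    """Lay out genes, candidate regions, planted transcripts and miRNAs."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome = _random_seq(rng, cfg.genome_length)
    margin = cfg.min_gene_distance + 1000
    cursor = 1000

    def advance(length: int) -> int:
        nonlocal cursor
        start = cursor
        cursor += length
        if cursor > cfg.genome_length - 1000:
            raise ValueError(
                f"genome_length={cfg.genome_length} too short for the requested features"
            )
        return start

    known_genes: list[TranscriptModel] = []
    candidate_regions: list[tuple[GenomicInterval, str, str]] = []
    region_counter = 0

    def new_region(iv: GenomicInterval, klass: str) -> str:
        nonlocal region_counter
        name = f"region_{region_counter}"
        region_counter += 1
        candidate_regions.append((iv, klass, name))
        return name

    # genes, with near-gene candidate regions attached to the first few
    for gi in range(cfg.n_known_genes):
        glen = int(rng.integers(1500, 3000))
        gstart = advance(glen)
        strand = "+" if rng.random() < 0.5 else "-"
        known_genes.append(
            TranscriptModel(
                id=f"gene_{gi}",
                strand=strand,
                exons=[GenomicInterval(cfg.chrom, gstart, gstart + glen, strand)],
            )
        )
        if gi < cfg.n_near_gene_regions:
            gap = int(rng.integers(200, cfg.min_gene_distance - 500))
            rlen = int(rng.integers(2000, 4000))
            rstart = advance(gap + rlen) + gap
            new_region(GenomicInterval(cfg.chrom, rstart, rstart + rlen), "near_gene")
        advance(margin)

    # intergenic candidate regions with planted lincRNAs
    lincrnas: list[TranscriptModel] = []
    lincrna_region: dict[str, str] = {}
    for li in range(cfg.n_true_lincrnas):
        n_exons = int(rng.integers(2, 6))
        exon_lens = rng.integers(150, 400, size=n_exons)
        intron_lens = rng.integers(80, 300, size=n_exons - 1)
        pad5 = int(rng.integers(200, 500))
        pad3 = int(rng.integers(200, 500))
        span = int(exon_lens.sum() + intron_lens.sum())
        rstart = advance(pad5 + span + pad3)
        tstart = rstart + pad5
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = tstart
        for k in range(n_exons):
            exons.append(GenomicInterval(cfg.chrom, pos, pos + int(exon_lens[k]), strand))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                istart, iend = pos, pos + int(intron_lens[k])
                if strand == "+":
                    genome[istart], genome[istart + 1] = "G", "T"
                    genome[iend - 2], genome[iend - 1] = "A", "G"
                else:
                    genome[istart], genome[istart + 1] = "C", "T"
                    genome[iend - 2], genome[iend - 1] = "A", "C"
                pos = iend
        tx = TranscriptModel(id=f"linc_{li}", strand=strand, exons=exons)
        lincrnas.append(tx)
        rname = new_region(GenomicInterval(cfg.chrom, rstart, rstart + pad5 + span + pad3), "lincrna")
        lincrna_region[tx.id] = rname
        advance(margin)

    # coding-like regions (planted synonymous-substitution pattern)
    for _ in range(cfg.n_coding_regions):
        rlen = int(rng.integers(2000, 4000))
        rstart = advance(rlen)
        new_region(GenomicInterval(cfg.chrom, rstart, rstart + rlen), "coding")
        advance(margin)

    # transcriptionally silent regions (no polymerase signal)
    n_silent = cfg.n_candidate_regions - region_counter
    for _ in range(n_silent):
        rlen = int(rng.integers(2000, 4000))
        rstart = advance(rlen)
        new_region(GenomicInterval(cfg.chrom, rstart, rstart + rlen), "silent")
        advance(margin)

    # pre-miRNA precursors in the remaining tail
    pre_mirnas: dict[str, GenomicInterval] = {}
    mirnas: list[MirnaRecord] = []
    for mi in range(cfg.n_mirnas):
        plen = int(rng.integers(80, 120))
        pstart = advance(plen)
        advance(500)
        strand = "+" if rng.random() < 0.5 else "-"
        mid = f"mir_{mi}"
        pre_mirnas[mid] = GenomicInterval(cfg.chrom, pstart, pstart + plen, strand)
        mirnas.append(MirnaRecord(id=mid, mature_seq="".join(_random_seq(rng, 22))))

    # plant 8mer seed sites and the pairing truth; one miRNA may repress
    # several lincRNAs, each lincRNA has at most one planted regulator
    planted_pairs: list[tuple[str, str]] = []
    planted_sites: list[tuple[str, str, int, tuple[GenomicInterval, ...]]] = []
    for k in range(cfg.n_planted_pairs):
        tx = lincrnas[k]
        mir = mirnas[k % max(1, cfg.n_mirnas // 2)]
        site = revcomp(mir.mature_seq[1:8]) + "A"  # 8mer in transcript sense
        exon_idx = int(rng.integers(0, len(tx.exons)))
        exon = tx.exons[exon_idx]
        gpos = exon.start + int(rng.integers(10, len(exon) - 10 - 8))
        planted = site if tx.strand == "+" else revcomp(site)
        genome[gpos : gpos + 8] = list(planted)
        # transcript coordinate of the planted site
        seq_before = 0
        exons_sense = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
        for e in exons_sense:
            if e is exon:
                if tx.strand == "+":
                    tpos = seq_before + (gpos - e.start)
                else:
                    tpos = seq_before + (e.end - (gpos + 8))
                break
            seq_before += len(e)
        planted_pairs.append((tx.id, mir.id))
        planted_sites.append(
            (tx.id, mir.id, tpos, (GenomicInterval(cfg.chrom, gpos, gpos + 8, tx.strand),))
        )

    genome_str = "".join(genome)
    genome_dict = {cfg.chrom: genome_str}

    # polymerase ChIP tags: genes and transcribed/coding regions get tags,
    # silent regions none (a toy occupancy track; the RPKM threshold then
    # separates occupied from unoccupied regions)
    chip_tags: list[GenomicInterval] = []
    def add_tags(iv: GenomicInterval, n: int) -> None:
        for p in sorted(rng.integers(iv.start, iv.end - 25, size=n)):
            chip_tags.append(GenomicInterval(cfg.chrom, int(p), int(p) + 25, "+"))

    for g in known_genes:
        add_tags(g.span, int(rng.poisson(200)))
    for iv, klass, _ in candidate_regions:
        if klass in ("lincrna", "coding"):
            add_tags(iv, max(5, int(rng.poisson(40))))

    # pairwise alignment material for coding-potential scoring
    csf_matrix = make_csf_matrix()
    region_alignments: dict[str, tuple[str, str]] = {}
    for iv, klass, name in candidate_regions:
        ref = genome_str[iv.start : iv.end]
        if klass == "coding":
            informant = []
            for i in range(0, len(ref) - 2, 3):
                codon = ref[i : i + 3]
                syns = _synonyms(codon)
                if syns and rng.random() < 0.5:
                    codon = syns[int(rng.integers(0, len(syns)))]
                informant.append(codon)
            inf = "".join(informant)
            inf += ref[len(inf):]
        else:
            bases = np.array(list(ref))
            mask = rng.random(len(ref)) < cfg.informant_sub_rate
            repl = _random_seq(rng, int(mask.sum()))
            bases[mask] = repl
            inf = "".join(bases)
        region_alignments[name] = (ref, inf)

    x1_mu = rng.uniform(*cfg.x1_mu_range, size=cfg.n_mirnas)

    feature_ids = [g.id for g in known_genes] + [t.id for t in lincrnas]
    weights = rng.uniform(0.5, 1.5, size=len(feature_ids))
    budget = cfg.mean_depth * 0.85
    baselines = {
        fid: float(w / weights.sum() * budget) for fid, w in zip(feature_ids, weights)
    }
    gene_beta2 = {fid: float(rng.normal(0.0, cfg.beta2_sd)) for fid in feature_ids}

    return SimulatedTruth(
        cfg=cfg,
        genome=genome_dict,
        known_genes=known_genes,
        candidate_regions=candidate_regions,
        lincrnas=lincrnas,
        lincrna_region=lincrna_region,
        pre_mirnas=pre_mirnas,
        mirnas=mirnas,
        planted_pairs=planted_pairs,
        planted_sites=planted_sites,
        chip_tags=chip_tags,
        region_alignments=region_alignments,
        csf_matrix=csf_matrix,
        x1_mu=x1_mu,
        gene_beta2=gene_beta2,
        baselines=baselines,
    )


# ---------------------------------------------------------------------------
# expression counts and reads


def _nb(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Counts with mean mu and variance phi*mu (Gamma-Poisson mixture)."""
    mu = np.asarray(mu, dtype=float)
    if phi <= 1.0:
        return rng.poisson(mu)
    shape = mu / (phi - 1.0)
    lam = rng.gamma(shape, phi - 1.0)
    return rng.poisson(lam)


def simulate_counts(
    cfg: SimulationConfig, truth: SimulatedTruth, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Per-feature per-sample counts following the planted model.

    Returns ``(counts, x1, depth_factor)`` where ``counts`` is features x
    samples, ``x1`` the true miRNA ln RPM covariate (miRNAs x samples), and
    ``depth_factor`` the per-sample library-size multiplier.  Planted
    repression acts through the condition-centered x1 of the pair's miRNA,
    so the configured b1/b3 are the true coefficients of the fitted model
    while baselines stay interpretable as expected reads.
    """
    samples = truth.sample_ids
    x2 = truth.conditions.astype(float)
    n = len(samples)
    b0, b1, b2, b3 = cfg.beta
    d = np.exp(rng.normal(0.0, 0.15, size=n))  # library-size factor

    x1 = pd.DataFrame(
        rng.normal(truth.x1_mu[:, None], cfg.x1_sigma, size=(cfg.n_mirnas, n)),
        index=[m.id for m in truth.mirnas],
        columns=samples,
    )

    mir_of = truth.mirna_of_lincrna()
    rows = {}
    for fid, baseline in truth.baselines.items():
        if fid in mir_of:
            xv = x1.loc[mir_of[fid]].to_numpy()
            xc = xv - xv.mean()
            eta = np.log(baseline) + b1 * xc + b2 * x2 + b3 * xc * x2 + np.log(d)
        else:
            eta = np.log(baseline) + truth.gene_beta2[fid] * x2 + np.log(d)
        rows[fid] = _nb(rng, np.exp(eta), cfg.dispersion)

    for mid, iv in truth.pre_mirnas.items():
        lam = np.exp(x1.loc[mid].to_numpy()) * cfg.mean_depth / 1e6 * d
        rows[mid] = rng.poisson(lam)

    counts = pd.DataFrame(rows, index=samples).T
    return counts, x1, d


@dataclass
class SimulatedReads:
    alignments: dict[str, list[SplicedAlignment]]  # sample -> aligned reads
    unmapped: dict[str, list[RawRead]]  # sample -> junction-spanning pool
    total_mapped: dict[str, int]
    counts: pd.DataFrame
    x1: pd.DataFrame


def simulate_reads(
    cfg: SimulationConfig, truth: SimulatedTruth, rng: np.random.Generator | None = None
) -> SimulatedReads:
    """Emit per-sample spliced alignments plus the unmapped junction pool.

    Reads are placed uniformly along each feature's spliced sequence.
    Reads contained in a single exon are emitted pre-aligned (BED12-style
    blocks); reads crossing a splice junction go to the unmapped pool as
    raw sequence+quality records (these are what the QC and junction-
    matching stages consume).  A configurable fraction of the unmapped pool
    carries planted QC defects (ambiguous bases or low-quality tails).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    counts, x1, _ = simulate_counts(cfg, truth, rng)
    features = truth.features()
    rl = cfg.read_length

    alignments: dict[str, list[SplicedAlignment]] = {s: [] for s in truth.sample_ids}
    unmapped: dict[str, list[RawRead]] = {s: [] for s in truth.sample_ids}

    for fid, feature in features.items():
        if isinstance(feature, TranscriptModel):
            tx = feature
        else:
            tx = TranscriptModel(id=fid, strand=feature.strand, exons=[feature])
        spliced = tx.spliced_sequence(truth.genome)
        L = tx.spliced_length
        eff_rl = min(rl, L)
        for s in truth.sample_ids:
            y = int(counts.at[fid, s])
            if y == 0:
                continue
            starts = rng.integers(0, L - eff_rl + 1, size=y)
            for k, st in enumerate(starts):
                blocks = tx.transcript_to_genomic(int(st), eff_rl)
                rid = f"{fid}:{k}"
                if len(blocks) == 1:
                    alignments[s].append(
                        SplicedAlignment(read_id=rid, sample_id=s, strand=tx.strand, blocks=blocks)
                    )
                else:
                    bases = spliced[int(st) : int(st) + eff_rl]
                    quals = [40] * eff_rl
                    if rng.random() < cfg.qc_defect_fraction:
                        if rng.random() < 0.5:
                            pos = rng.choice(eff_rl, size=3, replace=False)
                            arr = list(bases)
                            for p in pos:
                                arr[int(p)] = "N"
                            bases = "".join(arr)
                        else:
                            cut = int(rng.integers(5, eff_rl - 5))
                            quals = quals[:cut] + [5] * (eff_rl - cut)
                    unmapped[s].append(RawRead(rid, bases, quals))

    total_mapped = {s: len(alignments[s]) for s in truth.sample_ids}
    return SimulatedReads(
        alignments=alignments,
        unmapped=unmapped,
        total_mapped=total_mapped,
        counts=counts,
        x1=x1,
    )


# ---------------------------------------------------------------------------
# multi-species alignment


def make_tree(n_species: int) -> tuple[str, object]:
    """Ladder tree over ``ref, sp1..sp{n-1}``; the reference sits at a
    zero-length branch so its row equals the genome."""
    newick = "ref:0.0"
    for i in range(1, n_species):
        newick = f"({newick},sp{i}:{0.35 if i == n_species - 1 else 0.25}):{0.1}"
    newick = newick[: newick.rfind(")") + 1] + ";"
    tree = Phylo.read(_io.StringIO(newick), "newick")
    return newick, tree


def _evolve(
    rng: np.random.Generator,
    parent: np.ndarray,
    t: float,
    omega_site: np.ndarray,
) -> np.ndarray:
    """One branch of JC69 evolution with per-site rate multipliers."""
    lam = t * omega_site
    p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * lam))
    mask = rng.random(len(parent)) < p_change
    child = parent.copy()
    if mask.any():
        shift = rng.integers(1, 4, size=int(mask.sum()))
        child[mask] = (parent[mask] + shift) % 4
    return child


def simulate_maf(
    cfg: SimulationConfig,
    truth: SimulatedTruth,
    rng: np.random.Generator | None = None,
    block_size: int = 1000,
) -> tuple[list[tuple[int, dict[str, str]]], str]:
    """JC-evolve the genome on the tree; conserved at planted seed sites.

    Returns ``(maf_blocks, newick)`` where each block is
    ``(ref_start, {taxon: seq})`` covering ``block_size`` reference bases.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    newick, tree = make_tree(cfg.n_species)
    genome = truth.genome[cfg.chrom]
    code = {b: i for i, b in enumerate("ACGT")}
    root = np.array([code[b] for b in genome], dtype=np.int8)

    omega_site = np.full(len(genome), cfg.omega_background, dtype=float)
    for _, _, _, blocks in truth.planted_sites:
        for iv in blocks:
            omega_site[iv.start : iv.end] = cfg.omega_conserved

    leaf_seqs: dict[str, np.ndarray] = {}

    def walk(clade, seq: np.ndarray) -> None:
        for child in clade.clades:
            child_seq = _evolve(rng, seq, child.branch_length or 0.0, omega_site)
            if child.is_terminal():
                leaf_seqs[child.name] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.root, root)

    decode = np.array(list("ACGT"))
    taxa = ["ref"] + [f"sp{i}" for i in range(1, cfg.n_species)]
    blocks = []
    for start in range(0, len(genome), block_size):
        end = min(start + block_size, len(genome))
        rows = {t: "".join(decode[leaf_seqs[t][start:end]]) for t in taxa}
        blocks.append((start, rows))
    return blocks, newick


def extract_alignment(
    blocks: list[tuple[int, dict[str, str]]], start: int, end: int
) -> dict[str, str]:
    """Alignment rows for a reference interval from gapless tiling blocks."""
    rows: dict[str, list[str]] = {}
    for bstart, brows in blocks:
        blen = len(next(iter(brows.values())))
        s = max(start, bstart)
        e = min(end, bstart + blen)
        if s < e:
            for taxon, seq in brows.items():
                rows.setdefault(taxon, []).append(seq[s - bstart : e - bstart])
    return {t: "".join(parts) for t, parts in rows.items()}


# ---------------------------------------------------------------------------
# file emission


def write_truth(truth: SimulatedTruth, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated input and truth table to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = truth.cfg
    paths: dict[str, Path] = {}

    paths["genome"] = out / "genome.fa"
    io.write_fasta(paths["genome"], truth.genome)

    paths["known_genes"] = out / "known_genes.bed"
    io.write_bed6(
        paths["known_genes"], [g.span for g in truth.known_genes], [g.id for g in truth.known_genes]
    )

    paths["candidate_regions"] = out / "candidate_regions.bed"
    io.write_bed6(
        paths["candidate_regions"],
        [iv for iv, _, _ in truth.candidate_regions],
        [name for _, _, name in truth.candidate_regions],
    )

    paths["chip_tags"] = out / "chip_tags.bed"
    io.write_bed6(paths["chip_tags"], truth.chip_tags)

    paths["mirnas"] = out / "mirnas_mature.fa"
    io.write_fasta(
        paths["mirnas"], [(m.id, m.mature_seq.replace("T", "U")) for m in truth.mirnas]
    )
    paths["pre_mirnas"] = out / "pre_mirnas.bed"
    io.write_bed6(paths["pre_mirnas"], list(truth.pre_mirnas.values()), list(truth.pre_mirnas))

    paths["truth_transcripts"] = out / "truth_lincrnas.bed12"
    io.write_transcripts_bed12(paths["truth_transcripts"], truth.lincrnas)

    paths["truth_regions"] = out / "truth_regions.tsv"
    pd.DataFrame(
        [
            (name, iv.chrom, iv.start, iv.end, klass)
            for iv, klass, name in truth.candidate_regions
        ],
        columns=["name", "chrom", "start", "end", "class"],
    ).to_csv(paths["truth_regions"], sep="\t", index=False)

    paths["truth_pairs"] = out / "truth_pairs.tsv"
    pd.DataFrame(truth.planted_pairs, columns=["lincrna", "mirna"]).to_csv(
        paths["truth_pairs"], sep="\t", index=False
    )

    paths["truth_sites"] = out / "truth_sites.tsv"
    pd.DataFrame(
        [
            (linc, mir, tpos, blocks[0].start, blocks[-1].end, blocks[0].strand)
            for linc, mir, tpos, blocks in truth.planted_sites
        ],
        columns=["lincrna", "mirna", "transcript_pos", "start", "end", "strand"],
    ).to_csv(paths["truth_sites"], sep="\t", index=False)

    paths["csf_matrix"] = out / "csf_matrix.tsv"
    truth.csf_matrix.to_csv(paths["csf_matrix"], sep="\t")

    aln_path = out / "region_alignments.fa"
    pairs = []
    for name, (ref, inf) in truth.region_alignments.items():
        pairs.append((f"{name}|ref", ref))
        pairs.append((f"{name}|informant", inf))
    io.write_fasta(aln_path, pairs)
    paths["region_alignments"] = aln_path

    return paths


def write_reads(reads: SimulatedReads, outdir: str | Path) -> dict[str, Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample, alns in reads.alignments.items():
        p = out / f"{sample}.aligned.bed12"
        io.write_alignments_bed12(p, alns)
        paths[f"aligned:{sample}"] = p
    for sample, pool in reads.unmapped.items():
        p = out / f"{sample}.unmapped.fastq"
        io.write_fastq(p, ((r.id, r.bases, r.quals) for r in pool))
        paths[f"unmapped:{sample}"] = p
    sheet = pd.DataFrame(
        {
            "sample_id": list(reads.total_mapped),
            "condition": [0 if s.startswith("normal") else 1 for s in reads.total_mapped],
            "total_mapped": list(reads.total_mapped.values()),
        }
    )
    p = out / "samples.tsv"
    sheet.to_csv(p, sep="\t", index=False)
    paths["samples"] = p
    return paths
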