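"""The synthetic-study generator: determinism, truth tables, count law."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from lincmir import simulate
from lincmir.conservation import count_substitutions, estimate_omega
from lincmir.intervals import GenomicInterval

from conftest import small_config


def file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class TestConfigValidation:
    def test_too_many_lincrnas_rejected(self):
        cfg = small_config()
        cfg.n_true_lincrnas = cfg.n_candidate_regions + 1
        with pytest.raises(ValueError):
            cfg.validate()

    def test_underdispersion_rejected(self):
        cfg = small_config()
        cfg.dispersion = 0.5
        with pytest.raises(ValueError):
            cfg.validate()

    def test_genome_too_short_raises_sizing_error(self):
        cfg = small_config()
        cfg.genome_length = 20_000
        with pytest.raises(ValueError):
            simulate.simulate_genome(cfg)


class TestTruthTables:
    def test_region_classes_match_config(self, small_cfg, small_truth):
        by_class = {}
        for _, klass, _ in small_truth.candidate_regions:
            by_class[klass] = by_class.get(klass, 0) + 1
        assert by_class["near_gene"] == small_cfg.n_near_gene_regions
        assert by_class["lincrna"] == small_cfg.n_true_lincrnas
        assert by_class["coding"] == small_cfg.n_coding_regions
        assert sum(by_class.values()) == small_cfg.n_candidate_regions

    def test_near_gene_regions_are_within_exclusion_distance(self, small_cfg, small_truth):
        genes = [g.span for g in small_truth.known_genes]
        for iv, klass, _ in small_truth.candidate_regions:
            dmin = min(iv.distance(g) for g in genes if g.chrom == iv.chrom)
            if klass == "near_gene":
                assert dmin < small_cfg.min_gene_distance
            else:
                assert dmin >= small_cfg.min_gene_distance

    def test_planted_transcripts_have_canonical_splice_motifs(self, small_truth):
        genome = small_truth.genome
        for tx in small_truth.lincrnas:
            for a, b in zip(tx.exons, tx.exons[1:]):
                intron = genome[tx.chrom][a.end : b.start]
                if tx.strand == "+":
                    assert intron[:2] == "GT" and intron[-2:] == "AG"
                else:
                    assert intron[:2] == "CT" and intron[-2:] == "AC"

    def test_planted_site_sequence_on_transcript(self, small_truth):
        from lincmir.seq import revcomp

        mir_by_id = {m.id: m for m in small_truth.mirnas}
        tx_by_id = {t.id: t for t in small_truth.lincrnas}
        for linc, mir, tpos, _ in small_truth.planted_sites:
            seq = tx_by_id[linc].spliced_sequence(small_truth.genome)
            expected = revcomp(mir_by_id[mir].mature_seq[1:8]) + "A"
            assert seq[tpos : tpos + 8] == expected


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        cfg = small_config(seed=33)
        for d in ("a", "b"):
            truth = simulate.simulate_genome(cfg)
            reads = simulate.simulate_reads(cfg, truth)
            simulate.write_truth(truth, tmp_path / d)
            simulate.write_reads(reads, tmp_path / d / "reads")
        files_a = sorted((tmp_path / "a").rglob("*"))
        for fa in files_a:
            if fa.is_file():
                fb = tmp_path / "b" / fa.relative_to(tmp_path / "a")
                assert file_digest(fa) == file_digest(fb), fa.name

    def test_different_seeds_differ(self):
        t1 = simulate.simulate_genome(small_config(seed=1))
        t2 = simulate.simulate_genome(small_config(seed=2))
        assert t1.genome != t2.genome


class TestCountLaw:
    def test_dispersion_matches_configured_phi(self, rng):
        mu = np.full(200_000, 50.0)
        y = simulate._nb(rng, mu, phi=1.5)
        assert np.var(y) / np.mean(y) == pytest.approx(1.5, rel=0.05)

    def test_phi_one_is_poisson(self, rng):
        y = simulate._nb(rng, np.full(100_000, 30.0), phi=1.0)
        assert np.var(y) / np.mean(y) == pytest.approx(1.0, rel=0.05)

    def test_planted_repression_gives_negative_rank_correlation(self, rng):
        """b1 = -0.8 must show up as negative Spearman correlation between
        target RPKM-scale counts and the miRNA covariate across samples."""
        cfg = small_config()
        truth = simulate.simulate_genome(cfg)
        rhos = []
        for _ in range(5):
            counts, x1, _ = simulate.simulate_counts(cfg, truth, rng)
            for linc, mir in truth.planted_pairs:
                rho, _ = spearmanr(counts.loc[linc], x1.loc[mir])
                rhos.append(rho)
        assert np.mean(rhos) < -0.3

    def test_null_beta_gives_flat_fit(self, rng):
        from lincmir.glm import fit_pair

        cfg = small_config()
        cfg.beta = (2.0, 0.0, 0.0, 0.0)
        truth = simulate.simulate_genome(cfg)
        b1s = []
        for _ in range(10):
            counts, x1, _ = simulate.simulate_counts(cfg, truth, rng)
            for linc, mir in truth.planted_pairs:
                M = counts.sum(axis=0).to_numpy(dtype=float)
                fit = fit_pair(
                    counts.loc[linc].to_numpy(dtype=float),
                    x1.loc[mir].to_numpy(),
                    truth.conditions.astype(float),
                    M,
                )
                b1s.append(fit.beta1)
        assert abs(np.mean(b1s)) < 0.05

    def test_every_junction_has_spanning_reads_at_default_depth(self, small_cfg, small_truth):
        reads = simulate.simulate_reads(small_cfg, small_truth)
        # collect junction-read source positions from the unmapped pool ids
        spanning = {}
        for pool in reads.unmapped.values():
            for r in pool:
                fid = r.id.rsplit(":", 1)[0]
                spanning[fid] = spanning.get(fid, 0) + 1
        for tx in small_truth.lincrnas:
            n_junctions = len(tx.exons) - 1
            if n_junctions:
                assert spanning.get(tx.id, 0) >= n_junctions


class TestMaf:
    def test_fully_conserved_sites_have_no_substitutions(self, small_cfg, small_truth):
        cfg = small_config()
        cfg.omega_conserved = 0.0
        truth = simulate.simulate_genome(cfg)
        blocks, _ = simulate.simulate_maf(cfg, truth)
        for _, _, _, site_blocks in truth.planted_sites:
            for iv in site_blocks:
                rows = simulate.extract_alignment(blocks, iv.start, iv.end)
                assert count_substitutions(rows) == 0

    def test_longer_branches_mean_more_substitutions(self, rng):
        parent = rng.integers(0, 4, size=20_000).astype(np.int8)
        omega = np.ones(20_000)
        short = (simulate._evolve(rng, parent, 0.05, omega) != parent).sum()
        long = (simulate._evolve(rng, parent, 0.5, omega) != parent).sum()
        assert long > short

    def test_planted_sites_more_conserved_than_background(self, small_cfg, small_truth):
        from Bio import Phylo
        import io as _io

        blocks, newick = simulate.simulate_maf(small_cfg, small_truth)
        tree = Phylo.read(_io.StringIO(newick), "newick")
        site_rows = {}
        for i, (_, _, _, site_blocks) in enumerate(small_truth.planted_sites):
            iv = site_blocks[0]
            site_rows[i] = simulate.extract_alignment(blocks, iv.start, iv.end)
        # pool planted-site columns vs length-matched background windows
        pooled_site = {t: "".join(site_rows[i][t] for i in site_rows) for t in site_rows[0]}
        bg = simulate.extract_alignment(blocks, 1000, 1000 + 8 * len(site_rows))
        omega_site = estimate_omega(pooled_site, tree).omega
        omega_bg = estimate_omega(bg, tree).omega
        assert omega_site < omega_bg
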