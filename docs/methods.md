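# Methods

This note documents the models, procedures and numerical choices behind
`lincmir`, what the synthetic-study generator does and does not emulate,
and the limitations a user should keep in mind.

## The discovery procedure

The pipeline reconstructs long intergenic non-coding RNAs (lincRNAs) ab
initio from strand-specific spliced RNA-seq alignments and then tests, per
(lincRNA, miRNA) pair, whether the lincRNA's expression is reverse
correlated with the miRNA's across a normal/tumor cohort. Stages, in
order:

1. **Candidate regions.** Chromatin-signature (K4-K36) regions from two
   sources are unioned; any merged region overlapping or within
   `min_gene_distance` (default 5,000 bp) of a known gene is removed. The
   distance rule is strict: a gap of exactly the threshold keeps the
   region. The 5 kb default is a convention of the K4-K36 lincRNA
   literature, not a measured value, and is configurable.
2. **Polymerase occupancy.** RNA-polymerase-II ChIP tags are assigned to a
   region by their 5' position; tag density is expressed in RPKM
   (tags / region kb / million total tags) and regions must exceed 0.1
   RPKM strictly.
3. **Coding potential.** The codon-substitution-frequency (CSF) score of a
   region is the maximum, over all 90-base windows in all six reading
   frames (3 offsets x 2 strands, sliding in 3-base steps), of the summed
   per-codon log-odds `matrix[ref_codon, aligned_codon]`, averaged over
   informant rows when the alignment has more than two sequences.
   Reference codons containing gaps carry no information and score 0;
   informant codons containing gaps use the matrix's gap column. Regions
   scoring strictly above 20 are excluded as putatively protein-coding.
   The log-odds matrix is an input artifact; training a mammalian codon
   model is out of scope, and the generator emits a matched synthetic
   matrix (+1 synonymous / -1 otherwise) whose planted coding pattern
   forces scores of ~30 per window.
4. **Transcript assembly.** Putative exons are maximal read-covered
   intervals inside a region; intervals separated by a gap strictly
   smaller than 10 bp are merged (the left-to-right pass reaches the
   unique fixpoint because merging never widens a gap), and an interval
   needs at least 8 distinct overlapping reads. Candidate splice sites
   are canonical dinucleotides read on the reference — GT/AG for Watson-
   strand transcripts, CT/AC for Crick — within 25 bp of exon edges. All
   compatible (donor, acceptor) pairs with intron length >= 70 bp and
   span <= 100,000 bp form a junction sequence library (flank = read
   length - 1, stored in transcript-sense orientation). Unmapped reads
   are aligned to the library ungapped with at most 2 mismatches and must
   overhang the junction point by at least 8 bases on both sides; each
   read supports at most one junction (fewest mismatches; ties between
   distinct junctions are dropped). Matching uses pigeonhole
   seed-and-extend — the read is cut into `max_mismatch + 1` disjoint
   exact seeds — which is provably equivalent to the exhaustive scan.
   Finally, exons are nodes and supported junctions edges; each connected
   component becomes one transcript, exon boundaries refined to the
   best-supported donor/acceptor, strand voted by junction motif. This
   component assembler is a deliberate simplification of statistical
   segmentation assemblers; its exact-structure recovery rate on planted
   truth (>= 90%, typically 97-100% at default depth) is measured by the
   test suite rather than assumed.
5. **Target prediction.** Canonical seed sites are searched anywhere on
   the spliced sense-strand sequence: `7mer-m8` (reverse complement of
   miRNA positions 2-8), `7mer-A1` (reverse complement of positions 2-7
   followed by an A), and `8mer` (both). Each occurrence is reported once
   with its most specific type. Thermodynamic/accessibility site scoring
   is a non-goal. Sites are back-projected through the exon map and may
   cross junctions. Length-matched control intervals are taken 100 bp 5'
   of each site on the transcript (sites too close to the 5' end are
   dropped and counted).
6. **Quantification.** A read counts toward a feature when any aligned
   block overlaps the feature's exonic bases on the same strand, at most
   once per feature; ambiguous reads count for every feature they touch
   (declared, no rescue). RPKM = count / (exonic kb) / (library size in
   millions). miRNA abundance is quantified on the annotated ~80-120 nt
   precursor interval — mature-miRNA abundance is explicitly not claimed.
   A feature is "detectable" with RPKM strictly above 0.5 in strictly
   more than 15 of the 20 samples, counted over the whole cohort.
7. **Reverse correlation.** For each pair with a predicted site and both
   members detectable, counts are regressed as

   `ln E[y] = b0 + b1*x1 + b2*x2 + b3*x1*x2 + ln(M)`

   with x1 = miRNA ln(reads per million), x2 = tumor indicator, M =
   per-sample mapped reads (offset). Overdispersion is quasi-Poisson:
   Var[y] = phi*mu with phi = Pearson chi-square / residual df, and
   coefficient tests are two-sided t-tests on the residual df. When b3 is
   not significant at 0.05 the pair is refit without the interaction
   (dispersion re-estimated on the reduced model) and b1 is tested there;
   pairs with significant b3 are flagged condition-specific. A pair is
   called reverse correlated when b1 < 0 and its Benjamini-Hochberg FDR
   (computed within the gene and lincRNA families separately; pooling is
   available) is below 0.2. The sign requirement is an explicit design
   choice: significance alone would also admit positive associations.
8. **Conservation.** A site's conservation is the rate multiplier omega
   maximizing the Jukes-Cantor likelihood of its alignment columns on a
   fixed tree with all branch lengths scaled by omega (one omega per
   block; smaller = more conserved). Felsenstein pruning treats gaps/Ns
   as missing; columns with fewer than two informative taxa or gaps in
   more than half the taxa are skipped; a block with zero observed
   substitutions returns the boundary optimum 0 exactly; otherwise the
   1-D likelihood is maximized on [0, 10] by bounded scalar search with
   tolerance 1e-6. This single-parameter JC summary deliberately replaces
   richer per-site phylogenetic rate models: every downstream use is
   ordinal (rank-sum test of correlated vs other sites, signed-rank test
   of site vs its own upstream control, Spearman correlation of
   polymerase occupancy vs expression), for which a monotone conservation
   summary suffices.

## Fitting details

The IRLS implementation (log link, offset, Poisson working weights) is
written out directly so the dispersion and t-test conventions are
explicit; tolerance is 1e-8 on the deviance with at most 100 iterations.
Preconditions: >= 6 samples, non-constant x1, both conditions present,
not all counts zero. A diverging linear predictor (separation) or singular
design raises an error and the pair is excluded and flagged. With the
dispersion fixed the fit coincides with a plain Poisson log-link
regression; the test suite cross-checks coefficients, standard errors,
dispersion and p-values against an independent GLM implementation, and
verifies the exact offset identity (scaling all M by c shifts b0 by
-ln c and nothing else).

## The synthetic study

The generator emits every input the pipeline consumes, with the
statistical structure the analysis assumes. Defaults describe the study
design: 10 normal + 10 tumor samples; a 600 kb single-chromosome genome;
8 single-exon known genes; 50 candidate regions — 30 containing a planted
multi-exon lincRNA (2-5 exons of 150-400 bp, introns 80-300 bp with
canonical motifs), 8 near known genes, 5 with a planted synonymous-
substitution coding pattern, 7 transcriptionally silent; 12 miRNAs with
random 22-nt matures; 10 planted repressed (lincRNA, miRNA) pairs with
coefficients beta = (2, -0.8, 0.3, 0) and dispersion phi = 1.5; ~15,000
feature-assigned reads per sample of length 50 (the source study does not
state its depth, so depth is an explicit knob; the default gives planted
transcripts 200-400 reads per sample, enough for exact structure
recovery); a 5-taxon ladder tree with the reference at a zero-length
branch; rate multiplier 0.2 at planted seed sites and 1 elsewhere.

Counts are negative-binomial with Var = phi*mu (the moment-matched
realization of quasi-Poisson overdispersion, via a Gamma-Poisson
mixture). Each miRNA's per-sample ln RPM is drawn once and shared across
all its target pairs, mirroring one miRNA regulating many targets; the
repression effect acts through the condition-centered covariate so that
the configured b1 and b3 are exactly the true coefficients of the fitted
model while per-feature baselines remain interpretable as expected reads
(the centering shift is absorbed by the intercept). Reads are placed
uniformly along the spliced sequence; reads contained in one exon are
emitted pre-aligned (simulating an aligner is out of scope), while
junction-crossing reads are emitted as raw sequence + quality records —
the pool the QC and junction-matching stages consume. This diverts a
per-feature constant fraction of reads out of the counted alignments,
which scales each feature's quantified counts by a constant absorbed into
the intercept; b1 and b3 are unaffected. About 2% of the junction pool
carries planted QC defects (ambiguous bases or low-quality tails). The
multi-species alignment evolves the genome down the tree under
Jukes-Cantor with per-site rate multipliers.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing-error profiles and base-composition
bias; multi-mapping and repeat-induced ambiguity; alternative isoforms
and overlapping transcription; polymerase ChIP background (silent regions
receive zero tags, so the 0.1 RPKM threshold separates occupied from
unoccupied regions rather than grading a continuous background —
threshold arithmetic is exercised by closed-form unit tests instead);
insertions/deletions in the species alignment; and genome-scale region
counts. Results on this generator validate the machinery and its
statistical calibration, not discovery performance on real tissue.

## Reported calibration (recomputed by the tests and acceptance script)

* Coefficient recovery: each of the four coefficients within 3 standard
  errors of truth in >= 95% of 500 replicates at n = 200.
* Type-I error of the b1 t-test at the 20-sample design with phi = 1.5:
  within the 99% binomial band around 0.05 over 2,000 replicates.
* Omega consistency on 10,000 simulated columns over the 5-taxon tree:
  estimates within [0.95, 1.05] for true omega = 1 and [0.15, 0.25] for
  true omega = 0.2; two-taxon estimates match the closed-form JC distance
  divided by path length to 1e-4.
* End-to-end on the default study: >= 90% of planted multi-exon
  structures recovered exactly; planted 8mer sites recalled at 100%;
  pooled sensitivity >= 0.7 and pooled empirical FDR <= 0.3 for
  reverse-correlation calls at FDR < 0.2 over 20 expression replicates;
  correlated sites more conserved than other sites and than their 100-bp
  upstream controls (rank-sum and signed-rank p < 0.05).

## Known limitations

* The component assembler cannot separate overlapping transcripts or
  isoforms sharing exons; a region yields at most one model per connected
  component.
* Junction support requires reads to survive QC and carry at least
  8 + 8 anchor bases; very short exons (< anchor) cannot be linked.
* The quasi-Poisson t-test is approximate at small n; its calibration is
  verified at the 20-sample design but will degrade below ~10 samples.
* Omega estimates on 7-8 bp sites over 5 taxa are noisy individually;
  only their ranks are used, and the contrasts pool sites.
* Gene-level analysis treats genes as single-exon intervals from the
  annotation BED; gene isoform structure is out of scope.
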