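# Methods

This note documents the models, defaults and numerical decisions behind
hemoseq, and what the simulation-based tests do and do not establish about
real sequencing data.

## Study design emulated by the simulator

The simulator reproduces the data structure of a barcoded, multiplexed
targeted-resequencing case-control study: a capture panel over candidate
genes (coding exons, UTRs and intron-exon boundaries), a small deeply
sequenced discovery cohort (default 10 cases, 12 controls), and a larger
replication cohort (default 719 + 719) genotyped only at carried-over
sites. Design constants baked into the defaults: 42X mean on-target depth,
7% of raw reads on target, mapping-quality floor 50, allele-balance floor
20%, both-strand requirement, 10X depth floor, pooled-MAF floor 8%,
missingness ceiling 10%, top-5 carry-over, stage-2 gate of 80% power at
p < 0.005.

### Panel generation

`build_panel` lays genes left to right on contigs (5 per contig),
alternating strand. Each gene carries a random open reading frame
(ATG … stop, no internal stop) split across the configured exon count at
random cut points, so codons straddle exon junctions as in real
transcripts; first/last exons carry 24 bp UTR; targets are exons padded by
12 bp and merged. Default scale is 10 genes × 3 exons × 90 codons
(~3.9 kb of target) — a deliberately scaled-down analogue of a hundreds-of-
genes, ~644 kb clinical panel, chosen so a full read-level cohort simulates
in seconds. The first half of the genes forms the "coagulation_factor"
set, the second half the "anticoagulant" set used by the burden analysis.

### Genotype model

Controls are Hardy-Weinberg at each site's control MAF (dosage ~
Binomial(2, q)). Cases are Hardy-Weinberg at the case frequency implied by
the retrospective sampling model:

* background sites: p_case = q (null);
* the common risk SNP: p_case = OR·q/(1 + q·(OR − 1)), so the allelic odds
  ratio equals the configured OR exactly (default q = 0.22, OR = 1.45, a
  realistic common-variant effect for this phenotype);
* rare-burden sites: p_case = min(enrichment · q, 0.5) (default q = 0.02,
  4-fold enrichment, one missense site in each of the 5 anticoagulant
  genes — expected totals ≈ 8 case vs ≈ 2.4 control alleles at the default
  cohort size, matching the magnitudes such studies report).

Background variation defaults to 30 common SNVs (MAF ~ U(0.05, 0.5)), 60
rare SNVs (MAF ~ U(0.005, 0.05)) and 3 single-base deletions per panel,
giving a spectrum dominated by rare variants. Background SNVs avoid the
CDS of the burden gene set so that set's missense variation is governed
entirely by the configured burden block, mirroring the emulated design in
which the anticoagulant genes carried only the handful of rare missense
variants under test. HWE within groups, independence across sites, and no
linkage disequilibrium are assumed throughout.

### Read model

Fragments per target interval arrive as independent Poisson streams per
fragment-length class (lengths uniform in 50 ± 8 bp), calibrated so
coverage at every target position is Poisson(mean_depth) exactly, without
edge deficits. Fragment-length jitter exists so that coordinate-based
duplicate removal does not collapse unrelated fragments that coincidentally
share a start. Each fragment carries: a random haplotype of its sample
(het alt alleles are assigned to one haplotype per site), a random strand,
mapping quality 60 (5% of reads drawn at 20 to exercise the mapq filter),
per-base qualities from a two-point Q20/Q30 mixture (20%/80%, mean error
≈ 2.8 × 10⁻³ under error = 10^(−Q/10)), base flips at that rate, and its
sample's barcode with a 2 × 10⁻³ per-base tag error. A `dup_rate` (default
0.15) fraction of fragments is emitted twice with identical coordinates
and independent errors/mapq, modelling PCR duplicates. Off-target reads
are counted, never materialised: they exist only for enrichment
bookkeeping, so fixtures stay small. Deleted bases appear as `-` in the
reference-projected read string; insertions are not simulated (the calling
path accepts them, but no generator emits them). Published sources for
this kind of study do not state their coverage distribution, duplicate
rate or error mix; these defaults are the package's own choices, fixed
once.

**What passing tests do not show:** the simulator has no mapping errors,
no indel realignment ambiguity, no capture GC bias, no allele-selective
capture, no linkage disequilibrium and no population stratification.
Sensitivity/specificity gates passed on simulated cohorts bound the
pipeline's statistical logic, not the behaviour of a real aligner on real
libraries.

## Pipeline decisions

* **Filter order is fixed**: duplicate removal before the mapq filter.
  Removing low-mapq reads first could promote a lower-quality duplicate to
  group representative; the implemented order keeps the top-mapq read per
  (contig, start, end) group, then expunges reads below mapq 50 (50
  passes). Duplicate keys ignore strand by default (configurable); mapq
  ties break on the lexicographically smallest read id.
* **Barcode assignment** is nearest-neighbour global Hamming with
  `max_mismatch` (default 1); the manifest must have pairwise distance
  > 2·max_mismatch, which makes assignment unambiguous, and the simulator
  generates barcodes at distance ≥ 3.
* **Calling**: a candidate needs ≥ 2 alt reads (base quality ≥ 20); call
  quality is −10·log₁₀ P[X ≥ alt_reads], X ~ Binomial(depth, mean
  per-observation error), capped at 9999 when the tail underflows;
  genotype is het below allele balance 0.8, else homvar. Multi-allelic
  sites emit the majority alternate and are flagged. These three values
  (2, 0.8, Q20) and the call-quality floor (20) are reconstructions — the
  emulated workflow names the criteria but not the numbers — and all are
  configurable.
* **QC**: fail reasons are low_allele_balance (< 0.20; 0.20 passes),
  strand_bias (alt allele absent from either orientation; sites whose
  entire coverage is single-stranded fail conservatively and carry a
  distinct flag), low_depth (< 10) and low_quality. Failed calls are kept
  with reasons — genotyping needs them.
* **Genotype projection**: PASS call → its genotype; QC-failed variant
  evidence at the site → missing (evidence untrustworthy, not absent); no
  variant evidence and depth ≥ 10 → homozygous reference; otherwise
  missing. The 10X homref floor reuses the confident-call coverage
  threshold; the original genotyping script's exact rule is unpublished,
  so this linkage is a documented reconstruction (configurable
  `min_ref_depth`).
* **Screen**: MAF is computed on pooled non-missing case+control alleles;
  exclusion at missingness ≥ 0.10 ("less than 10%" passes). Two-sided
  Fisher uses the sum-of-smaller-probabilities definition (scipy's
  default; no mid-p). Ranking ties break by larger |log OR|, then genomic
  position — a deterministic choice where the emulated design is silent.
* **Burden**: allele-count (dosage) collapsing — het = 1, homvar = 2,
  missing = 0 — over nonsynonymous SNVs (missense + nonsense), matching
  "total number of nonsynonymous variants" semantics; one-sided
  case-excess binomial tail with p0 from individual counts; a two-sided
  doubled variant is available by flag. An optional `damaging` column
  restricts to externally predicted damaging sites; the package never
  computes such predictions.
* **Replication power** is the normal-approximation two-proportion power
  on allele counts (2 per individual, independence assumed), pooled null
  s.e. and unpooled alternative s.e., two-sided at alpha2 = 0.005; at
  p1 = p2 it returns exactly alpha. Selection is inclusive at power =
  0.80. Whether the original computation was allelic or genotypic, and
  its sidedness, is unstated; both choices are configurable. The pipeline
  simulates replication at genotype level (the analogue of targeted
  Sanger genotyping), drawing stage cohorts from the truth frequencies;
  screen hits without a truth record replicate as null at their observed
  discovery frequency.
* **Annotation** translates the affected codon (reverse-complemented on
  minus-strand transcripts) with the standard genetic code only;
  stop-retained changes are synonymous; multi-transcript hits report the
  most severe class (nonsense > frameshift > missense > inframe >
  synonymous > UTR > intronic). Positions outside exons but inside or
  adjacent to a gene report as intronic; the panel has no intergenic
  class. Indels are frameshift iff length mod 3 ≠ 0; no realignment.
* **Concordance** percentages are rounded to one decimal everywhere;
  stratification follows input A's genotype (the validation platform's
  framing); the overall rate is symmetric in the inputs.
* **Determinism**: one seed drives everything; stages draw from
  numpy `default_rng([seed, stream_key])` sub-streams, so reruns are
  byte-identical and stages are independently re-runnable.

## Calibration facts worth knowing

* **Fisher's exact test is conservative at the discovery scale.** With 20
  vs 24 alleles the test's attainable size at nominal 0.05 is ≈ 0.026-0.034
  depending on MAF (exact enumeration over binomial allele counts;
  ≈ 0.0295 averaged over MAF ~ U(0.08, 0.5)). Null simulations of the
  screen reproduce this (empirical rate ≈ 0.0296 over ~5.5 × 10⁵ tests).
  No simulation of this design will put the rejection rate at 0.05; the
  property guaranteed — and tested — is that the type-I error never
  exceeds the nominal level.
* **Combined-CI coverage** of the Woolf interval at OR 1.5, q 0.25,
  719 + 719 individuals is ≈ 95-96% over 200 replicates, consistent with
  the nominal rate.
* The minimum detectable minor-allele count at 20 vs 24 alleles and
  α = 0.05 is 4 (pooled MAF ≈ 9.1%) — slightly above the 8% screen floor,
  which therefore admits a few formally undetectable sites.

## Problem sizes used by tests and the acceptance script

Simulation-heavy checks run at sizes chosen to make the statistics sharp
while keeping the whole suite fast: the unit cohorts use a 4-gene panel at
the full 22-sample/42X design; the null-screen calibration uses 1000
(tests) or 300 (script) cohorts of 576 sites drawn at genotype level; CI
coverage uses 200 two-stage cohorts at the full 719 + 719 replication
size; the Fisher oracle enumerates every 2×2 table with row margins ≤ 30;
the consequence oracle covers every CDS position × every substitution of
the default 10-gene panel. Genotype-level draws (`hwe_genotype_matrix`)
stand in for read-level simulation wherever the question is purely
statistical, because the two are equivalent under the error-free
projection and the former is orders of magnitude cheaper.

## Known limitations

* Single-base indels only; no realignment; colorspace/chemistry artifacts
  and capture thermodynamics are out of scope.
* No covariate-adjusted (logistic) association, interaction/epistasis
  tests, or external deleteriousness predictions; known-variant novelty is
  a lookup against user-supplied tables.
* No copy-number analysis (short reads and capture preclude it in the
  emulated design too).
* The crude combined odds ratio is the cross-product estimator; adjusted
  estimates from multivariable models are a different quantity and are not
  computed here.
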