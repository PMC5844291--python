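# Methods

## Mixture model

The package models a spontaneous suppressor screen in a haploid yeast.
Genomic DNA of N revertants of one ts mutant is mixed in equal mass
proportions and sequenced as a single library. For a site where k of the N
genomes carry a non-reference allele, a read covering the site carries that
allele with probability

    f_eff = (k/N)(1 − e) + (1 − k/N)(e/3),

where e is the aggregate per-base sequencing error rate and e/3 the rate at
which a non-carrier read miscalls to one specific alternate base (uniform
miscall spectrum). The three reference classes are k = N (the ts anchor and
parental background variants, allele frequency ≈ 1) and k = 1 (a private
suppressor, ≈ 1/N). Everything is haploid: no heterozygosity anywhere.

## Simulator

`make_genome` draws i.i.d. bases at a given GC fraction (default 0.36,
an AT-rich fungal-like composition). `make_annotation` places
non-overlapping single-exon CDS genes (length a multiple of 3, uniform in
300–1500 bp, random strand) and rewrites the genome inside each interval so
the CDS is well formed — ATG start, sense codons, one terminal stop. This
in-place rewrite is deliberate: the genome is a product of the same builder,
and it guarantees codon-level effect naming is well defined everywhere a
mutation can land.

`make_screen` plants one shared missense ts mutation in the designated ts
gene, `n_background` (default 5) shared parental variants anywhere outside
the ts gene, and per revertant one private suppressor (configurable 0–2) in
target genes drawn by weight, with a missense/nonsense bias of 0.7/0.3 by
default. Identical substitutions may recur in different revertants; they are
independent events, as in a real spontaneous screen. Insertions are
supported in the truth/genomes but off by default because the built-in
aligner is ungapped; indel-containing data should enter as external SAM.

`simulate_pool_reads` draws per-revertant fragment counts as Poisson with
mean proportional to the revertant's mass fraction, so pooled depth at a
site is Poisson with mean N × coverage_per_genome (default 10 × 30 = 300×).
Inserts are normal (mean 400 bp, sd 40 bp — a typical paired-end library),
fragments lie fully inside the chromosome, and both 150 bp mates receive
uniform substitution errors at `error_rate` (default 0.002). Base qualities
are constant Q37; quality-aware calling is out of scope. Read names encode
the true origin (revertant, chromosome, fragment start) for test oracles
only — the pipeline never reads them.

What the simulator does **not** model: PCR duplicates, GC bias, indel
errors, quality decay along the read, mapping ambiguity of real repeat
structure, or strand bias. Passing tests therefore demonstrate the
statistical logic of mixture deconvolution, not robustness to real-library
artifacts.

## Aligner

A k-mer index (default k = 15) over the concatenated reference seeds each
read at non-overlapping offsets on both strands; candidates are extended
ungapped and scored by Hamming distance. The best placement wins only if it
is unique and within `max_mismatch_fraction` (default 0.1) of the read
length; ties are dropped rather than placed randomly so repeats cannot
fabricate allele counts. On ≤10 kb instances the mapper provably agrees
with a brute-force all-offset Hamming scan (tested). Pileup tallies every
aligned base at its reference coordinate with no quality weighting.
Coordinates are 1-based inclusive throughout (VCF/GFF convention); SAM
ingestion walks CIGAR operations (M/=/X consume both, I/S query only, D/N
reference only) and skips secondary/supplementary/unmapped records.

## Pooled caller

At each site and each of the three alternate bases the caller computes the
exact binomial upper tail P(X ≥ alt_count | X ~ Binomial(depth, e/3)) via
`scipy.stats.binom.sf`. Family-wise error is controlled by Bonferroni over
3 × genome length tests (a clean, testable guarantee; exposed as a flag). A
call must satisfy q ≤ α (default 0.05), allele frequency ≥ `min_af`
(default 0.02 — the screen's selection cutoff) and depth ≥ `min_depth`
(default 10). `estimate_error_rate` offers a plug-in estimate of e (total
non-reference fraction over ≥1000 unmasked sites) for data whose error rate
is unknown; a mask should exclude true variant sites.

## Classifier and recurrence filter

Per mixture, a call at the known ts locus with af ≥ 0.9 is the anchor; a
missing or low-frequency anchor raises `AnchorIntegrityWarning` (possible
sample mix-up or loss of the ts allele) and sets a distinct CLI exit code.
Calls matching the parental VCF, or any call at af ≥ 0.8, are
background_common — the 0.8 floor (not 1.0) tolerates binomial sampling
noise at fixed sites. Remaining calls at af ≥ 0.02 are suppressor
candidates. No upper af cap is applied below 0.8: k revertants legitimately
sharing one suppressor give af ≈ k/N. Effects are named at codon level
(missense "G338D", nonsense "Q64Stop", "silent", insertions by frame).

Across the mixtures of a screen, one event is one (mixture, variant) pair;
identical substitutions in different mixtures are independent events. Genes
with ≥ 2 events (threshold configurable; 2 matches the two-event evidence
standard of such screens) are reported; genes of one protein complex pool
into a complex-level report when at least two distinct member genes
contribute and the complex total reaches the threshold — single-gene
evidence never masquerades as complex evidence. Reports are flagged
intragenic when the unit contains the ts gene itself. Mid-frequency variants
recurring at the same position across mixtures are not subtracted as
artifacts, because genuinely recurrent suppressors are expected; the
distinct-variant count in each report makes them visible for manual review.

## Design calculators

* Revertant frequency = revertants / cells plated, with verdicts
  partitioning [0, ∞) at the window [1e-8, 1e-6], endpoints inclusive in
  "suitable". Screens slightly above 1e-6 still round to 1e-6, so the
  nearest power of ten is reported alongside the strict verdict.
* Lane multiplexing: mixtures × pool size genomes per lane.
* Detection power: depth d ~ Poisson(N·c) truncated at 6σ; given d the
  alternate count is Binomial(d, f_eff) and the site is called when the
  count reaches both the Bonferroni-corrected binomial critical value and
  ⌈min_af·d⌉. Matches a Monte-Carlo simulation of the calling rule within
  3σ over a coverage × min_af grid (tested), and is monotone in coverage
  and in k_sharing.

## Numerical and design choices

* All randomness flows from `numpy.random.default_rng(seed)`; equal seeds
  give byte-identical FASTQ/VCF output. Stage seeds in the pipeline are
  derived as fixed offsets from the run seed.
* The binomial tail is computed by scipy's regularized incomplete beta;
  it agrees with an arbitrary-precision rational-arithmetic oracle to 12
  significant digits for depth ≤ 1000 (tested).
* Critical counts for the power model are settled exactly around
  `binom.isf` with a bounded fix-up loop, removing inverse-survival
  off-by-ones.
* Problem sizes in the test-suite and acceptance computations use a 100 kb
  genome with 20 genes for the headline frequency-model checks and
  10–30 kb genomes elsewhere; these sizes put ≥50 pooled reads on every
  planted site (the regime the statistics need) while keeping the suites
  quick to run.
* Coverage is parameterised per pooled genome (`coverage_per_genome`), with
  pooled depth = N × coverage; either reading of "30-fold" coverage is
  expressible by scaling this one parameter.

## Known limitations

Ungapped alignment only (indel screens require external SAM input); no
diploid genotyping; Bonferroni is conservative at very high genome sizes;
the uniform miscall spectrum understates context-dependent errors of real
sequencers; complex membership must be supplied by the user (TSV), no
pathway database is bundled.
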