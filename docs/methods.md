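# Methods

`tedeff` implements a pipeline for detecting and scoring defective
transcription elongation (TE^deff) in bulk tumor RNA-seq cohorts, together
with the downstream analyses that characterize the phenotype: differential
exon meta-profiles, intron-retention quantification from spliced alignments,
RNAP II traveling ratios, permutation-based region enrichment, and survival
stratification. This note records the models, conventions and parameter
choices, and what the synthetic cohort does and does not emulate.

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`. GTF (1-based
closed) converts on read and write; BED and bedGraph pass through unchanged.
For a minus-strand gene the TSS is the largest transcribed coordinate and
5'→3' order runs toward smaller coordinates. The promoter is the strand-aware
window (−1000, +1) around the TSS: 1001 bp covering 1 kb upstream plus the
TSS base, clipped at coordinate 0. A gene's exon set is the union of its
isoforms' exons; introns are the gaps between consecutive union exons, so
exons and introns tile the TSS→TTS span exactly once (a tested invariant).

## AT genes and the TE^deff score

AT (alternatively transcribed) genes are genes whose cohort-level expression
variance is dominated by transcript-isoform switching. The switch score of a
gene is

    mean over isoforms i of Var_s[ log2(x_is + 1) − log2(g_s + 1) ]

where `x_is` is isoform expression and `g_s` gene expression in sample `s` —
the isoform-level variance residual to gene-level variation. The residual
cancels any per-sample scaling shared by all isoforms (library size,
gene-level biology), so the score isolates usage changes. Genes above a
score quantile (default 0.90; a configurable convention, not an externally
fixed value) are kept if their isoforms split into two anti-correlated
clusters: average linkage on `1 − Pearson r` of the *gene-residual* log
profiles, cut into two groups, accepted only when the between-cluster mean
correlation is negative. Clustering on residuals rather than raw profiles is
deliberate: shared gene-level variation otherwise correlates all isoforms of
a gene positively and can mask a genuine usage seesaw. The cluster with the
smaller mean transcript length is the short cluster.

The per-sample TE^deff score is

    log2 [ (mean short-cluster expression + 1) / (mean long-cluster expression + 1) ]

pooled over all isoform×sample cells of all AT genes (a `per_gene` flag
averages within genes first; pooled is the default). Samples with score
strictly greater than −1 are labeled TE^deff; the boundary value goes to
TE^prof because the cutoff is strict. The pseudocount of 1 guards zero
counts. The group signature is the per-gene Welch (unequal-variance) t of
TE^deff vs TE^prof log2 expression; external profiles are matched to it by
Spearman correlation over the gene intersection.

## Exon-bin profiles and gene classes

For every expressed gene — 90th-percentile normalized count strictly above
30 (linear-interpolation percentile) — the Welch t of TE^deff vs TE^prof
expression is computed per exon (RPKM scale, as provided) and mapped onto 20
bins ordered 5'→3'. Exon `i` of `n` sits at fractional position
`(i − 0.5)/n`; with `n ≥ 20` bin `j` averages the exons in `((j−1)/20,
j/20]`, with `n < 20` each bin takes the exon nearest its center
(deterministic, identity at `n = 20`, mean-preserving when `n` is a multiple
of 20). For small cell-line panels a flag switches the emitted statistic to
signed −log10 p.

Gene classes are called from the bin vector with threshold `t0` (default 2):

* **Class I** — body bins 2–17 mean t ≤ −t0 *and* terminal bin 20 t ≥ +t0
  (gene-body loss with 3'-terminal gain, the spurious-elongation pattern);
* **Class II** — overall mean t ≥ +t0 and not Class I (broad overexpression);
* otherwise neutral.

The bin ranges and `t0` are this package's own conventions (exposed as
arguments); the class definitions themselves follow the phenotype's
published description. The structural contrast reports per-class log10
genomic length and mRNA/genomic-length ratio with a Welch t-test. The
methylation meta-profile applies the same group t-statistic to β-values on a
transcript-relative axis (2 kb flanks in flank-fraction units, gene body
scaled to unit length; bins with fewer than 3 probes are NA).

## Junction counting and intron retention

Junctions are enumerated from annotation (consecutive union exons); de-novo
gaps are ignored so eligibility is well defined. From a SAM/BAM, with
mapping quality strictly greater than 20:

* **EE** (exon–exon): a gapped alignment whose N gap equals the intron
  exactly, with ≥ 8 aligned bases on each flanking block (8 counts);
* **EI/IE** (exon–intron / intron–exon): an alignment running ungapped
  across the donor (left) or acceptor (right) boundary with ≥ 8 bases on
  each side, whose start lies within ±150 bp of the boundary.

The ±150 bp window is interpreted as a bound on the read start relative to
the boundary (the published description is ambiguous between start, span and
coverage; this convention is noted and configurable). Junction coordinates
use genomic orientation (donor = left exon end) regardless of strand, and a
read is tallied once per junction it satisfies. CIGAR M/I/D/N/S/=/X are
supported; reads with other operations are skipped and counted in a warning.
The per-sample retention ratio is Σ(EI+IE)/Σ(EE) over eligible junctions
(EE ≥ 5 and intron length > 500 bp; ineligible junctions leave both
numerator and denominator). Median splits put ties in the low group, so an
even number of distinct scores divides exactly in half (42 → 21 + 21).
Counting is verified against an independent per-base brute-force scanner
over anchor (7/8/9) and MAPQ (19/20/21) boundary fixtures.

## Region enrichment

The observed overlap of a gene set's regions (promoters, exon unions or
intron unions) with an interval dataset is the number of genes whose region
intersects the dataset by at least one base. The null replaces each query
gene with a background gene sampled with replacement (the query gene itself
may be redrawn; exclusion is a flag), trimming or extending the sampled
gene's region to the query gene's region length — anchored at the background
region's start, truncation keeping the 5' part and extension at the
transcription-3' end — so every replicate reproduces the query set's
region-length distribution exactly (a tested invariant). With `n_perm`
replicates (default 1000) the result is `z = (observed − mean)/sd` with a
two-sided normal-tail p; two gene sets are contrasted by delta-Z. No
multiple-testing correction is applied by default since Z/delta-Z rankings
are the product; a Benjamini–Hochberg option would be a thin wrapper and is
deliberately left to the caller. Promoter permutations use a vectorized
path; null calibration (background-drawn queries) shows |mean z| < 0.2 and
~5% type-I error at |z| > 1.96.

## ChIP profiles and traveling ratio

Coverage is run-length encoded from bedGraph. The meta-gene profile
extracts TSS−2 kb … TTS+2 kb per gene, length-normalizes the body onto a
101-point grid by cubic-spline sampling (linear for genes shorter than 4 bp
of body — degenerate inputs), takes flank points at a fixed 20 bp step, and
scales per million reads; the aggregate is the per-position mean across
genes, strand-oriented. When a library size is not supplied it is estimated
as coverage area divided by read length (default 50 bp). The traveling ratio
is mean body occupancy (TSS+300 → TTS, transcription direction) divided by
mean occupancy in TSS ± 300 bp; the windows are conventional pausing-index
choices, exposed as arguments. TR is scale-invariant and NA when the TSS
window is empty.

## Survival analyses

Group comparisons fit a single-covariate Cox proportional-hazards model
(lifelines) on the group indicator; the reported p is the Wald test on that
coefficient, with the log-rank test alongside. Kaplan–Meier estimates are
verified against hand-computed product-limit values. The TIL score is the
mean log2(x+1) expression of GZMK and PRF1, median-split (ties low); with a
marker missing it falls back to the available one with a warning.
Therapy-class assignment matches raw drug annotations case-insensitively and
exactly against an editable shipped vocabulary
(`tedeff/data/therapy_vocabulary.tsv`); unmatched annotations are "other".
Two-factor stratification crosses TE^deff status with a binary factor into
four strata, reporting empty strata with n = 0 and excluding them from
pairwise tests.

## The synthetic cohort

The generator plants every downstream effect in one self-contained bundle.
Defaults describe the study conditions all recovery guarantees refer to:
60 samples, 25% TE^deff, 80 genes (10% AT, 20% Class I at 50–200 kb, 20%
Class II at 2–15 kb, the rest neutral including the GZMK/PRF1 markers),
negative-binomial counts with dispersion 0.2 around gene means of ~50–500
normalized counts, a shared per-sample library factor (log-sd 0.2) and a
per-gene-per-sample biological factor (log-sd 0.4).

* **Isoform switching.** Every gene carries one full-length and one
  5'-truncated isoform. The log2 short/long usage ratio is −2.5 at baseline,
  shifted by +2 in TE^deff samples for AT genes. Usage itself is noisy:
  log-sd 1.0 for AT genes — high isoform-usage variance being the defining
  property of the class, and matching the several-log2-unit within-group
  spread seen in tumor cohorts — and 0.1 for non-AT genes (stable usage).
  This puts TE^deff samples near −0.5 and TE^prof near −2.5 around the −1
  cutoff.
* **Exon effects.** In TE^deff samples, Class I genes lose body-exon
  expression (×0.4, exons 2…n−1) and gain at the last exon (×4.0 — the sharp
  terminal peak of spurious 3' transcription); Class II genes gain ×2.0
  throughout; AT genes' 3' exons follow long-isoform usage.
* **Alignments.** 50 bp single-end reads per junction (Poisson mean 8 per
  sample), spliced with 10–40 bp anchors, unspliced across a boundary at the
  group retention rate (0.12 TE^deff vs 0.02 TE^prof); 3% of reads get
  MAPQ ≤ 20 to exercise the quality filter. Every gap coincides with an
  annotated intron by construction (and by test).
* **Coverage.** TSS-peaked tracks with per-gene body/TSS ratio around the
  group target (0.2 vs 0.8, log-sd 0.15).
* **Methylation.** β-values dip at the TSS (−0.08), rise in the body
  (+0.10) and dip at the TTS (−0.05) in TE^deff samples.
* **Survival.** Exponential times with a TE^deff hazard ratio of 3,
  administrative censoring at day 1500, drug annotations drawn from the
  shipped vocabulary plus targeted/other agents.

A fixed seed yields a byte-identical bundle (hashed in tests). What the
generator does *not* emulate: mapping ambiguity and positional coverage bias,
batch effects, FFPE degradation, paired-end fragments, realistic sequence
content, correlated gene–gene structure, and isoform diversity beyond two
isoforms per gene. Recovery results on it therefore demonstrate that the
estimators measure what they claim under controlled noise — not that the
thresholds transfer to any particular real cohort.

## Problem sizes

The test suite runs a reduced cohort (24 samples, 32 genes) for per-module
checks and five full default cohorts for the recovery guarantees; null
calibrations use 1000 null queries (200 permutations each) and 1000 null
survival simulations. These sizes give stable estimates (binomial s.e.
≈ 0.7% on a 5% rate at n = 1000) while keeping the whole suite around a
minute of runtime.

## Known limitations

* The AT-gene metric and its 0.90 quantile are package conventions, chosen
  for cohorts where switching-dominated genes are a minority; both are
  exposed as arguments so alternative metrics can be swapped in.
* Junction counting is annotation-anchored; unannotated junctions and
  paired-end mate correlation are out of scope.
* Enrichment p-values assume the permutation distribution is approximately
  normal (it is binomial-like; heavily discrete datasets at small query
  sizes will show conservative tails).
* The Cox model is univariate by design; confounder adjustment is out of
  scope.
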