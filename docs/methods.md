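# Methods

## The assay being modelled

Nonsense-mediated decay (NMD) suppresses transcripts carrying premature
termination codons. The screen this package analyses pools N isogenic
knockout clones in equal ratio (default N = 3: two *STAG2* frameshift
clones and one *TP53* frameshift clone), treats one compound per well of a
96-well plate, and sequences targeted amplicons in which each clone's
mutant allele is distinguishable from wild type. Reads carry a plate
barcode in the forward-primer region and a well barcode in the
reverse-primer region, so an entire multi-plate screen is pooled into one
sequencing run and demultiplexed computationally.

## Demultiplexing

Barcodes sit at fixed, manifest-declared offsets. A read is assigned on an
axis (plate or well) iff **exactly one** manifest barcode lies within
`max_mismatches` (default 1) Hamming distance of the observed k-mer; no
match or more than one match leaves the axis unassigned. The manifest
loader enforces pairwise Hamming separation greater than
`2 * max_mismatches` within each barcode set; under that invariant any read
whose true barcode acquired at most `max_mismatches` substitutions is
provably assigned to its true well, and the "exactly one within tolerance"
rule never ties. The production path uses a precomputed lookup over each
barcode's substitution neighbourhood (ties map to no-assignment at table
build time), which is exactly equivalent to the reference scan and is
tested as such.

## Allele classification

The amplicon panel is a small pseudo-reference: per gene, one wild-type
allele and one or more clone-specific mutant alleles, each carrying a
*diagnostic window* — by default the ±10 nt around the edit (the deletion
junction for a frameshift allele; the unedited site for wild type). A read
is classified by exact substring containment of these windows, searching
the read and its reverse complement: one window hit gives that allele,
several give AMBIGUOUS (excluded from both numerator and denominator of
every downstream statistic), none gives UNCLASSIFIED. Panel validation
enforces the stronger invariant that no allele's window occurs in any other
allele's full sequence in either orientation, so error-free reads classify
unambiguously by construction.

Exact matching makes the per-read classification probability
`(1 - eps)^L` for window length L. With the default 20–21 nt windows and
per-base substitution error `eps = 0.001`, about 98 % of reads classify to
their true allele; the remainder become UNCLASSIFIED, never a wrong allele
(mutating one window into another would require several coordinated
errors). Because the statistic is a within-well ratio, this loss is
unbiased to first order and the tests assert agreement between observed
accuracy and this analytic expectation rather than an arbitrary yield.
Quality scores are parsed but unused by default; an optional mean-quality
read filter exists and is off by default, since the assay defines no
quality gate.

## Pool-corrected mutant allele fraction

For mutant allele *a* observed with *m* mutant and *w* wild-type reads:

    raw MAF    = m / (m + w)
    corrected  = raw / e_a,     e_a = n_a * delta_a / N

with *n_a* carrier lines and zygosity dosage `delta_a` (0.5 heterozygous,
1.0 homozygous/hemizygous). `e_a` is the allele's expected maximum fraction
in the pool, so complete NMD blockade with equal per-cell expression scores
approximately 1. Zero depth propagates as *missing*, never 0; wells below
`min_depth` (default 200 reads per allele, a stability floor for ratio
estimates) are flagged low-coverage, excluded from null fitting, and
disqualify hit calls for their well.

## Null model and hit calling

Negative-control (DMSO) wells are pooled across all QC-passing plates; per
allele the null is summarised by the mean and sample SD (n−1) of corrected
MAF, and the hit threshold is `T = mean + k * SD` with `k = 5`. A single
fixed threshold can replace the per-allele thresholds to mirror reporting
that quotes one screen-wide cutoff. A library well is a hit iff the
corrected MAF of **every** mutant allele **strictly** exceeds its threshold
(boundary equality is not a hit), no allele is missing or low-coverage, and
the plate passed QC. Hits are reported sorted by the minimum per-allele
exceedance margin. Plate QC re-expresses the positive-control check on the
sequencing readout itself: mean positive-control corrected MAF must be at
least `q = 2` times the negative-control mean (the simulated
translation-inhibitor effect of ~3.5x comfortably passes); a zero negative
mean with positive signal counts as a pass (+inf ratio).

With Gaussian-like null fluctuations the per-allele tail at k = 5 is about
2.9e-7; requiring all three reporters jointly makes false positives
negligible, which the calibration study (10,000 simulated untreated wells,
five seeds, zero hits) confirms.

## Recovery analysis

Input is a per-variant table of mutant/wild-type read counts at the variant
site for four samples: biological duplicates of treated and control. A
variant passes the inclusion filter iff it is heterozygous and has at least
`d_min = 5` reads in **all four** samples (boundary inclusive). Per-sample
MAF is `m / (m + w)`; a configuration switch selects the `m / w`
(mutant-to-wild-type ratio) variant for compatibility with tools that
report that form, but the bounded total-denominator form is the default
everywhere. Replicates are aggregated as the arithmetic mean of per-sample
MAFs (replicates as equal units, not pooled counts), and

    FC = mean treated MAF / mean control MAF,    recovered iff FC >= 2.

If the control mean is exactly zero, 0.5 is added to the mutant and
wild-type counts of all four samples before recomputing — FC stays finite
and the ordering of variants is preserved. Recovery rates are stratified by
mutation class (frameshift indel, nonsense, other SNV, control SNP); a
class with no passing variants reports a missing rate, not 0. Each variant
is an independent unit; there is no gene-level collapsing. Whether a
variant is "predicted to undergo NMD" is accepted as an input annotation,
not computed.

Two groups of variants are compared with the closed-form 2×2 chi-squared
test of equal proportions; the Yates continuity correction (default,
matching R's `prop.test`) shrinks `|ad - bc|` by N/2 and is capped so the
statistic is never negative. The p-value uses the chi-squared distribution
with 1 df. Degenerate tables (zero row/column margin) are an error.

## Synthetic data

**Screen generator.** The mixture model assumes every line expresses each
gene equally per cell and that NMD suppression acts multiplicatively on
mutant-allele transcript output through the escape ratio theta. For allele
*a* of gene *g* the expected fraction among the gene's reads is

    frac_a = n_a * delta_a * theta / (theta * M_g + W_g)

with `M_g` the gene's total mutant dosage in the pool and `W_g = N - M_g`
its wild-type dosage; all mutant alleles of a gene share the well's theta,
and at theta = 1 the fraction reduces to `e_a`. Defaults encode the assay's
measured conditions: baseline escape `theta0 = 1/20` (*STAG2*) and `1/6`
(*TP53*), positive-control effect multiplier 3.5 (translation-inhibitor
scale), per-well depth ~ NegBin(mean 56,753, size 20 — moderate
overdispersion), per-base substitution error 0.001, and a per-well Gaussian
noise multiplier on theta (CV 2 %) standing in for plate/handling
variation. Reads are the allele amplicon flanked by the plate and well
barcodes with i.i.d. substitutions; sequencing-indel errors are off by
default since window classification, not gapped alignment, is the unit
under test. Compound effects multiply theta in the designated library
wells. Per-read truth travels in the read names, per-well truth in a JSON
manifest, and output is byte-reproducible for a fixed seed (gzip written
without timestamps). What this does **not** emulate: PCR duplicates and
chimeras, quality-score structure, primer-sequence artefacts, or
line-to-line expression differences — so passing tests demonstrate the
statistics and plumbing, not robustness to those real-data effects.

**Variant-table generator.** Per variant, a control MAF q is drawn from a
class-specific Beta distribution, per-sample depths independently from
NegBin(mean 200, size 8), control mutant counts from Binomial(depth, q) and
treated counts from Binomial(depth, min(1, q·f)) with the class's true fold
f (saturated draws are flagged in the truth manifest). Somatic classes use
Beta(4, 16) (mean 0.2): genome-wide NMD suppression is typically more
moderate than at engineered reporter loci, and this regime also gives the
documented detection properties (fold-3 variants detectable at depth ≥ 50)
analytic headroom. Common heterozygous SNPs use Beta(50, 50), i.e. balanced
allelic expression near 0.5, where a fold-change rule should and does stay
silent. Default true folds are 3 for truncating classes (frameshift,
nonsense), 1 for non-truncating SNVs and control SNPs.

## Numerical and interface choices

* Corrected MAF is computed exactly as `raw / e_a`; no rounding is applied
  internally. Serialized tables print floats at 6 significant digits; full
  precision is available from the API.
* Sample SD uses the n−1 denominator; fewer than two usable control wells
  per allele is an error unless a fixed threshold is configured.
* Hit ordering uses a stable sort on the minimum exceedance margin, so
  reruns are byte-identical.
* The simulators derive everything from one `numpy` Generator per run;
  identical config + seed gives bit-identical files, different seeds give
  different read orderings with indistinguishable summaries.
* Degenerate inputs: empty FASTQ gives an all-zero count matrix; truncated
  FASTQ records fail with the record index; an empty variant table writes
  empty outputs and exits cleanly; unknown alleles, classes, roles, or
  config keys are errors naming the offender.

## Problem sizes used in validation

The validation studies run at the conditions they describe: the clean
demultiplexing study uses one 96-well plate at exactly 10,000 reads/well;
null calibration uses 10,000 library wells plus 1,000 controls at the
full 56,753-read depth across five seeds; the spike-in study uses four
96-well plates at 20,000 reads/well with nine inhibitors spiked at 3x, 5x
and 10x; recovery studies use 500-variant tables at the default depth model
and a fixed-depth-1000 table for fold-change accuracy. Unit tests use
smaller plates (12–24 wells, hundreds to thousands of reads per well)
chosen so that every statistical assertion retains analytic margin.

## Known limitations

* Exact-window classification discards reads with any substitution inside
  the window; for error rates far above ~1 % or very long windows a
  tolerant matcher would be needed.
* The pool correction assumes equal line mixing and equal per-cell
  expression; systematic line imbalance would bias corrected MAFs by the
  imbalance factor.
* The null model is Gaussian-summary based (mean + k·SD); heavy-tailed
  plate artefacts would require a robust location/scale estimator.
* The recovery fold change ignores replicate disagreement; no dispersion
  or significance is attached to individual variant calls — only the
  class-level chi-squared comparison is inferential.
* No dose–response curve fitting (EC50) is performed; the dose table is
  reporting only.
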