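# Methods

## Model

A bulked-segregant experiment with two pools, each sequenced as one sample.
The unit datum is a biallelic site with per-pool (ref_depth, alt_depth,
genotype).  The pool's alternate-allele frequency (SNP-index) is
alt/(ref+alt), undefined — not zero — at zero coverage; undefined sites are
excluded from scoring rather than imputed.

Cross designs are encoded as the pair of expected causal-locus bulk
frequencies (m̄, w̄): F2 recessive (1, 1/3); backcross-then-selfed
(BCnF2) identical to F2; F2 dominant (2/3, 0) with the mutant bulk being the
dominant-phenotype bulk; RIL and DH (1, 0).  These follow from counting alt
alleles in the genotype classes that each phenotype bulk can contain.

### varBScore

Per window of n SNPs, each pool's deviation is summarised as

    SD = sqrt( Σ_j (x_j − expectation)² / (n − 1) ),

a root-mean-square deviation about the *design expectation*, not the window
mean — a pool sitting uniformly at the wrong frequency must register a large
deviation.  The sample-style n−1 denominator is retained from the
definition of the statistic; it is isolated in `sd_from_expectation` so the
convention can be swapped without touching anything else.  The window score
is the product −log10(SD_M + c) · −log10(SD_W + c).

Numerical choices:

- **Pseudocount c** (default 0.01, ladder 0.01/0.001/0.0001): bounds the
  score at (−log10 c)² when both SDs vanish. Larger c compresses the
  dynamic range; the default keeps the cap at 4, comparable across runs.
- **Clamping** (default on): SD + c can exceed 1 (SD reaches
  sqrt(n/(n−1)) for a maximally wrong pool), making a log term negative.
  When both expectations are extreme (RIL/DH), two negative terms would
  multiply into a spurious positive score at maximally *wrong* windows, so
  each term is floored at 0.  `clamp_negative=False` exposes the raw
  product.
- **df filter** (default 0.3): SNPs enter windows only if |M − W| > df.
  The causal geometry gives |1 − 1/3| = 2/3, so 0.3 keeps tightly linked
  SNPs while removing markers whose pools agree; it is a configurable
  choice, not a derived constant, and is echoed in every run's config file.
- **Windows**: fixed SNP count (default 20) advanced by a fixed step
  (default 5), per chromosome, trailing partial windows dropped. With S
  surviving SNPs the window count is floor((S − n)/step) + 1. Windows are
  reported as the span of their first/last SNP and plotted at the midpoint.

The ΔSNP-index comparison statistic (window mean of M − W) is computed on
the same windows.

### Region calling

No canonical rule exists for delimiting peak regions, so the caller is an
explicit convention: windows with varBScore at or above the q-quantile
(default 0.999) of the *positive* scores are selected and merged within a
gap (default 5 Mb, matching Mb-scale linkage blocks in a large, low-recombination
genome).  The quantile uses the discrete lower order statistic so the
threshold is an attained score; ties at the threshold are then included by
construction, and the near-maximal windows flanking a peak merge into one
region instead of the peak being represented by a single window.  The
threshold is a quantile rather than an absolute score because the score's
scale depends on c.  Cascade survivors inside called regions are ranked by
enclosing-region peak score, then by per-SNP |M − W|.

### Candidate cascade

Four pure predicates applied in a fixed order (allelic difference → EMS
type → effect → background), each recording its survivor count.  The
allelic-difference filter operates on genotype calls (opposite homozygotes
in either orientation); an optional allele-frequency fallback (≤0.1 / ≥0.9)
substitutes for missing calls.  The EMS-type test is literal on the VCF
forward strand: C→T or G→A, which already covers both strands of the
C:G→T:A transition — no reverse-complement expansion.  The retained effect
set is protein-altering terms (missense, start/stop loss, stop gain, coding
indels); it is configurable because annotation vocabularies vary.  The
background panel is any set of (chrom, pos, ref, alt) keys (from VCFs or a
4-column table); matching is exact on all four fields.

## Simulator

The generator emulates the study design the analysis assumes: a population
(default 431 individuals, a realistic F2 size for this kind of experiment)
segregating one recessive causal mutation on a 500-Mb chromosome carrying
2,000 markers; bulks of 30 extreme-phenotype individuals; pooled sequencing
at mean 70×.

- **Meiosis**: gametes from an F1 heterozygote with all mutant-line alleles
  in coupling; crossovers between adjacent markers occur with the Haldane
  fraction r = (1 − e^(−2d))/2 at 1 cM/Mb (no interference; the map-function
  interface admits alternatives).  Chromosomes are unlinked.  RIL/DH
  populations are doubled single gametes; residual RIL heterozygosity is not
  modelled.
- **Bulk selection**: mutant bulk from causal-homozygote individuals; wild
  bulk from the non-mutant phenotype classes ({AA, Aa} for F2), or from AA
  only under the "homozygous" selection variant that models F3-validated
  bulks.  True bulk frequencies are exact genotype means of the members.
- **Observation model**: per site and pool, depth ~ Poisson(mean_depth) and
  alt reads ~ Binomial(depth, af(1−e) + (1−af)e) with error rate e
  (default 0.005, a realistic post-filter mismatch rate; cross-mapping
  between homoeologous subgenomes can be approximated by raising it).
- **EMS spectrum**: each marker is a C→T/G→A transition with probability
  0.995 (the regime where such transitions constitute over 99% of
  mutations), otherwise a uniform non-EMS substitution; the causal site is
  always EMS-type and annotated `missense_variant`.
- **VCF genotypes**: pooled GT is thresholded from the *true* bulk
  frequency at 0.15/0.85 — an explicit convention, since real pooled-sample
  caller behaviour is not modelled; the truth file carries exact values.
- All draws flow through one `numpy.random.Generator` seeded from the
  config, so outputs are byte-reproducible.

What the simulator does not emulate: read-level errors and mapping, capture
efficiency bias, polyploid homoeolog cross-mapping structure, segregation
distortion, and multi-locus or incompletely penetrant phenotypes.  Passing
the recovery tests therefore shows the statistic behaves correctly under
its own model assumptions, not that those assumptions hold for any given
real dataset.

## Probe scoring

Canonical (strand-merged) 15-mers, because capture hybridisation is
strand-agnostic; k-mers containing N are skipped.  The probe score is the
mean of its constituent canonical k-mer counts (a fully unique 120-mer
probe scores exactly 1.0); max-count mode is provided since the aggregation
rule is a design choice.  Probes scoring above 100 are rejected as
repetitive; probes containing N are rejected as gap probes.  Target tiling
places probes every stride (default = probe length) with a final
right-aligned probe; per-target bases are partitioned exactly into covered
(under ≥1 retained probe), gap-lost (uncovered N bases) and repeat-lost
(uncovered non-N bases).  Close-match rescue against an external aligner is
out of scope; the status model leaves room for it.

## Problem sizes used in the test suite

Simulation-backed properties run 50 replicates of the default configuration
(1 × 500 Mb chromosome, 2,000 markers, 431 individuals, bulks of 30, 70×),
with the causal position drawn per replicate; the whole suite completes in
well under a minute.  The recovery property asks the rank-1 called region
to contain the causal locus in ≥ 45/50 replicates; the noise property asks
the fraction of windows > 50 Mb from the causal site exceeding half the
genome-wide maximum to be strictly smaller for varBScore than for
|ΔSNP-index| in ≥ 40/50.

## Known limitations

- The df filter and region-calling parameters materially shape results on
  sparse data; both are logged with every run for that reason.
- The allelic-difference filter assumes reliable pooled genotype calls; on
  F2 wild bulks (expected causal-site frequency 1/3) the causal site is
  heterozygous-like and survives region scoring but *not* the cascade —
  cascade-based candidate lists presume homozygous-selected (e.g. F3) wild
  bulks.
- Window scores at chromosome ends with fewer than window_n surviving SNPs
  are simply absent; no shrunken partial windows are emitted.
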