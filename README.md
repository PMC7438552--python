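# bseseq

Bulked segregant exome sequencing (BSE-Seq) analysis for mapping causal
mutations in large plant genomes such as bread wheat.

In a bulked-segregant experiment, DNA from the two phenotypic extremes of a
segregating population (e.g. 30 mutant-phenotype and 30 wild-phenotype F2 or
F3 plants) is pooled and each pool is sequenced as a single deep sample.
Away from the causal locus, both pools contain a random mix of parental
alleles; near it, phenotype selection drives the pools' allele frequencies
towards the values the cross design predicts.  `bseseq` locates that region
and reduces the variants inside it to a short list of candidate EMS-induced
mutations.

## The varBScore statistic

For an F2 population segregating one recessive causal mutation, Mendelian
segregation fixes the expected alternate-allele frequency of the causal site
at m̄ = 1 in the mutant bulk (all *aa*) and w̄ = 1/3 in the wild bulk
(*AA*:*Aa* = 1:2).  For a window *k* of *n* consecutive SNPs with observed
mutant/wild bulk frequencies M<sub>kj</sub>, W<sub>kj</sub>:

    SD_M = sqrt( Σ_j (M_kj − m̄)² / (n − 1) )
    SD_W = sqrt( Σ_j (W_kj − w̄)² / (n − 1) )

    varBScore_k = −log10(SD_M + c) × −log10(SD_W + c)

with pseudocount c (default 0.01), so a window sitting exactly at both
expectations scores (−log10 c)² = 4.  Because the product needs *both* pools
at expectation simultaneously, single-pool sampling noise — the dominant
source of false peaks in the plain ΔSNP-index = mean(M − W) — cannot
produce a high score.  Windows are ranks of SNPs (default 20 SNPs advanced
by 5), applied after a differentiation filter |M − W| > df (default 0.3).

Also included:

- **candidate filter cascade** — opposite-homozygote (allelic-difference)
  filter → EMS-type filter (C→T / G→A) → protein-altering-effect filter →
  background-panel filter, with per-stage counts;
- **region caller** — quantile threshold over positive window scores plus
  interval merging, and ranking of cascade survivors inside regions;
- **population simulator** — F2/backcross/RIL/DH meiosis with Haldane
  recombination, phenotype-selected bulks, Poisson×binomial pooled read
  sampling, and an EMS mutation spectrum, emitting a standard two-sample
  VCF plus ground truth;
- **probe designer** — genome 15-mer histogram scoring of capture probes
  with the score-100 rejection rule.

## Worked example

Simulate an experiment (one 500-Mb chromosome, 2,000 markers, bulks of 30
drawn from a 431-plant F2, 70× depth) and map the causal locus, which this
seed places at 250,000,000 bp:

```sh
bseseq simulate --out-dir demo/sim --seed 11
bseseq score demo/sim/simulated.vcf --out-dir demo/score
```

```
INFO bseseq: 2001 variants read, 2001 after QC, 69 windows, 1 regions
```

`demo/score/regions.bed` contains the single called region:

```
chr1	243841639	250891340	region_1	1.6596287296423404
```

which spans the true causal position (`demo/sim/truth.tsv` records it at
chr1:250,000,000 with true mutant-bulk frequency exactly 1.0).  The
top-scoring windows in `demo/score/windows.tsv` sit inside it:

```
chr1	246134445	250891340	248512892	20	0.0640	0.0241	1.6596	0.6226
chr1	243841640	249704691	246773165	20	0.0803	0.0191	1.6048	0.6031
```

Reading a row: across these 20 SNPs the mutant bulk deviates from m̄ = 1 by
SD ≈ 0.02 and the wild bulk from w̄ = 1/3 by SD ≈ 0.06, giving
varBScore ≈ 1.66 (cap 4.0); the mean ΔSNP-index ≈ 0.62 approaches its causal
expectation of 2/3.  `bseseq filter` then reduces the differentiated SNPs to
EMS-type, protein-altering, background-free candidates, and `bseseq report`
runs both steps and ranks the survivors by enclosing-region score.

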