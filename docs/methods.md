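# Methods

`sweepscape` implements the analytical chain used to detect domestication
selective sweeps in two-population whole-genome data and to ask whether the
swept regions and frequency-divergent sites are enriched for regulatory
genome features. Every input can be generated by the built-in simulator, so
the full chain runs end to end with no external data.

## The scan model

**Per-site differentiation.** For each biallelic SNP the two-population
Weir–Cockerham variance-components estimator is computed,

    theta = a / (a + b + c),

where `a`, `b`, `c` are the among-population, among-individual and
within-individual components evaluated from the per-population sample sizes
n_i, allele frequencies p_i and observed heterozygote fractions h_i. The
estimator is undefined (and excluded from window means) when either
population has fewer than two called genotypes or the pooled site is
monomorphic. Negative values of theta are retained in window means: they
are part of the estimator's sampling distribution, and clipping them would
bias bin averages upward.

**Windowing.** Statistics are accumulated in 20 kb bins sliding by 10 kb
(both configurable; the bin width must be a multiple of the step). Only
bins fully inside a chromosome are formed. Bins with fewer than 20 SNPs
carry their SNP count but no statistics.

**Nucleotide diversity.** The default per-bin pi is the sum over sites of
the unbiased expected heterozygosity `2 p (1-p) * 2n/(2n-1)` (n = called
diploid genotypes) divided by the bin width, i.e. per-bp diversity under
the standard sample-frequency estimator. A literal alternative — the count
of sites carrying at least one heterozygous genotype per bp — is available
via `pi_mode="het_count"` for users who want the simpler "heterozygous SNP
per bin size" bookkeeping; the two differ by a roughly constant factor at
these sample sizes and give the same outlier ranking.

**Direction signal.** `ln_ratio = ln(pi_wild / pi_dom)` per bin; positive
values mark diversity loss in the domestic population, the expected
footprint of a domestication sweep.

**Outlier calling.** Both statistics are Z-transformed over unmasked bins
(mean and SD of the realized genome, ddof=1). A bin is a domestic-direction
outlier when *both* Z(mean FST) and Z(ln ratio) exceed the upper one-sided
normal quantile for the chosen alpha; wild-direction outliers use the lower
tail of the ln ratio symmetrically. The default alpha is 0.001 one-sided
(Z > 3.090). Two conventions circulate for describing this style of cutoff
— a plain Z-test level and a Bonferroni-style family level — and they do
not coincide; we therefore expose alpha as a parameter and have
`call_outliers` report the *raw* statistic thresholds implied by the
Z cutoffs, which is what a reader needs to compare scans. Window FST is the
arithmetic mean of per-site theta ("average of ratios") by default, with a
ratio-of-averages mode (`fst_mode="ratio_of_averages"`) that sums the
variance components before dividing.

**Regions.** Flagged bins on the same chromosome within 50 kb are merged
by single linkage; each region is annotated with the closest gene
(distance 0 when overlapping; ties broken toward the smaller gene start).

## QC cascade

Seven post-calling filters run in a fixed order with first-hit attribution,
so the per-rule removal counts always partition the input: (1) read depth
outside [5x, 2x per-sample mean] in more than half the samples; (2) MQ < 30
or BQ < 20; (3) within 5 bp of an indel; (4) of any SNP pair closer than
4 bp, the lower-QUAL member; (5) tri-allelic records; (6) call rate below
90%; (7) exact one-sided Hardy–Weinberg test toward heterozygote excess at
p < 0.001, pooled over populations. The depth rule is evaluated per sample
against each sample's own mean depth because a single site-level depth
threshold conflates coverage heterogeneity among samples with site-level
artefacts. The heterozygote-excess test sums the exact conditional
probabilities of heterozygote counts at least as large as observed; note
the minimum attainable p at a fully heterozygous balanced site is
`2^n / C(2n, n)`, so the rule cannot fire below ~13 diploid samples.
Close-pair ties at equal QUAL keep the later site — an arbitrary but
deterministic choice.

## Comparative annotation transfer

Intervals project through UCSC-style alignment chains: an interval maps
iff at least `min_match` (default 0.1) of its bases fall in aligned blocks
of a single best-scoring chain; the projected interval is the span of the
block images on the target, with strand-reversed chains flipped into
forward coordinates. Intervals claimed by two or more qualifying chains
are reported `split` and rejected rather than stitched, matching the
conventional lift-over behaviour. The reciprocal filter then keeps a
projection only if projecting it back with the reverse chains lands on the
source chromosome and recovers at least `min_back_overlap` (default 0.5)
of the source interval — "high-quality" reverse mapping is not a standard
quantity, so we use the common reciprocal-best threshold and expose it.

## Enrichment statistics

* **Recovery rate**: percent of predicted intervals overlapped by >= 1
  experimental interval; displayed integer-truncated (85% means
  13,767/16,098) with the exact fraction retained.
* **Shuffle null**: features are re-placed uniformly at random
  (length-preserving, non-overlapping, cross-chromosome, chromosome chosen
  proportional to length) n times; the empirical p is `(k+1)/(n+1)` where
  k counts randomisations with overlap >= observed. The +1 correction
  keeps p positive and unbiased-conservative at finite n. The overlap
  statistic counts feature intervals hitting the observed set by default;
  a base-pair mode is available and is the better-behaved (nearly
  continuous) choice for calibration checks.
* **Locus overlap**: with a universe of genome bins and a reference subset
  (the outlier bins), a universe bin is a "hit" when it overlaps >= 1
  query interval; the one-sided Fisher exact test on
  (ref&hit, ref&~hit, other&hit, other&~hit) asks for enrichment, with
  Benjamini–Hochberg correction across query sets and a q < 0.05
  significance line. Degenerate tables (hits covering all or none of the
  universe) are flagged and carry p = 1.

## Allele-frequency divergence

Per-site AF is the alternate-allele count over called alleles, per
population; dAF = |AF_dom − AF_wild| over sites segregating in both
populations (absolute difference, so allele labelling is irrelevant).
Sites are assigned to dAF bins of width 0.1 (left-closed, top bin closed
at 1.0 — the width is configurable). Per feature f and bin b,

    M(f, b) = log2( p(f|b) / p(f) ),

with cells in empty bins undefined rather than zero, and a per-feature
chi-squared test of the observed per-bin counts against the expectation
from the overall bin proportions (df = populated bins − 1). The exonic
perturbation control shifts the dAF of exon-overlapping sites toward 1 by
an additive delta (clipped) and re-runs the M-value analysis to measure
how much apparent enrichment physically interleaved classes inherit; a
permutation mode (shuffling dAF among exonic sites) is provided as a
no-signal variant, since the exact recipe for such controls is not
standardised.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis relies on:

* **Populations**: 67 domestic and 17 wild diploid samples (defaults).
* **Allele frequencies**: an ancestral frequency drawn from a neutral-like
  density proportional to 1/p truncated to [1/(2n), 1−1/(2n)], plus
  independent Gaussian drift noise (SD 0.08, clipped to [0,1]) per
  population. This yields the high between-population AF correlation of
  closely related domestic/wild pairs without a coalescent.
* **Diversity calibration**: sites are placed by a Poisson process whose
  rate is calibrated against the AF law so expected per-bp heterozygosity
  matches pi_wild = 0.0020; realized mean heterozygosity is then matched
  per population (pi_dom = 0.0016) by solving for a contraction/expansion
  of AFs around 0.5 on the drawn sites. The expansion (kappa > 1) fixes a
  fraction of domestic sites outright, which also produces wild-private
  polymorphism, as observed in such pairs.
* **Sweeps**: planted by direct AF manipulation inside declared windows —
  the alternate allele rises by `delta` (default 0.8) in the domestic
  population, and a fraction `1 − f_pi` (default f_pi = 0.05) of sites
  lose polymorphism outright, fixing at the nearer post-shift state.
  Retained sites are capped at AF 0.99 so they stay segregating and carry
  sweep-grade dAF. Direct manipulation gives exact control of effect size
  for power tests, which forward simulation would not.
* **Features**: gene models with CDS/intron/UTR structure, promoters
  (TssA) at the TSS, genic enhancers inside gene bodies, distal enhancers
  offset ~40 kb from the TSS, proximal elements within 1.5 kb and distal
  elements ~100 kb away — reproducing the distance-to-TSS ordering that
  real chromatin-state annotation shows.
* **Peaks**: each predicted interval is recovered with probability r by a
  jittered, centre-anchored peak; decoy peaks are placed uniformly.
* **Chains**: per chromosome, a walk alternating geometric-length aligned
  blocks with short indels produces a forward chain, its exact reciprocal
  and the implied donor genome layout. We derive the donor layout from
  the walk (rather than taking it as input) because an externally fixed
  target layout is generally inconsistent with a random indel process.

Deliberately absent: linkage disequilibrium beyond window-level AF
sharing, recombination-rate variation, mutation-rate heterogeneity,
sequencing error, and any correlation between sweep placement and gene
density. Passing tests therefore certify the *statistical machinery* —
estimators, calibration, thresholds, projections, contingency tests — not
the biological realism of any particular dataset; on real data the
outlier thresholds are data-dependent quantities, as the reported raw
thresholds make explicit.

## Numerical choices and degenerate inputs

* Internal coordinates are 0-based half-open everywhere; VCF positions are
  converted at the boundary (original 1-based kept in `pos1`). Chromosome
  names match by exact string comparison.
* theta at a site with zero total variance (a+b+c = 0) is NaN, never 0/0.
* Z-transforms error on zero variance rather than emitting infinities.
* `ln_ratio` is defined only when both per-bin pi values are positive.
* M-value cells in empty bins are NaN, not 0; the chi-squared uses only
  populated bins.
* The shuffle places each interval with bounded retries (default 1000) and
  errors on infeasible packings instead of looping forever.
* All generators and permutation tests take explicit seeds; the pipeline
  derives one sub-seed per stage from the run seed, and a rerun with the
  same configuration reproduces every output file byte for byte.

## Default problem sizes

The default synthetic genome is two 10 Mb chromosomes (1,998 sliding
bins, ~160k SNPs before QC) with five planted 60 kb hard sweeps — large
enough that genome-wide Z thresholds are stable and each sweep spans
multiple bins, while a full pipeline run stays well under five minutes on
a single CPU. Validation uses 200 shuffle randomisations by default
(1000 in the original protocol; the empirical-p resolution scales as
1/(n+1) and can be raised via `n_shuffles`).
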