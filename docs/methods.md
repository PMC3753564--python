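# Methods

## The unit of analysis

Every computation operates on a *paired site*: one 1-based genomic position
with a reference base and two read stacks (normal, tumour), each read
carrying its called base, phred base quality, phred mapping quality, strand,
and two flags (the read's alignment deletes this base; the read has an
indel immediately adjacent). Reads spanning a deletion count towards depth
but never towards allele counts — a deleted base has no base call. N calls
are excluded from allele counts but kept in depth. The variant allele at a
site is the single most common non-reference base; ties are broken in fixed
A<C<G<T order for determinism, and additional alternate alleles are
ignored (multi-allelic sites are out of scope).

## Calling models and their assumptions

All four callers reduce genotypes to reference/variant (AA, AB, BB per
sample; nine joint genotypes) and assume a diploid genome — none models
aneuploidy or copy number, so calls are confounded with any such events,
exactly as in the tools they emulate.

**Shared kernel.** P(read | g) = m·[f_g·P(b|ref) + (1−f_g)·P(b|var)] +
(1−m)/4, with P(b|a) = 1−e if b=a else e/3, e = 10^(−baseQ/10),
m = 1 − 10^(−mapQ/10). f_g defaults to (1−ε, 0.5, ε) with ε = 10⁻³; ε
absorbs residual error in nominally homozygous genotypes. An unmapped read
(mapQ 0) contributes a flat 1/4 and carries no information.

**varscan.** Observed variant frequency ≥ `min_var_freq` (0.20) *and* at
least `min_variant_reads` (2) variant reads give a variant genotype
(homozygous above 0.75); otherwise homozygous reference. Where the two
samples' heuristic genotypes differ, a one-tailed Fisher exact test is run
on the (sample × allele) table — tumour-variant enrichment for the somatic
direction (normal AA), normal-variant enrichment for the LOH direction
(normal AB); normal BB mismatches are classed unknown. The p-value is
computed as the exact hypergeometric tail (identical to one-sided
`fisher_exact`, but vectorisable); score = 1 − p, emitted at p ≤ 0.05.
The p threshold and minimum read support are conventional defaults; the
original tool's purity-adjusted thresholds are out of scope.

**somaticsniper.** Joint posterior P(g_N, g_T | D) ∝ P(D_N|g_N)·P(D_T|g_T)
·P(g_N)·P(g_T|g_N) with P(g_N) = (1−3θ/2, θ, θ/2) at θ = 10⁻³ and a
genotype-change prior that keeps the genotype with probability 1−μ and
splits μ = 10⁻⁴ evenly over the two other genotypes (no transition
structure is claimed by the original description). The somatic score
S = round(−10·log10 Σ_g P(g_N=g, g_T=g | D)), capped at 255. Note a
structural property verified by the exact nine-term oracle: at moderate
depth S is bounded by the (AB,AB) diagonal term — a heterozygous normal
emits an all-reference stack with probability 0.5^depth·θ — so S reaches
the cap only for deep normal stacks (around depth 90 at these priors), not
at depth 50.

**jointsnvmix.** Mixture over the nine joint genotypes: π ~ Dirichlet(δ);
per sample and genotype the reference-read count a out of depth d is
Binomial(d, μ_g) with Beta(α_g, β_g) priors. MAP-EM: the E-step computes
responsibilities γ_i(j,k) ∝ π_jk·Bin(a_i^N|d_i^N, μ_j^N)·Bin(a_i^T|d_i^T,
μ_k^T); the M-step applies the usual MAP updates (pseudocounts minus one in
numerator and denominator). The penalized log-likelihood (data likelihood
plus Dirichlet and Beta log-priors) is evaluated each iteration and
asserted non-decreasing; training stops when the improvement falls below
`tol` or at `max_iter`. Default pseudocounts: α/β per genotype (AA
1000/10, AB 500/500, BB 10/1000), δ = 10⁶ on (AA,AA) and 2 elsewhere —
a deliberately weak off-diagonal prior that reproduces the qualitative
over-calling of somatic probability this model family is known for; the
off-diagonal δ mass and the training subset fraction (default 1.0, with
fixed-seed subsampling below that) are configurable because the original
description quantifies neither. JSM1 scores sites with the binomial count
kernel; JSM2 swaps in the per-read quality-weighted kernel with μ_g as the
reference fraction — in the noise-free limit the two coincide up to a
genotype-independent constant, which is asserted in the tests.

**strelka_like.** An explicitly simplified rendition of the
marginalised-somatic-fraction idea: the normal genotype posterior uses the
shared kernel and the θ prior; the non-somatic hypothesis generates tumour
reads at the normal genotype's allele fraction; the somatic hypothesis
(prior μ = 10⁻⁴) marginalises the tumour variant fraction s uniformly over
the grid {h, 2h, …, 1} with h = `grid_step` = 0.01. The reported score is
the joint posterior of the most likely normal genotype and the somatic
event. Grid coarseness perturbs the raw posterior by well under 0.02
(asserted against a 5× finer grid). Strand bias and realignment terms of
the real tool are delegated to the filter suite; no LOH hypothesis is
modelled, so this caller emits somatic candidates only.

**Scores.** A candidate's `score` is the probability of the event class it
reports. Callers whose native output is phred-scaled (somaticsniper,
strelka_like) quantize the score through the integer phred value, so
score = 1 − 10^(−phred/10) holds exactly and score histograms show the
characteristic phred gaps; the unrounded posterior is kept in `raw_score`.
Inclusion thresholds for the raw candidate sets are deliberately low
(varscan p ≤ 0.05; somaticsniper S ≥ 15; jointsnvmix probability ≥ 10⁻³;
strelka_like phred ≥ 1) to generate large candidate sets for the
comparison stage.

## Filter suite

Eight removal rules, evaluated on the variant reads of the relevant sample
(tumour for somatic candidates, normal for LOH candidates), at any base
quality: (1) all variant reads on one strand; (2) mean variant base quality
< 15; (3) no variant base quality over 30; (4) mean variant mapping quality
< 15; (5) no variant mapping quality over 40; (6) more than two other
candidate positions (from any caller) within 50 bp either side; (7)
spanning-deletion reads > 20% of overall depth in either sample; (8)
adjacent-indel reads > 20% of reads in either sample. Readings chosen
where the plain wording leaves room: "over 30"/"over 40" and "less than 15"
are strict; the 50 bp window is inclusive and excludes the site itself;
overall depth in rule 7 includes the spanning-deletion reads themselves.
With zero variant reads the strand and quality rules pass vacuously. A
site is removed if *any* rule fails; for pass-rate reporting the strand
rule is applied first and the other seven are scored on its survivors,
while the overall verdict is order-independent.

Under fair strand assignment a site with v variant reads is 100% one-sided
with probability 2·(1/2)^v = (1/2)^(v−1) (both all-forward and all-reverse
outcomes count). Summing this over candidate sites gives the expected
number of one-sided sites from random sampling alone; the observed excess
over this Poisson-binomial null is the signature of one-strand systematic
error.

## Synthetic data generator

The generator emulates the statistical structure the analysis needs from a
matched exome pair, per site and per read:

* per-site truth class: clonal somatic (expected tumour VAF = purity/2 for
  a heterozygous mutation in a diploid tumour), subclonal somatic (tumour
  VAF drawn uniformly from `subclonal_vaf_range`, not additionally scaled
  by purity), germline heterozygote/homozygote (VAF ½ / 1 in both
  samples), systematic-error site, or background;
* per read: true allele ~ Bernoulli(expected VAF), strand ~ Bernoulli(½),
  base and mapping qualities from configurable discrete distributions, the
  observed base corrupted to a uniformly-chosen other base with probability
  10^(−baseQ/10); at systematic-error sites, reads on the one susceptible
  strand are additionally flipped to the error base with
  `systematic_error_read_rate`, in both samples;
* depth per sample ~ Poisson(mean) or negative binomial;
  `normal_contamination` (default 0) lets a fraction of tumour signal leak
  into the normal.

Defaults are the study conditions used throughout the tests and the
acceptance script: 5×10⁴ sites, mean depth 60 in both samples (exome-like),
purity 0.8, 30 clonal + 30 subclonal somatic SNVs with subclonal VAF
U(0.03, 0.15), germline heterozygote rate 10⁻³ (human-scale) and homozygote
rate 5×10⁻⁴, systematic-error site rate 10⁻³ with per-read rate 0.1,
spanning-deletion and adjacent-indel read rates 0.01, HiSeq-like base
qualities (mostly Q30–40 with a small low tail) and bwa-like mapping
qualities (80% at 60). Sites are laid out every 100 bp on one chromosome.

The **split null** simulates one non-cancer sample at 2× the normal depth
with no somatic truth and assigns each read independently to the
pseudo-normal or pseudo-tumour with a fair coin (whether real BAM splits
preserve read pairs is unspecified, and at the pileup level the read is the
natural unit), so every somatic call on the pseudo-pair is a false
positive.

What the generator does **not** emulate: exome capture geometry and the
one-direction coverage tails outside targets, GC and mappability bias,
read-position error profiles, error motifs (homopolymers, GG motifs),
indels beyond per-read flags, and copy number. Passing tests therefore
demonstrate correctness of the models and the internal consistency of the
statistics under the stated noise structure — not performance on real
sequencing data, where systematic error is richer than the one-strand
mechanism simulated here.

## Numerical choices and degenerate inputs

All posteriors are computed in log space and normalised with logsumexp;
posterior vectors sum to 1 within 10⁻⁹. Phred-to-probability uses a
precomputed lookup for integer qualities. EM mixture weights are clipped
away from zero and renormalised; μ is clamped to (10⁻⁶, 1−10⁻⁶) with a
warning when degenerate (≤ 1) pseudocounts would push an update out of
range. Zero-depth samples: varscan makes no call; the Bayesian callers use
a uniform (empty-product) likelihood, so with no reads at all the posterior
equals the prior (somaticsniper then reports S = 0, strelka_like the
somatic prior). Fisher p-values are clipped at 1. The phred score caps at
255 to keep probabilities representable.

## Concordance statistics

The comparison matrix holds each caller's score and class per site.
Overlap counts partition sites by the exact subset of callers reporting
them (the partition provably sums to the number of distinct sites).
Pairwise Pearson correlations use sites shared by a pair (≥ 3 required;
zero-variance score vectors reported as undefined — the varscan score
degenerates to 1.0 on strong candidate sets, which is itself informative).
Threshold sweeps report, per caller and score threshold, the retained
count, the fraction found by any other caller *at any score*, and the
fraction present in a supplied known-site list — the dbSNP-proportion
analog, which on synthetic data is the germline truth positions and on
real data a user-supplied BED/VCF. VAF profiles sort each caller's unique
sites by tumour variant proportion and plot both samples' proportions
against the scaled index i/(n−1) (formula chosen for comparability across
sample sizes). Pass-rate tables use a two-proportion chi-square test with
continuity correction for pairwise differences at α = 0.05 (Fisher exact
available as an alternative; no particular test is canonical for this
table). Truth-based evaluation defines sensitivity per true-VAF bin as the
fraction of somatic truth sites receiving a somatic call with score ≥ 0.95,
and germline leak as the fraction of a caller's somatic calls landing on
germline truth sites.

## Problem sizes

The test suite and the acceptance script scale the studies to run on one
CPU in a few minutes: the caller-character study uses the full default
5×10⁴ sites; the strand-bias calibration uses 10⁴ error-driven candidate
sites plus 500 small replicates for the systematic-error excess; EM
parameter recovery uses 10⁴ sites at depth 30 drawn from the generative
model; the demonstration pipeline uses 5×10³ sites with a 2×10³-site split
null; the exhaustive Fisher check covers every 2×2 table with total ≤ 60.
Seeds are fixed throughout (20130709 in the tests; derived from `--seed`
in the acceptance script), and a fixed seed reproduces byte-identical
pileups and pipeline manifests.

## Known limitations

The four models are desk-scale re-implementations sharing one kernel, not
bit-compatible ports: real VarScan heuristics (depth gates, purity
adjustment), SomaticSniper's full base-space genotypes, JointSNVMix's exact
hyperparameter schedule and Strelka's realignment, strand-bias and noise
terms are all absent or simplified, so absolute candidate counts and scores
are not comparable with the original tools — only the qualitative
behaviours (detection limits, score calibration, error susceptibility) are
expected to transfer, and those are what the tests assert. LOH candidates
are labelled but not biologically interpreted. The transition–transversion
ratio is deliberately not implemented as a quality metric.
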