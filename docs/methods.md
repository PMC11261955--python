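# Methods

This note records the models, numerical choices and known limits of the
package, in the order the pipeline runs them.

## Summary-statistics conventions

Positions are 1-based inclusive on GRCh38; the variant key is
`(chrom, pos, ref, alt)` with `alt` the effect allele. Association
strength is always the 1-df chi-square `(β/se)²`, never recovered by
inverting the p-value: the strongest hits in a biobank-scale scan have
p-values far below double underflow (< 1e-300), where `(β/se)²` remains
exact. P-values are produced from the chi-square survival function only
for reporting.

Cross-cohort harmonization matches variants on the exact key or with
ref/alt swapped (the swapped record's β is negated and its allele
frequency complemented). Strand flips are never attempted: both inputs
are assumed aligned to the same build, and silently "fixing" a strand-
ambiguous A/T or C/G pair is more dangerous than dropping it. Mismatches
are excluded and counted. Variants present in only one cohort are kept
and flagged — population-enriched low-frequency alleles are often
genuinely absent from one biobank, and dropping them would bias the
low-frequency end of the scan.

The MHC (chr6:28,510,120–33,480,577, GRCh38) is excluded from
variant-level counting by default: its LD structure breaks the pairwise
independence logic of clumping.

## Inverse-variance-weighted meta-analysis

Fixed effects only: weights `wₖ = 1/seₖ²`, pooled effect
`Σwₖβₖ/Σwₖ`, pooled SE `(Σwₖ)^(-1/2)`. A Cochran's Q column is emitted
for diagnostics but never used for filtering; no random-effects or
sample-size-weighted variants are offered. Single-cohort records pass
through unchanged with `n_cohorts = 1`.

## Dynamic-threshold LD clumping

A variant at LD r² to a lead of strength χ² carries expected transferred
(non-centrality) signal r²·χ². The admission threshold for secondary
signals near an admitted index is therefore `T = min(0.1, 5/χ²)`: any
candidate whose residual signal could still exceed a chi-square of 5 is
not counted as independent. The ambient +1 expectation of a null
chi-square is deliberately not added — the rule concerns transferred
signal, and the 0.02 boundary at χ² = 250 pins the algebra to `5/χ²`.

Selection is greedy by ascending p (chi-square breaks underflow ties,
then position, then alleles, so output is deterministic). Three rules
block a candidate:

1. r² ≥ T of any already-admitted, more significant index within ±2 Mb;
2. any admitted index with T < 0.02 (χ² > 250) suppresses *all*
   candidates within ±1 Mb regardless of r², because r² estimates that
   small are unreliable exactly where residual signal is still large;
3. no interval of width 1 Mb may contain more than two admitted indexes
   (`max_per_mb`, a config override for the rare conditionally-verified
   triple signal).

The ±2 Mb screen is re-evaluated around every admitted index, not only
the locus lead — slightly stricter than anchoring on the primary.
Unknown LD pairs default to r² = 0 (independence), which is permissive
for counting; the triplet reader warns when pairs are missing. Admitted
indexes within 1 Mb are single-linkage chained into loci.

The entire rule set is pinned by a test that compares the greedy
implementation against an independent brute-force re-evaluation on
hundreds of random blocks (random positions, random PSD r² matrices,
random signal strengths).

## Line-model mixture

### Prior covariance

A component with scale s, slope b, correlation ρ places on the true
effect pair the covariance

    Σ = s²·u uᵀ + s²(1−ρ)/(1+ρ)·v vᵀ,
    u = (1, b)/√(1+b²),  v = (−b, 1)/√(1+b²).

This eigen-axis construction has the properties that make the three
parameters interpretable: ρ = 1 collapses the prior exactly onto the
line; at |b| = 1 the parameter ρ equals the Pearson correlation of the
two components; and a slope-0 group retains a small second-trait
variance s²(1−ρ)/(1+ρ) ≈ 0.005·s² at ρ = 0.99, which is what lets the
"primary-trait-only" group absorb variants with incidental small
secondary effects instead of leaking them to the shared group. Scale
0.6 is calibrated so that ~95% of true effects (two Gaussian SDs) lie
within 1.2 on the log-odds scale; the 2-SD coverage 0.9545 is asserted
analytically in the tests.

### Likelihood and EM

Observation noise is independent Gaussian with the reported SEs, so the
marginal likelihood of an observed pair under a component is a bivariate
normal with covariance Σ + diag(se₁², se₂²), evaluated in closed form
(2×2 determinant algebra, vectorized over variants). Scale and
correlation are never estimated — they are modelling choices, not
identifiable nuisances at a few hundred points.

EM: E-step responsibilities from current proportions; M-step proportions
to mean responsibility, each free slope to the bounded scalar maximizer
(golden-section/Brent, bounds ±10, xatol 1e-6) of its responsibility-
weighted log-likelihood. A candidate slope step is accepted only if it
does not lower the weighted objective, keeping the ascent property exact
rather than up-to-optimizer-wobble; the log-likelihood trace is stored
and asserted non-decreasing. Convergence at gain < 1e-6 or 300
iterations. Five restarts with free slopes drawn Uniform(−2, 2) from the
seeded generator guard against the slope-labelling local optimum in
free-two-slope fits; the best restart is returned.

### Model comparison

Nested fits are compared by 2·Δloglik with df = difference in free
parameters (free slopes + mixing proportions) against a chi-square
reference. The null sits on a boundary (a vanishing proportion), where
that reference is not exact; results carry `boundary_nonregular=True`
rather than a corrected null, because the comparisons of interest are
decided by dozens of log-units, far from the regime where boundary
corrections matter.

### Membership posteriors

Analytic posteriors are the E-step responsibilities at the fitted
parameters. The Gibbs sampler alternates label draws
zᵢ ~ Categorical(γᵢ(π)) with π ~ Dirichlet(α + counts), α = 1 by
default, 2000 sweeps with 500 burn-in, and reports mean label
indicators; it integrates over uncertainty in the proportions, which
the analytic posteriors condition away. A seed is mandatory. With
proportions held fixed the sweep means converge to the analytic
posteriors (law-of-large-numbers check in the tests at 10,000 sweeps).
One caveat found during testing: when two components are identical the
data carry no information about π, its marginal posterior is flat, and
the label chain mixes slowly — tolerances for that degenerate symmetric
case reflect the chain's true Monte-Carlo error, not the nominal
binomial one.

## Dissection statistics

* Bonferroni thresholds: strict = FWER/n, loose = expected-by-chance/n.
* Overlap reports count secondary-scan hits below each threshold among
  the index variants the secondary scan actually covers (the report
  always states its own denominator); direction concordance is
  sign(β₁)·sign(β₂) > 0 among loose hits, zero effects counted
  discordant.
* Sharing proportion = mean shared-group posterior over associations
  with primary p below a cutoff (default 1e-11, the confidently
  classifiable top of the distribution). Soft averaging is the
  lower-variance choice; a `hard` flag counts posteriors > 0.5 instead.
  Under the true model the mean posterior is unbiased for the true
  mixing proportion (verified at n = 2000).
* Membership–membership association is Spearman's rank correlation with
  average ranks for ties; two-sided p by t-approximation, or exact
  permutation enumeration below n = 10.
* Coding-association categories from the best r² of an index variant to
  any protein-coding variant: > 0.95 (a coding lead is encoded r² = 1),
  0.70–0.95, other; boundaries follow the strict-inequality convention
  at the upper cut. The low-frequency enrichment 2×2 (minor allele
  frequency < 5%) is tested with two-sided Fisher's exact
  (point-probability method) because the smallest expected cell is
  marginal for a chi-square; the test suite pins scipy's p against a
  direct hypergeometric-tail enumeration.

## Synthetic data

`simulate_effect_pairs` draws group labels from the configured
proportions, true pairs from each group's prior covariance (sampling
along the line when ρ = 1 makes Σ singular), SEs from
Uniform(se_low, se_high) and observed effects with independent Gaussian
noise — exactly the generative model the classifier assumes. Defaults
are the study conditions: scale 0.6, ρ 0.99, a slope-0 group plus a
slope-0.447 shared group, SEs on [0.01, 0.05].

`simulate_ld_block` uses exponential-decay correlation
r = exp(−decay·distance) (all-positive, a simplification documented
here; the clumping rule consumes only r²) and draws Z ~ N(μ, R) with
μᵢ = r(i, causal)·√χ²_causal, so E[Zᵢ²] = r²χ² + 1 — the relation the
clumping threshold is built on, asserted empirically in the tests.

`simulate_two_cohorts` derives two noisy scans with an effective-size
ratio and a seeded population-private variant subset, exercising the
single-cohort pass-through of the meta-analysis.

What the generators do *not* emulate: allele-frequency-dependent effect
sizes, signed LD, linkage between the mixture and genomic position,
imputation error, or sample overlap between cohorts. Passing tests
therefore demonstrate correctness of the algorithms under the stated
model, not robustness to those real-data features.

## Problem sizes and runtime

The test suite and the acceptance script run simulations at desk scale:
effect-pair fits at n = 400 with 20 replicates (matching the size of the
confidently classifiable top half of a large scan, ~200–400 indexes),
clumping oracles on blocks of ≤ 20 variants, Gibbs law-of-large-numbers
checks at 10,000 sweeps on ≤ 100 variants. At these sizes the whole
suite completes in under two minutes on one CPU. Genome-scale counts
(hundreds of independent loci from millions of variants) depend on
biobank-scale inputs and are out of scope; the package's correctness at
scale follows from the per-block rules, which are exhaustively checked
at small size.

## Known limitations

* Exactly two groups per comparison; no ≥3-group mixtures.
* No fine-mapping, credible sets or conditional analysis — index
  variants are representatives of LD-independent signals, not causal
  candidates.
* LD is consumed precomputed; no genotype parsing, no build liftover.
* The LRT p-value near the boundary is approximate (flagged, see above).
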