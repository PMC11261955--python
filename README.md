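# thyrodissect

Dissection of GWAS associations into shared and trait-specific components.

Autoimmune hypothyroidism sits at the intersection of two biological axes:
systemic autoimmunity (shared with other autoimmune diseases) and
thyroid-specific dysfunction (visible as population variation in TSH
levels). Given genome-wide association results for the primary disease and
for secondary scans along each axis, this package separates the primary
scan's independent associations into groups that are disease-specific,
shared with systemic autoimmunity, or shared with thyroid function — and
quantifies how large each component is.

It is aimed at statistical geneticists working with GWAS summary
statistics; no individual-level genotypes are needed anywhere.

## What it does

1. **Meta-analysis** (`thyrodissect.meta`): fixed-effects
   inverse-variance-weighted combination of two cohorts' summary
   statistics, `β̂ = Σ wₖβₖ / Σ wₖ` with `wₖ = 1/seₖ²`, retaining variants
   private to one cohort (e.g. population-enriched low-frequency alleles).
2. **LD-independent index variants** (`thyrodissect.clump`): greedy
   selection from the most significant hit downwards with a *dynamic* LD
   threshold `T = min(0.1, 5/χ²)` — the r² at which a correlated variant
   would retain an expected residual chi-square of 5 — plus a 1 Mb
   suppression zone around exceptionally strong signals (T < 0.02) and a
   cap of two signals per megabase. Indexes within 1 Mb are merged into
   loci.
3. **Line-model mixture classification** (`thyrodissect.linemodels`): each
   index variant contributes an effect-size pair (β₁, β₂) from the primary
   and a secondary scan. True pairs are modelled as a mixture of zero-mean
   bivariate Gaussians concentrated around lines β₂ = b·β₁ through the
   origin, parametrized by *scale* s (effect-magnitude SD along the line;
   default 0.6, so ~95% of effects lie within 2s), *slope* b, and
   *correlation* ρ (tightness around the line; default 0.99). Observed
   pairs add per-variant Gaussian noise with the reported standard errors,
   so each component's marginal likelihood is N(0, Σ_b + diag(se₁², se₂²)).
   Mixing proportions and free slopes are fitted by EM; nested fits are
   compared by likelihood ratio; per-variant membership posteriors come
   from the analytic E-step or a Gibbs sampler that integrates over the
   proportions.
4. **Dissection statistics** (`thyrodissect.dissection`): Bonferroni
   overlap counts with direction concordance, sharing proportions over the
   strongest associations, Spearman correlation between membership
   posteriors, and the low-frequency coding-association enrichment 2×2
   with Fisher's exact test.
5. **Synthetic data** (`thyrodissect.simulate`): seeded generators for
   effect-pair mixtures, LD blocks of Z-scores with a causal signal, and
   paired-cohort scans — every stage runs and is tested without any
   external data.

## Worked example

```python
from thyrodissect import (LineModelGroup, LineModelMixture,
                          MixtureSimConfig, simulate_effect_pairs)

# 400 synthetic effect pairs: half disease-only (slope 0), half shared
# (slope 0.447), scale 0.6, correlation 0.99
pairs = simulate_effect_pairs(MixtureSimConfig(n=400, seed=7))

groups = [LineModelGroup(scale=0.6, slope=0.0, cor=0.99, slope_fixed=True),
          LineModelGroup(scale=0.6, slope=0.5, cor=0.99, slope_fixed=False)]
res = LineModelMixture(pairs, groups).fit(seed=7)
print(res.summary())
```

```
Line-model mixture fit
==========================================================
observations:    400    log-likelihood: 78.8344
EM iterations:    12    converged: True
----------------------------------------------------------
group    scale     slope    cor  fixed     prop
    1    0.600    0.0000  0.990   True   0.4608
    2    0.600    0.4396  0.990  False   0.5392
==========================================================
```

The free slope is recovered at 0.4396 (truth 0.447) and the mixing
proportions at 0.46/0.54 (truth 0.5/0.5). Membership posteriors via Gibbs:

```python
member = res.gibbs(n_iter=2000, burn_in=500, seed=7)
print(member.head(3).to_string(index=False))
```

```
key  p_group1  p_group2  map_group
 v0  0.000000  1.000000          2
 v1  0.110667  0.889333          2
 v2  0.433333  0.566667          2
```

`res.plot_scatter(prob_cutoff=0.80)` draws the effect-size scatter colored
by group for assignments above 80% posterior.

The dynamic clumping threshold at a lead chi-square of 250:

```python
>>> from thyrodissect import dynamic_threshold
>>> dynamic_threshold(250.0)
0.02
```

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
thyrodissect meta --a fg.tsv --b ukbb.tsv --out meta.tsv
thyrodissect clump --stats meta.tsv --ld ld.tsv --out index_variants.tsv
thyrodissect classify --pairs pairs.tsv --slopes "0,free" --seed 7 --out membership.tsv
thyrodissect dissect --pairs pairs.tsv --membership membership.tsv --out report.json
thyrodissect run --config run.yaml          # all stages, checksummed report
```

Summary statistics are tab-separated with columns
`chrom pos ref alt af beta se pval` (GRCh38, 1-based positions, remappable
via a column map); LD is read as `key_i key_j r2` triplets or a square
matrix with keys `chrom:pos:ref:alt`.

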