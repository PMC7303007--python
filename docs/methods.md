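# Methods

This note records the statistical model behind `crosstrait`, the defaults
and numerical choices, what the simulator does and does not emulate, and
the design decisions taken where the published workflow leaves the details
open.

## Model

All analyses operate on per-variant Z statistics from two GWAS of
(possibly) overlapping cohorts.  Under a polygenic model on standardized
genotypes with per-variant effect pairs

    (β₁ⱼ, β₂ⱼ) ~ N₂(0, [[h₁²/M, ρ_g/M], [ρ_g/M, h₂²/M]]),

the marginal association statistics satisfy the regression relations

    E[χ²ⱼ]       = 1 + N h² lⱼ / M,
    E[z₁ⱼ z₂ⱼ]   = c + √(N₁N₂) ρ_g lⱼ / M,     c = ρ_p N_s / √(N₁N₂),

where `lⱼ` is the LD score of variant j (sum of r² with everything inside a
±1 Mb window, self term included), `N_s` the number of shared samples and
`ρ_p` the phenotypic correlation within the overlap.  The package uses
these relations three ways: to estimate h², ρ_g, r_g (LD score
regression); to absorb the overlap term `c` (free intercept; the same
quantity appears as the null Z–Z correlation `s` in the bivariate tests);
and to generate synthetic data that satisfies them exactly.

## LD scores

`compute_ld_scores` estimates r² from a reference dosage matrix (≥ 25
samples required; VCF panels supported through cyvcf2).  Cross-variant
terms use the small-sample-adjusted estimator r²_adj = r² − (1−r²)/(n−2);
the self term is counted as exactly 1, keeping `l ≥ 1` interpretable
(adjustment of the self term would be a constant shift the regression
intercept absorbs anyway).  Variants with reference MAF < 0.01 are dropped
before scoring — r̂² is unstable below that.  Precomputed scores are
accepted as a two-column TSV.

## LD score regression

Single-step weighted least squares with a free intercept and
heteroskedasticity weights 1/max(l, 1).  No two-step or constrained
intercept: at the scales this package targets, recovery tests show the
simple fit is unbiased, and a free intercept is what absorbs confounding
and overlap.  Standard errors are delete-one block jackknives over 200
contiguous genomic blocks (⌊SNPs/10⌋ blocks below 200 SNPs; fewer SNPs
than blocks is an error).  For r_g the three slopes (two heritabilities,
one covariance) are re-estimated on a shared block grid, the ratio formed
per leave-out, and the jackknife variance taken on the ratio, so the SE
propagates the h² uncertainty.  Monte-Carlo calibration (200 replicates at
M = N = 20,000) shows the jackknife SE slightly conservative (mean 0.094
vs. true spread 0.088) with 95% interval coverage ≈ 0.96.  If either ĥ² is
non-positive, r_g is reported undefined rather than imaginary.

## Null Z–Z correlation

`estimate_z_correlation` uses the product-moment correlation of the two Z
vectors restricted to the null band |z| ≤ 2 in both traits, which resists
contamination by strong true signal.  Truncating a bivariate normal to a
box attenuates its correlation (for s = 0.4 the band value is ≈ 0.33), so
the band estimate is de-attenuated by numerically inverting the truncated
bivariate-normal box-correlation map (Gauss–Legendre quadrature + Brent
root finding; the map is monotone).  The correction assumes
standard-normal null margins; under polygenic inflation it is approximate,
and genuinely polygenic *correlated* traits still contribute genetic
covariance to the band, so `s` then exceeds the pure overlap term — making
the combined tests slightly conservative, which is the safe direction for
discovery.  With fewer than 100 band variants the estimator falls back to
all variants, uncorrected, with a warning.

## Bivariate tests and the min-p rule

For two statistics O'Brien's optimal combination reduces to
`(z₁+z₂)/√(2(1+s))`; the dLC statistic standardizes an arbitrary
non-negative linear combination, with √N weights by default (the weights
are configurable — the original implementation's choice is not published).
With equal weights dLC coincides with OB identically, so the min-p rule
only differs from OB when the two studies' sample sizes differ.  The
smaller of the two p-values is reported *without* multiplicity correction,
mirroring the published rule; its inflation is quantified empirically by
`type1_error_experiment` (bounded above by 2× the per-test rate, observed
well below that) rather than corrected.

## Discovery, clumping, replication

* The order-of-magnitude criterion is non-strict at the boundary
  (p_biv ≤ p_uni/10); the replication "more significant" criterion is
  strict (p_comb < p_disc).  The published text does not disambiguate
  either boundary; ties are measure-zero in practice.
* Clumping is greedy and unchained: a variant linked (r² > 0.10, ±1 Mb)
  only to an absorbed member, not to the lead, seeds its own locus.  This
  matches standard clumping practice; a brute-force restatement of the
  rule serves as the test oracle.  Missing LD for a within-window pair is
  treated as r² = 0 with a warning.
* Cross-analysis collapsing is a union–find over per-analysis loci:
  components merge on a shared member variant or lead–lead r² > 0.10.
* Direction consistency in replication requires all three signs (both
  discovery studies and the replication cohort) to agree; a zero statistic
  never counts as consistent.
* The discovery–replication meta-analysis uses dLC with s = 0 (independent
  cohorts) and √N weights, with the discovery N taken as N₁+N₂.  Printed
  combined p-values in the packaged table are used as *inputs* to the
  replication rule: they are not exactly reproducible from printed
  per-study p-values alone, so `combine_disc_rep` is validated against its
  own closed form instead.
* BH-FDR q-values come from statsmodels' step-up implementation, checked
  in tests against an exhaustive hand-rolled oracle.

## Harmonization

Variants are matched by identifier; study 2's Z is negated when its effect
allele equals study 1's other allele directly or via strand complement.
Pairs not reconcilable by swap/complement are dropped with a logged count.
Palindromic (A/T, C/G) variants are dropped by default, since swap and
strand flip are indistinguishable; an optional frequency rescue keeps them
when both studies' effect-allele frequencies are decisively away from 0.5
(|eaf − 0.5| > 0.08) and uses frequency concordance to orient the sign.
Coordinates are 1-based GRCh37 by convention.  Records whose p disagrees
with 2Φ(−|z|) beyond rounding keep their Z and have p recomputed; domain
violations (p ≤ 0, N ≤ 0, invalid alleles) drop the record.

## Simulator

`simulate_sumstats` draws Z-scores directly — the sufficiency level the
analyses consume — per independent LD block b with AR(1) correlation
R(b)ᵢⱼ = ρ_b^|i−j|:

    Z_t = √N_t · R b_t + ε_t,   Var(ε_t) = R,   Cov(ε₁, ε₂) = c·R.

Defaults: 200 blocks of 100 variants (M = 20,000), h² = 0.3 per trait,
r_g = 0.5, N = 20,000 per study, no overlap, MAF uniform on (0.05, 0.5).
Block ρ values are spread evenly over (0.1, 0.9): real genomes have
strongly heterogeneous LD, and it is precisely the spread of LD scores
that identifies the regression slope — with a single shared ρ the score is
nearly constant and h² is unidentified.  A scalar ρ remains available for
closed-form unit checks.  Blocks sit 3 Mb apart so no ±1 Mb window spans
two blocks, and each block fits inside one, making the analytic score
l_j = Σ_k ρ_b^(2|j−k|) exact.  Alleles are drawn from the four
non-palindromic pairs with the alphabetically earlier base as effect
allele, so a simulated pair harmonizes losslessly.  Output is
bit-reproducible under a fixed seed.

What the generator does *not* emulate: realistic LD maps (blocks are AR(1)
and mutually independent), allele-frequency-dependent architecture,
case-control liability-scale effects, population stratification, and
imputation error.  Passing recovery tests therefore demonstrate
correctness of the estimators under their own model assumptions, not
robustness to real-data pathologies such as stratification-inflated
intercepts.

## Problem sizes used in the checks

Fixture bookkeeping runs on the 23-row packaged table (instantaneous).
Calibration of the O'Brien test uses 100,000 independent null variants;
parameter recovery uses M = N = 20,000 with 200 replicates per
genetic-correlation grid point {0, 0.25, 0.5, 0.8} (the binomial SE of the
coverage estimate is then ≈ 1.5%); negative-control pipeline runs use
M = 50,000, where an uncorrelated polygenic pair yields on the order of
one false-positive locus per run.  These sizes give stable fits while
keeping a full test run to a couple of minutes on one CPU.

## Known limitations

* A single null correlation `s` genome-wide; no per-region variance model.
* Two traits only, by design; no conditional/joint stepwise analysis.
* No liability-scale conversion of h²; estimates are on the observed
  scale of the supplied statistics.
* Novelty annotation is a lookup against a supplied prior-report list, not
  a computed gene assignment.
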