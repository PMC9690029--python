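# Methods

## Setting and assumptions

`bimr` performs two-sample Mendelian randomization: the exposure and
outcome effect estimates come from two separate GWAS of (ideally)
non-overlapping samples drawn from the same population. Instruments must
satisfy the three IV assumptions — association with the exposure,
independence of confounders, and no effect on the outcome except through
the exposure. The estimators differ in how much of the third assumption
they can relax; the pipeline therefore always reports the principal IVW
random-effects estimate alongside the sensitivity estimators and
diagnostics rather than a single number.

All effects are per-allele log-odds ratios. Causal estimates are expressed
as the change in log-odds of the outcome per 1-unit increase in
log-transformed odds of the exposure, and exponentiated to odds ratios for
reporting.

## Harmonization

Outcome records are aligned to the exposure's effect allele: identical
pairs pass through, swapped pairs have the outcome beta negated and the
allele frequency complemented, and complementary-strand pairs are flipped
first. Palindromic variants (A/T, C/G) are aligned textually and then
retained only when both allele frequencies are outside
[limit, 1 − limit] (default limit 0.42) *and* fall on the same side of 0.5;
anything else — including a missing frequency — is dropped, because the
strand cannot be inferred. The conservative default limit follows common
two-sample MR practice. Variants absent from the outcome GWAS are dropped
with no proxy lookup. Harmonization is idempotent and invariant to a joint
allele/beta-sign recoding of the outcome table; both properties are tested.

## Instrument selection

Selection keeps associations at p ≤ 5 × 10⁻⁸ (configurable) and then
greedily clumps them: visit variants by ascending p-value (ties broken
lexicographically by id, for determinism), accept the best remaining one,
and discard every remaining variant with r² > 0.001 to an accepted variant.
When the LD matrix lacks a pair, variants within 10,000 kb on the same
chromosome are pruned instead; LD information takes precedence over
distance when both exist. The LD matrix is an input (square TSV); the
package does not compute LD from genotype panels.

Instrument strength: per-variant F = (β/σ)²; total variance explained uses
the standardized-trait approximation r² = Σ 2·eaf·(1−eaf)·β², and the
aggregate F = (n−k−1)/k · r²/(1−r²). The approximation treats the
log-odds-scale betas as standardized effects, which is adequate for
flagging weak instruments but not a substitute for individual-level r².

## Estimators: numerical choices

- **IVW** uses first-order weights (outcome SE only), consistent with the
  Wald-ratio SE definition. The random-effects model is multiplicative
  overdispersion with the factor floored at 1, so its SE can never fall
  below the fixed-effect SE. Normal reference distribution.
- **MR-Egger** orients all instruments to positive exposure beta before the
  weighted fit (weights 1/σ_Y²); SEs carry the same floored overdispersion
  factor; t distribution with J−2 df. Requires ≥ 3 instruments.
- **Weighted median** interpolates midpoint cumulative weights
  sⱼ = Σᵢ≤ⱼ w′ᵢ − w′ⱼ/2 at 0.5. The SE is the standard deviation over
  n_boot (default 1,000) parametric-bootstrap replicates with each ratio
  redrawn from N(β̂ⱼ, wald_seⱼ²); the bootstrap seed is mandatory and
  recorded.
- **Contamination mixture** profiles over a grid defaulting to the IVW
  random-effects estimate ± 10 SE in 2,001 steps. The random-effects SE
  (not fixed) sets the width so the grid stays wide when instruments are
  heterogeneous — with a contaminated set the fixed-effect SE can be an
  order of magnitude too narrow. ψ defaults to 1.5 × SD of the ratio
  estimates. The confidence set keeps grid points within 3.84 of twice the
  profile deviance and may be disconnected; the reported CI endpoints are
  the extremes of the set.
- **MR-PRESSO** (default 1,000 simulations, outlier α = 0.05 after
  Bonferroni): the observed statistic is the leave-one-out weighted
  residual sum of squares; null replicates redraw outcome betas around the
  leave-one-out fitted values and re-apply the same functional. Empirical
  p-values use (r+1)/(n+1) so none is exactly zero. The distortion test
  compares the relative change (θ_corrected − θ_raw)/|θ_corrected| with the
  same statistic under removal of 1,000 random same-size subsets; it is
  reported as not applicable when nothing is flagged.

Degenerate inputs: a single instrument degenerates IVW to the Wald ratio
with a warning; identical ratios give Q = 0 and every estimator returns the
common ratio; all-zero weights are an error.

## Power

Power of the two-sided IVW test for a binary outcome uses
Φ(|ln OR|·√(n·r²·K(1−K)) − z_{1−α/2}). The pipeline computes it with the
instrument r² and the estimated odds ratio when the outcome case fraction
is supplied (it is not recoverable from summary tables; 0.5 — the most
favourable K(1−K) — is used otherwise, and flagged in the output). A
simulation oracle in the test suite confirms the approximation matches the
empirical rejection rate of the IVW test in the regime it assumes:
precisely estimated exposure effects, so the outcome side dominates the
estimator's variance.

## Synthetic data generator

The generator emulates the summary statistics of two binary-trait GWAS with
a known causal effect θ. Per instrument: minor-allele frequency uniform on
[0.1, 0.5]; true exposure effect uniform on [0.05, 0.15] with the effect
allele coded as the exposure-increasing allele (the usual convention —
also what keeps "directional" pleiotropy directional after Egger's
orientation step); SEs from the logistic-score approximation
1/√(2·maf(1−maf)·n·K(1−K)), which makes the configured sample sizes
interpretable as real case/non-case counts; estimates are truth plus
Gaussian noise at those SEs; p-values are two-sided Wald. The shipped
scenario pack mirrors a published bidirectional depression/reflux design:
31 forward instruments with outcome n = 385,276 (case fraction
80,265/385,276) and 24 reverse instruments with outcome n = 173,005
(59,851/173,005), with generating effects log(1.31) and log(1.28). The
effect-size range is chosen so instruments clear genome-wide significance
at those sample sizes, as real instruments must; a consequence is that the
synthetic instrument r² (and hence analytic power) is higher than typical
published values for psychiatric traits.

Pleiotropy modes: `balanced` (mean-zero direct effects — inflates
heterogeneity without biasing IVW), `directional` (non-zero mean — biases
IVW, detected by the Egger intercept), `inside_violating` (direct effects
proportional to instrument strength — breaks InSIDE, biasing Egger too).
Tables are written with randomized allele presentation (swaps, optional
palindromic pairs) so harmonization is exercised end to end, and an LD
matrix (identity, optionally block-correlated) accompanies them for
clumping tests.

What the generator does **not** emulate: realistic LD structure beyond
block toys, winner's-curse in instrument discovery, sample overlap between
the two GWAS, population stratification, and allele-frequency differences
between studies. Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to those features of
real data.

## Calibration checks and their conditions

The acceptance suite runs: IVW against a normal-equations WLS oracle and
the weighted median against a brute-force cumulative-weight scan (100
random sets each); type-I error of IVW-random at the null (31 instruments,
1,000 replicates, band 5% ± 2%); recovery of the scenario-pack effects
(mean within 0.01, CI coverage in [92%, 98%], 1,000 replicates each
direction); Egger-intercept recovery under directional pleiotropy within 3
Monte-Carlo SEs of the generating mean; and MR-PRESSO detection of a 10-σ
planted outlier in ≥ 95% of 100 seeded runs with the corrected estimate
closer to truth on average.

The Egger recovery run uses an effectively noise-free exposure side
(n = 5 × 10⁶): the intercept is unbiased only under the no-measurement-
error (NOME) assumption, and at scenario-scale exposure noise it shows the
classical slope-dilution leakage (≈ +10% of the intercept here) — a
property of the estimator, documented rather than hidden. The PRESSO
planted-outlier runs occasionally flag a second variant because the
outlier perturbs every leave-one-out fit; the planted variant itself is
flagged in every run at these settings.

Problem sizes throughout (replicate counts, simulation counts, grid
resolution) are the package's defaults and are chosen to keep Monte-Carlo
error well below the tolerances being asserted.

## Known limitations

- No proxy-SNP substitution, liftover, or VCF input.
- No correlated-instrument IVW; the LD matrix is used for clumping only.
- The aggregate F and power depend on the standardized-trait r²
  approximation; published F/power values computed with other tools (or
  unpublished r² inputs) will not be reproduced exactly.
- No multiple-testing adjustment across directions or outcomes; the report
  notes this rather than imposing one.
- Sample-overlap handling is limited to flagging identical input files.
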