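# Methods

## Design

Two-sample MR treats genetic variants as instruments for a modifiable
exposure under the three instrumental-variable assumptions: association with
the exposure, independence from confounders of the exposure-outcome
relationship, and no effect on the outcome except through the exposure.
Summary statistics for exposure and outcome come from non-overlapping GWAS.
Two-step MR extends this to mediation: step 1 estimates the exposure's
effect on a mediator (β1) by two-sample MR; step 2 estimates the mediator's
direct effect on the outcome (β2) by multivariable MR with the exposure as a
covariate; the indirect effect is β1·β2 and the proportion mediated
β1·β2/β0, where β0 is the IVW total effect.

## Estimators and conventions

All binary-trait effects are on the log-odds scale; odds ratios and their
CIs are exponentials of the corresponding log-scale quantities.

**Wald ratio / IVW.** The per-SNP ratio uses the first-order SE
σ_Y/|β_X|, which ignores the exposure-side sampling error; this is the
convention under which IVW is exactly weighted least squares of β_Y on β_X
through the origin with weights σ_Y⁻². The exposure-side error is accounted
for where it matters: in the weighted-median bootstrap and in the MR-PRESSO
simulations. Fixed-effects SE is (Σw)^{−1/2}; the random-effects model is
multiplicative — SE scaled by √(Q/(J−1)) — with underdispersion clipped at 1,
so the random-effects SE is never smaller than the fixed one. The
fixed-vs-random choice follows the heterogeneity rule: fixed iff Cochran's Q
p > 0.05 (strictly). IVW inference is normal; a 95 % CI is ±1.96·SE.

**MR-Egger.** Instruments are first oriented so every exposure beta is
positive (both betas negated together); the intercept of the weighted
regression (weights σ_Y⁻²) then estimates the average directional
pleiotropic effect on the exposure-increasing allele, and the slope a
pleiotropy-adjusted causal effect. SEs carry the same multiplicative
overdispersion scale clipped at 1; inference uses t(J−2). Directional
pleiotropy is declared absent when |intercept| < 0.1 and its p > 0.05.

**Weighted median.** Wald ratios are sorted; the cumulative weight midpoints
s_j = (Σ_{k≤j} w_k − w_j/2)/Σw use inverse ratio-variance weights
β²_X/σ²_Y; the estimate linearly interpolates the (s_j, ratio_j) curve at
s = ½. The SE is the standard deviation of the estimate over a parametric
bootstrap (default 1000 replicates) that redraws both betas from normals at
their SEs; the bootstrap seed is mandatory, making results bit-reproducible.

**MR-PRESSO.** The observed residual of SNP j is d_j = β_Yj − b_{−j}·β_Xj
with b_{−j} the leave-one-out fixed-effects IVW estimate; the global
statistic is RSS = Σ_j d_j²/σ²_Yj. Its null distribution is simulated
(default 1000 draws) by redrawing β*_Xj ~ N(β_Xj, σ_Xj) and
β*_Yj ~ N(b_{−j}β_Xj, σ_Yj); p-values are add-one Monte-Carlo,
(1 + #{RSS* ≥ RSS})/(n_sim + 1), so the smallest attainable p is
1/(n_sim+1). Per-SNP outlier p-values compare d_j² with its simulated
distribution and are Bonferroni-adjusted across J; flagged SNPs (adjusted
p < 0.05) are removed for the corrected IVW estimate. The distortion test
compares the observed estimate shift against shifts from removing random
same-size subsets; it preserves the spirit of the published distortion test
without reproducing its exact bootstrap scheme. With few instruments and a
gross outlier, the leave-one-out estimates for clean SNPs are themselves
contaminated, and the outlier test can flag most of the set; the
implementation treats "all or all-but-one flagged" as a fatal diagnostic
rather than returning a meaningless corrected estimate.

**Multivariable MR.** Weighted least squares of β_Y on the K exposure-beta
columns with no intercept and weights σ_Y⁻²; SE scale max(1, √(RSS_w/(J−K)))
and t(J−K) inference. With K = 1 this reproduces the multiplicative
random-effects IVW point estimate and SE exactly. An identically-zero
exposure column is dropped (coefficient 0, SE ∞) so the fit reduces to the
lower-dimensional model. The instrument set is the union of each exposure's
selected instruments, jointly re-clumped on best p; all rows are harmonized
to the first exposure's orientation. A conditional instrument-strength
diagnostic (weighted residual chi-square of each exposure column given the
others, per remaining degree of freedom) is reported but not acted on.

**Mediation decision table.** With two-sided significance at α = 0.05:
partial (all of β0, β1, β2 significant), full (β0 not significant, β1 and β2
significant), none (β0 significant, β1 or β2 not), no causal path (neither).
The proportion mediated is reported only for partial/full; values outside
[0, 1] (inconsistent mediation — opposite-sign indirect and total effects,
or a non-significant β0 in the denominator) are returned as computed with a
warning, never clipped. The delta-method SE of the indirect effect,
√(β2²σ1² + β1²σ2²), is a first-order diagnostic; it drops the σ1²σ2² term
and is accurate when the coefficients dominate their SEs.

## Instrument selection

Genome-wide significance is strict (p < 5e-8), as is the strength filter
(F = β²/SE² > 10). Clumping is greedy best-p-first: repeatedly keep the
remaining SNP with the smallest p (ties broken lexicographically by id) and
discard remaining SNPs with r² ≥ 0.001 against it, additionally requiring
them to lie within 10 Mb when positions are available; with an r²-only
matrix the r² criterion alone governs, since at r² < 0.001 the distance
criterion is rarely binding. LD is an input (square or long-format TSV), not
computed from genotypes, which keeps the package free of reference-panel
downloads.

## Harmonization

The outcome (or mediator) record is placed on the exposure's effect-allele
orientation: identical pair kept, swapped pair negated, strand-complement
pairs complemented first. Palindromic SNPs (A/T, C/G) are excluded
unconditionally by default, reproducing the source study's handling (it
reports nine such exclusions for its largest exposure); an optional
frequency-inference policy keeps them when both EAFs are below 0.42 or
above 0.58, orienting by frequency concordance. Instruments with zero
exposure beta after harmonization are excluded (undefined Wald ratio). The
harmonization report accounts for every matched SNP exactly once:
n_input = n_harmonized + n_palindromic + n_mismatch + n_zero_beta_exp.

## Power

For a case-control outcome, power = Φ(√(n·R²_XZ·K(1−K))·|ln OR| − z_{1−α/2}),
the normal-approximation non-centrality form with the binary-outcome
variance factor K(1−K); R²_XZ = Σ 2·EAF(1−EAF)β² over instruments. The form
is symmetric in OR ↔ 1/OR and strictly increasing in n, R²_XZ and |ln OR|.
The minimum detectable OR inverts it by bisection to 1e-6. Published online
calculators of this family may differ by small constant-factor conventions;
the closed form used here is stated so results are reproducible.

## Synthetic data

The generator emulates the summary-level inputs of a psychiatric-exposure /
behavioural-mediator / case-control-outcome study. Defaults are the study
dimensions: exposure GWAS n = 150,064; mediator GWAS n = 632,802; outcome
GWAS n = 228,951 with case fraction 0.5372; 150 exposure instruments with
per-SNP effects γ_j ~ N(0, 0.03²); total effect ln 1.06 split as
direct + β1·β2 with β1 = 0.0438 and β2 = 0.1467; MAF ~ U(0.05, 0.5).
Standard errors use the per-allele variance approximation
1/√(2·MAF(1−MAF)·n_eff), with n_eff = n·K(1−K) for the binary outcome. At
these settings roughly half of the 150 exposure SNPs reach genome-wide
significance per replicate — the order of the 68-of-147 yield in the
motivating study — and the instrument F statistics fall in the same
30–140 range.

Mediator-specific instruments (default 150, δ_j ~ N(0, 0.015²)) are
generated alongside: without them the mediator's genetic effects are exactly
β1·γ_j, collinear with the exposure's, and the multivariable fit would be
unidentified — as in real data, mediation analysis needs instruments that
move the mediator independently of the exposure.

Horizontal pleiotropy is defined relative to the exposure-increasing allele
(the orientation MR-Egger uses), so a nonzero pleiotropy mean remains
directional after instrument re-orientation; on the reported effect allele
it enters as sign(γ_j)·α_j. Balanced pleiotropy (mean 0) inflates
heterogeneity without moving the Egger intercept. Palindromic allele pairs
and discordant (swapped) codings are injected per SNP with the configured
probabilities and recorded in the ground-truth object, so harmonization
bookkeeping can be audited exactly.

What the generator does *not* emulate: LD between instruments is off by
default (identity matrix, matching post-clumping data; an optional
block-LD mode exercises the clumping path), there is no sample overlap
between the two GWAS, no population stratification, no winner's-curse-free
replication betas, and allele frequencies carry no sampling noise. Passing
calibration tests on these data therefore demonstrates estimator
correctness under the stated model, not robustness to those artefacts.

## Test problem sizes

Calibration suites use 500 replicates of J = 50 instruments for IVW
coverage and the Egger intercept type-I rate, 100 seeds for MR-PRESSO
outlier detection (J = 20, one SNP displaced by 10·SE, 1000 simulations
each), and 200 replicates at the full study scale (150 + 150 instruments)
for proportion-mediated recovery. These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands while keeping the whole suite
under a minute of estimator time.

## Known limitations

- First-order Wald SEs understate uncertainty for weak instruments; the
  IVW coverage at the simulated study scale is ~93–95 %, at the lower edge
  of nominal when many instruments are retained without a strength filter.
- MR-Egger under winner's-curse instrument selection shows the usual
  regression-dilution bias on single replicates; the type-I calibration of
  its intercept test is verified on unselected instruments.
- The MR-PRESSO distortion test is a Monte-Carlo analogue, not a
  byte-for-byte replication of the reference implementation.
- Proportions mediated are ratios of estimates; their sampling distribution
  is heavy-tailed when β0 is imprecise, which is why only the mean over many
  replicates is asserted in tests.
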