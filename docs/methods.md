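# Methods

## Model and scope

`mrmediate` implements two-sample Mendelian randomization (2SMR) from GWAS
summary statistics, plus two-step mediation. The causal diagram is

```
        theta_xm          theta_my
   X  ───────────►  M  ───────────►  Y
    └────────────────────────────────┘
                theta_direct
```

with X an exposure (e.g. a micronutrient), M a candidate mediator (e.g. a
blood metabolite) and Y a binary disease outcome on the log-odds scale.
Per SNP j the inputs are marginal association estimates (β̂, se) for each
trait from non-overlapping samples. Under the instrumental-variable
assumptions (relevance, independence from confounders, no direct path to
the outcome), the per-SNP Wald ratio β̂_yj/β̂_xj estimates the causal
effect, and the estimators differ in how they pool ratios and in which
violations they tolerate.

## Instrument selection

A SNP is an instrument for a trait when (1) p < 5×10⁻⁶, (2) it survives
greedy clumping — visit SNPs in ascending p (ties by id), discard
neighbours on the same chromosome within 10,000 kb or with LD r² ≥ 0.001
when an LD matrix is supplied — and (3) F > 10 with F = R²(n−2)/(1−R²).
R² defaults to the frequency-free z²/(z²+n−2) (with which F reduces to
z² algebraically); 2·eaf(1−eaf)β² is available for standardized
continuous traits with known frequencies. No LD reference panel is
bundled: without a user matrix, clumping is distance-only, which is the
dominant pruning effect at a 10,000 kb window. Per-SNP F is the inclusion
rule; the set-level mean F is also reported.

## Harmonization

Alleles are aligned to the exposure's effect allele: swapped alleles flip
the outcome beta's sign (and eaf → 1−eaf); strand complements (A↔T, C↔G)
are renamed; pairs needing both get the sign flip. Palindromic SNPs
(A/T, G/C) can only be oriented by frequency: they are kept when both
eafs lie outside 0.5 ± 0.08 on the same side of 0.5, and excluded as
ambiguous otherwise — including whenever a frequency is missing
(conservative default; the window is configurable). Indels and
multi-allelic records are excluded. Every input SNP receives exactly one
action, so harmonization reports are audit-complete.

## Estimators

- **IVW**: weighted regression of β_y on β_x through the origin, weights
  1/se_y². Default variance model is multiplicative random effects — the
  fixed-effect se is inflated by √(Q/(m−1)) when Cochran's Q exceeds its
  degrees of freedom, never deflated. A fixed-effect flag exists.
- **MR-Egger**: same regression with a free intercept, after orienting
  inputs so every β_x ≥ 0. The intercept estimates average directional
  pleiotropy; slope and intercept ses use the same max(1, Q_res/(m−2))
  multiplicative inflation. Requires ≥ 3 instruments and a non-degenerate
  design (collinear β_x raises an error).
- **Weighted median**: ratios sorted ascending with normalized
  inverse-variance weights w_j = 1/se(ratio_j)²; cumulative midpoints
  p_k = Σ_{i≤k}w_i − w_k/2; the estimate interpolates ratio against p at
  p = 0.5. Consistent when > 50% of weight is on valid instruments.
- **Simple/weighted mode**: normal-kernel density of the ratios with
  bandwidth `bandwidth_factor × 0.9·min(sd, IQR/1.349)·m^(−1/5)`
  (modified Silverman), evaluated on a 512-point grid spanning the ratios
  ± 3 bandwidths; ties in the argmax break toward the smaller ratio. The
  weighted variant uses inverse-variance weights in the density.

Ratio standard errors use the first-order delta approximation
se_y/|β_x| (second-order available behind a flag); with F > 10 instruments
the first-order form is standard. Median and mode ses come from a seeded
parametric bootstrap (default 1,000 replicates) redrawing β_x*, β_y*
normal around the observed values with the observed ses. 95% intervals
use the normal quantile 1.959964 throughout; odds-ratio reporting
exponentiates beta and its CI.

## Sensitivity diagnostics

- **Cochran's Q** of the ratios against the fixed-effect pool,
  chi-square with m−1 df.
- **Egger intercept test**: intercept ≠ 0 indicates directional
  pleiotropy.
- **MR-PRESSO** (global + outlier; the distortion test is deliberately
  omitted): observed RSS uses leave-one-out IVW slopes; `n_sim` (default
  1,000) Monte-Carlo replicates redraw β_y* from the fitted model;
  global p is the rank statistic (1+#{RSS*≥RSS})/(n_sim+1), bounded
  below by 1/(n_sim+1). A SNP is an outlier when its observed RSS term
  exceeds the 1 − α/m quantile of its simulated terms (α = 0.05,
  Bonferroni-scaled by m).
- **Leave-one-out**: one IVW per omitted SNP, same variance model as the
  headline fit.

## Mediation

Step 1 regresses the mediator on the exposure's instruments (β₁); step 2
regresses the outcome on the mediator's instruments after removing any
SNP with exposure p < 5×10⁻⁶ (the overlap rule keeps the two steps'
instruments independent; the threshold defaults to the selection
threshold and is strict — a boundary p equal to the threshold is
retained). The indirect effect is β₁β₂ with Sobel se
√(β₁²se₂² + β₂²se₁²); the mediated proportion is β₁β₂/β_total. The
proportion CI divides the indirect CI endpoints by β_total with the
total treated as fixed — this reproduces the published style of
proportion intervals exactly — re-ordering endpoints when β_total < 0; a
two-term delta variant propagating se_total sits behind a flag. All
three component fits share one IVW variance model so the product and
ratio stay interpretable. Identities `indirect = beta1*beta2` and
`proportion = indirect/beta_total` hold to machine precision in every
result object.

## Screens and reverse MR

`run_screen` maps a battery of exposures over one outcome. A trait
passes when its IVW p (after the configured multiplicity adjustment;
default none, with Bonferroni and Benjamini–Hochberg available) is below
α = 0.05 *and* neither the Egger intercept nor the PRESSO global test is
significant at α. Diagnostics that the instrument count cannot support
(Egger needs 3, PRESSO 4) do not disqualify. Per-trait failures are
isolated into a status column; the screen always completes. `reverse_mr`
swaps the roles with identical machinery. Reports are long-format
(one line per trait × method) with a fixed column order, deterministic
given a seed.

## Synthetic generator

`simulate_sumstats` draws, per SNP, maf ~ U(0.05, 0.5) and a true
exposure effect with random sign and magnitude uniform in [0.5, 1.5]
before rescaling so the instruments jointly explain `var_explained_x` of
the exposure (default 0.02). The uniform magnitude keeps every planted
SNP a genuine instrument — with N(0,1) magnitudes a sizeable fraction of
"instruments" would fall below their own significance filter, making the
configured instrument count fictitious. Mediator-specific SNPs get their
own effects (`var_explained_m`, default 0.05); true mediator and outcome
effects follow the structural model, plus optional per-SNP pleiotropic
effects α_j ~ N(pleiotropy_mean, pleiotropy_sd) acting directly on the
outcome. Observed betas add independent noise with the
standardized-trait approximation se = 1/√(2·maf(1−maf)·n), separately
per trait (no sample overlap). About 8% of SNPs are palindromic and 20%
of outcome rows are strand-renamed to exercise harmonization; positions
are spaced 20,000 kb so clumping is the identity unless linkage is
planted.

Defaults mirror the motivating study design: m = 9 exposure instruments,
n_x = 64,979 (UK-Biobank-scale nutrient GWAS), n_m = 8,299
(metabolite-GWAS scale), n_y = 184,683 (FinnGen-scale case-control,
≈ 20,001 cases + 164,682 controls), and effects
theta_xm = 0.5, theta_my = −0.1, theta_direct = −0.25 (total −0.3,
mediated proportion 1/6).

What the generator does **not** emulate: LD between instruments (beyond
planted toy blocks), liability-scale case-control ses, winner's-curse
selection from a genome-wide panel, population stratification, or sample
overlap between cohorts. Passing tests therefore certify the estimators'
algebra and their operating characteristics under the stated model, not
robustness to those real-data pathologies.

## Numerical choices and degenerate inputs

- p-values of exactly 0 in input tables are clamped to the smallest
  positive double with a warning; rows with se ≤ 0, identical alleles,
  eaf outside [0,1] or p outside (0,1] are dropped and counted.
- R² is clipped to [0, 1−10⁻¹²]; F is undefined at n ≤ 2.
- All-identical ratios: Q = 0 (p = 1), mode/median return the common
  ratio; zero kernel bandwidth falls back to the common ratio.
- Clumping tie-breaks by SNP id make the retained set independent of
  input row order; bootstrap and PRESSO are bit-reproducible under a
  fixed seed.
- The Egger normal-equations solve raises on near-singular designs
  rather than returning noise.

## Problem sizes used in the checks

The operating-characteristic checks run at: IVW coverage and Q
uniformity, 1,000 null replicates at m = 10; Egger intercept recovery
and PRESSO outlier power, 200 replicates at m = 50 and m = 10; mediation
recovery, 200 replicates per true proportion (0.1/0.3/0.5) at m = 50
instruments per trait and n = 100,000 with var explained 0.05 (per-SNP
F ≈ 100, the strong-instrument regime); null screens, 50 replicates of
20 traits at the generator defaults. The closure checks are
scale-calibrated: IVW attenuation from exposure-side noise is ≈ 1/F̄, so
these settings bound the weak-instrument bias of the total effect near
0.003 — well inside the 0.01 unbiasedness band they assert.

## Known limitations

- Without a user LD matrix, clumping cannot remove long-range LD within
  the window rule.
- The PRESSO distortion test and Steiger filtering are out of scope, as
  are multivariable MR and difference-method mediation.
- The weighted-median/mode bootstrap is this package's declared
  contract; other implementations use different resampling schemes, so
  their ses agree only in distribution.
- The mediated-proportion CI with a fixed total understates uncertainty
  when se_total is non-negligible; use the delta variant for honest
  propagation.
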