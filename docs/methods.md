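# Methods

This note documents the statistical models and procedures implemented in
`foodsec`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate about real
survey data.

## The cross-classification model

Both food-security instruments — the 10-item resource-constraint module
(AFSSM) and the 6-item physical food security instrument (PFS) — map a
raw affirmative count onto the same four ordered severity levels (High,
Marginal, Low, Very low; cut points 0 / 1–2 / 3–5 / 6–10 and
0 / 1–2 / 3–4 / 5–6 respectively). The joint status is defined as

    joint = max(severity_AFSSM, severity_PFS),

the most severe of the two assignments. The rule is implemented as a
severity maximum rather than a 16-entry lookup table; the explicit grid
lives in the test-suite as an independent oracle. The maximum rule is
exactly the published grid, generalizes to any pair of ordered scales,
and makes the structural properties (monotonicity in each raw score,
commutativity, the 1/3/5/7 cell-to-category tallies, and the dominance
bounds joint-High ≤ min of marginal Highs, joint-VeryLow ≥ max of
marginal VeryLows) theorems rather than table facts.

A respondent missing either battery receives no joint status; the
analytic sample requires completeness on both (the inclusion filter
retains age ≥ 60 with all 16 items non-missing and tallies exclusions
by reason). "Refused" and "don't know" count as missing for all
inclusion rules while remaining distinguishable at ingest. AFSSM items
skipped by the household screener carry a distinct sentinel and count
as negative responses by default (`screened_as="missing"` flips this);
public-use files do not record which convention upstream scoring used,
so both are provided.

## Design-based estimation

All variance estimation is first-stage Taylor linearization with the
with-replacement approximation: per-respondent score contributions are
summed within PSU, and deviations of PSU totals are pooled within
strata with the factor n_h/(n_h−1). Design degrees of freedom are
(#PSUs − #strata). Strata with a single PSU raise an error by default;
`lonely_psu="center"` centers the lonely PSU at the grand mean instead.

- **Multiyear weights.** Pooling k two-year cycles divides each 2-year
  weight by k (k = 6 for a 2007–2018-style pool). The interview weight
  serves home-interview analyses, the MEC weight any analysis touching
  examination variables (depression, and by the same logic the
  self-reported-health models), and the two-day dietary weight the HEI
  analyses.
- **Prevalence.** Horvitz–Thompson ratio estimator; CIs are Wald on the
  logit scale with the design df (guaranteed inside [0, 1]); a plain
  Wald option exists. Korn–Graubard small-domain intervals were
  considered and not implemented: no analysis here concerns domains
  small enough for the beta-based correction to matter, and the logit
  interval is the common default in this literature.
- **Rao–Scott test.** The Pearson statistic is computed on weighted
  estimated proportions scaled by the unweighted n. The residual vector
  u = p̂_rc − p̂_r·p̂_·c is linearized (Jacobian applied to the cell
  covariance), and the generalized design-effect eigenvalues δ_k are
  those of n·A^{1/2} V̂_u A^{1/2} with A = diag(1/expected). The
  default second-order (Satterthwaite) form reports
  F = X² / Σδ on df1 = d/(1+a²), df2 = df1·(design df), where d is the
  nominal df and a² the squared CV of the δ's; `order=1` gives the
  mean-deff correction. Under simple random sampling the δ's are ≈ 1
  and the statistic collapses to X²/d, which the tests verify, and the
  simulated type-I error under independence with log-normal weight
  variation stays within [0.03, 0.07] at nominal 0.05.
- **Regressions.** Point estimates are pseudo-maximum-likelihood
  (weighted IRLS via statsmodels GLM); the variance is the sandwich
  B⁻¹GB⁻¹ with B the weighted information and G the stratum-centered
  covariance of PSU score totals. CIs use t with design df reduced by
  the number of non-intercept parameters. Degenerate inputs (constant
  outcome, empty exposure level, perfect separation — detected by
  fitted probabilities at 0/1) raise errors rather than returning
  fits. With equal weights and one stratum the estimates agree with
  ordinary logistic/OLS fits to 1e-8.
- **Pairwise design t-tests.** Domain means are joint ratio estimators
  (domains zero-weighted, not subset, so PSU-level covariance between
  groups is kept); the raw two-sided p is multiplied by the number of
  comparisons (6 for four groups) and capped at 1.
- **Cross-model coefficient comparison.** Stata's stacked
  estimating-equation approach (`suest`) is replaced by a
  design-respecting paired bootstrap: PSUs are resampled with
  replacement within strata, both models are refit on every replicate,
  and the per-term coefficient differences yield percentile CIs and a
  two-sided bootstrap p (with the +1 small-sample correction). The
  contract — a p-value per shared coefficient — is preserved; the
  numeric internals of the Stata command are not reproduced.

## Factor-analysis diagnostics

Bartlett's sphericity statistic is −(n−1−(2p+5)/6)·ln|R| on p(p−1)/2
df. KMO is Σr²/(Σr²+Σq²) over off-diagonal pairs, with q the
anti-image partial correlations from the standardized inverse of R.
Extraction is principal-axis with squared-multiple-correlation initial
communalities, iterated to a communality tolerance of 1e-3 (looser
tolerances stall on near-Heywood items; this matches common practice in
factor-analysis software). Retention defaults to eigenvalue > 1.
Item correlations are Pearson on 0/1 indicators by default — matching
the common default when factoring binary survey items — with pairwise
tetrachoric correlations as an option. The tetrachoric option matters
for one structural check: phi coefficients attenuate unequally under
heterogeneous item thresholds and can leave a spurious second
eigenvalue just above 1 even for a one-factor item set, while the
tetrachoric matrix collapses it. Survey weights are not applied in the
EFA by default (a weighted-correlation option exists); the published
analysis does not state its weighting, and the diagnostics here are
structural rather than population-descriptive.

## HEI-2015 scoring

The per-person simple algorithm: both 24-hour recalls are summed before
any ratio is formed; each of the 13 components is scored by linear
interpolation of its constituent-to-energy ratio between the published
min/max standards, clipped to [0, max points]; the total is the sum
(0–100). Density components use amount per 1,000 kcal; added sugars and
saturated fat use percent of energy (16 kcal per teaspoon equivalent, 9
kcal per gram); the fatty-acid component uses the (MUFA+PUFA)/SFA
ratio, with zero saturated fat scored as most favorable when any
unsaturated fat is present and as zero when the diet reports no fat at
all. The standards table ships as an editable YAML file and every test
hand-computes against it. Respondents missing either recall day, or
with zero pooled energy, are unscorable and propagate NaN.

## The synthetic-data generator

The generator's defaults define the study conditions used throughout
the tests.

**Measurement model.** The 16 item responses come from a correlated
latent-threshold (probit) model: three factors f ~ N(0, Φ) — resource
constraint, physical limitation, and a severity/frequency factor
carried by the two "whole day" items — with loadings of 0.88–0.94 for
the first eight AFSSM items on factor 1, 0.45/0.80 cross-loadings for
the two whole-day items on factors 1/3, and 0.70–0.80 for the PFS items
on factor 2. Unique variances scale each latent to unit variance; item
i is affirmative when its latent exceeds τ_i. High within-scale
loadings are required to reproduce the near-Guttman raw-score
distribution of the resource-constraint scale (many zeros, few 1–2
scores relative to the tail).

**Calibration.** Seven parameters — per-scale threshold shift,
log-spread and severe-tail shift, plus the factor-1/2 correlation — are
fit by nested Nelder–Mead over a fixed 200,000-draw Monte-Carlo sample
to seven anchors: the published AFSSM shares (86.0/6.0/4.7/3.3 %), PFS
shares (52.7/31.4/11.4/4.4 %), and the joint cross-classified
distribution (48.3/30.8/13.6/7.3 %), with a final joint polish. The
scale marginals are independent of the inter-factor correlation, which
makes the sequential scheme well-posed. A single correlation cannot
match both the joint-High excess and the joint-VeryLow tail exactly —
the calibrated model lands within about 1.4 percentage points of every
anchor (joint Very low 6.6 vs 7.3 being the widest gap) — so recovery
tests compare estimates against the *model-implied* shares recorded in
the truth ledger, computed by large-sample Monte Carlo, not against the
anchors. The calibrated values are frozen as defaults;
`calibrate_thresholds()` reproduces them and raises if asked for
targets more than 2 points out of reach.

**Outcomes.** Depression and poor self-reported health are Bernoulli
draws from logistic models on the joint category (odds ratios
2.92/6.36/14.6 and 3.44/7.64/12.7 for Marginal/Low/VeryLow vs High,
base rates 3.5 % and 12 % in the High category) plus small centered
covariate effects. PHQ-9 item patterns are generated consistently with
the drawn binary flag (totals ≥ 10 iff flagged), so the pipeline's own
scoring reproduces the planted outcome exactly. Weight history,
condition flags and the functional-difficulty item carry mild severity
gradients.

**Design.** Respondents are allocated uniformly to 15 strata × 2 PSUs;
2-year weights are log-normal (σ = 0.5, CV ≈ 0.53) with MEC and dietary
weights as jittered copies. Weights are independent of all outcomes, so
weighted estimators are unbiased for the superpopulation parameters and
the exact Monte-Carlo SE of a weighted share is p(1−p)·Σw²/(Σw)², which
the recovery tests use as their yardstick.

**Dietary generator.** A latent diet-quality u per respondent has mean
(HEI target mean)/100 by joint category (defaults 58.5/56.5/55.1/53.4)
and SD 0.10; each component's density interpolates linearly between its
zero-score and full-score standard in proportion to a noisy copy of u,
making the expected total approximately 100·u and strictly decreasing
in severity. Setting all category means equal removes the gradient
(null case).

**What the generator does not emulate.** Demographic oversampling and
weight–outcome correlation (weights are noninformative here); item
nonresponse mechanisms beyond optional uniform missingness;
between-PSU intraclass correlation in the items (PSUs affect variance
estimation only through the resampling structure); measurement error in
recalls. Passing recovery tests therefore demonstrates correctness of
the estimators and pipeline plumbing under a faithful design geometry,
not robustness to informative weighting or cluster-level confounding.

## Problem sizes

Routine tests run at n = 500–10,000; the coverage study uses 200
replicates of n = 2,000 (binomial 3σ band around nominal 95 %); the
Rao–Scott type-I simulation uses 500 replicates of n = 600; the
calibration Monte Carlo uses 200,000 draws. These sizes make the full
suite complete in well under a minute while keeping Monte-Carlo error
small relative to every asserted tolerance.

## Known limitations

- Tetrachoric correlations are estimated pairwise and PSD-repaired by
  eigenvalue clipping; they are not jointly maximum-likelihood.
- The paired bootstrap treats strata as fixed and PSUs as exchangeable
  within strata; very small numbers of PSUs per stratum (2, as here)
  make percentile CIs conservative.
- The Rao–Scott implementation targets two-way tables; higher-order
  log-linear hypotheses are out of scope.
- The HEI standards file encodes the 2015 edition; other editions can
  be supplied as YAML but component *kinds* are limited to density,
  percent-energy and the fatty-acid ratio.
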