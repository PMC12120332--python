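# Methods

This note records the models, the synthetic-data generator's assumptions,
the numerical choices, and the known limitations — the things a maintainer
would want before trusting or extending the package.

## The measurement model

Each river-year deploys two audit receivers: *first* at the release site
(river-km 0 by convention) and *last* at the river mouth, `d` km
downstream. A fish enters the study when detected at the first receiver
and succeeds when detected at the last. Both quantities are **minimum
estimates**: a fish can pass a receiver undetected. Fish detected at the
last receiver but never at the first demonstrably passed the first and are
counted as entered and succeeded. When a first receiver performs very
badly (detection efficiency below 0.5 by default; the two real cases were
0% and 2.7%), entry falls back to the release: every released fish counts
in the denominator.

### Detection efficiency

The estimand is the probability `p` that a receiver detects a passing
fish. Fish *known* to have passed are those detected at the receiver or
somewhere downstream (the river mouth for the first receiver; a marine
array for the last). The default estimator conditions on downstream
detection: among fish detected downstream — all of which certainly passed —
the detected fraction estimates `p` without confounding by in-river
survival. The pooled form
`n_detected / (n_detected + n_missed_but_seen_downstream)` is also
available (`method="pooled"`); under mortality between the receivers it is
biased upward, because a fish missed at the receiver only reveals itself
by surviving the rest of the river (analytically, with survival `S` and
detection `p₁ = p₂ = 0.9`, `S ≈ 0.55`, the pooled estimator centres on
0.948 rather than 0.90). The conditional form is exact in expectation in
the same regime and is what the recovery simulations validate.

### Rate of migration success

With success `S` over distance `d`, `r = S^(1/d)` is the per-kilometre
survival a memoryless chain would need to produce `S` — the geometric mean
survival per km. `r^D` standardizes populations to a common reference
distance `D`. The source tables print both 31.52 and 31.54 km for the mean
river distance in different places; both constants are exported
(`STANDARD_DISTANCE_KM`, `STANDARD_DISTANCE_KM_ALT`) and neither is
silently preferred. `S = 0` maps to `r = 0` by the limiting convention,
avoiding `0^(1/d)` ambiguity. Population success is computed from all
tagged fish (detection-based entry); only the individual-level model drops
the fish missing a biometric.

## Individual covariates

Body condition is the residual from one OLS fit of `log mass` on
`log fork length` pooled across **all** fish with complete biometrics (all
rivers and years), not per-river fits: the covariate is meant to measure
mass-for-length against a common allometry. Natural logs throughout;
residuals are invariant to unit rescaling (only the intercept moves) and
proportional under a change of log base. Tag burden is
`100 · tag mass / body mass` (percent, both in air).

## Mixed models

`smoltrak.glmm` implements logit-link random-intercept GLMMs for Bernoulli
and beta responses by Laplace approximation: for fixed
`(β, log σ_g, [log φ])` the random-effect vector is profiled out by
Fisher scoring (expected information; step-halving; tolerance 1e-10), and

    ℓ ≈ h(b̂) − ½·[log det D + log det(Z'WZ + D⁻¹)]

is maximized over the outer parameters with L-BFGS-B, with a Nelder-Mead
polish only if the final gradient is large for the likelihood's scale.
Wald SEs come from the numerical Hessian of the marginal log-likelihood.
Random factors are crossed (river and year each contribute one variance);
the beta family uses the mean-precision parametrization with a single
scalar precision φ (no dispersion covariates). On shared test data the
engine agrees with `lme4::glmer` and `glmmTMB` point estimates and
log-likelihoods to ~3–4 decimals; one pytest cross-checks this against
`Rscript` directly.

Fixed-effect-only models go through statsmodels: gamma GLM (log link — the
family was prescribed, the link is this package's choice) for speed,
binomial GLM for spatial success variation, and `BetaModel` for the
landscape beta regression. Responses touching 0 or 1 are squeezed by
`y' = (y(n−1) + 0.5)/n` before beta fitting (applied only when needed).

Likelihood-ratio tests use `2ΔLL` against `χ²(Δk)`; tiny negative
statistics from optimization noise are clamped to zero (conservative).
Step-down selection drops, each round, the term whose removal has the
largest LRT p above α = 0.05 (ties toward fewer parameters) and never
removes a significant term. Kendall's W is computed on the largest
complete river × year submatrix when year coverage is unbalanced (most
cells, ties toward more years), with average ranks and the standard tie
correction; Levene's test centres on group medians (the Brown–Forsythe
form, matching common ecological practice) and keeps singleton groups in
the group count. The temporal chi-square compares each river's later years
against its first-year proportion, summing `(O−E)²/E` over success and
failure cells; df = number of later river-years.

Bedrock contrasts are estimated marginal means on the link scale with
continuous covariates at their observed means and dummies at observed
frequencies; pairwise p-values use the studentized-range (Tukey)
distribution with `k` = number of levels and residual df.
Marginal-effect curves vary one covariate over its observed range, hold
the rest at means/frequencies, and report `expit(η ± 2·SE)^D` bands after
distance standardization.

## The synthetic study generator

The generator emulates the campaign structure the estimators assume, under
one seeded `numpy` Generator (byte-identical tables per config):

- **Catchments.** Per-class land-cover proportions from beta samplers
  (means ≈ 0.17 grassland, 0.15 woodland/wetland, 0.02 urban, 0.12
  agricultural), redrawn jointly until the five covers sum to ≤ 1; peat
  separately; one dominant bedrock class; lognormal area and gradient,
  Poisson barrier counts.
- **Per-km survival.** `logit(r) = Σ m_k x_k + α_bedrock` with the fitted
  study coefficients as defaults (grassland −6.74, woodland 1.19, wetland
  4.35, peat −9.29; igneous 6.02, metamorphic −0.55, sedimentary 1.46).
  A year effect (SD 0.3 on the logit, default) makes rates vary between
  years within a river.
- **Cohorts.** Fork length ~ Normal(142, 9) mm; `log mass = −12.614 +
  3.222·log length + ε`, `ε ~ N(0, 0.06)` (intercept/slope fitted to the
  44 packaged cohort means; the residual SD matches the order of the
  printed condition SDs); biometrics rejection-sampled to the tagging
  thresholds (≥130 mm, ≥20 g); tag mass 1.6 g. The latent ε is the true
  condition the recovery tests target.
- **Fates.** Whole-river survival per fish is
  `expit(logit(r^d) + 1.111·(c − c̄) − 0.117·(burden − burden̄))` — the
  individual slopes back-solved from the study's printed marginal
  predictions (success 0.49→0.27 over burden 1.00→9.15%; 0.12→0.56 over
  condition −1.44→0.57). Centring keeps population survival at `r^d` in
  expectation. Death km is drawn from the implied geometric chain, so the
  generator is exactly the model the rate statistic inverts.
- **Detections.** Survivors are detected at first/last/marine receivers
  with probabilities 0.945 / 0.913 / 0.90 (the study's measured means);
  timestamps follow a constant per-fish lognormal speed (the simplest
  movement model producing the observed marginal speeds — the study
  reports realized speeds, not a movement model). Contaminants — exact
  duplicates, pre-study timestamps, unknown tag codes — are injected at
  5% / 2% / 2% and booked in the ground truth.
- **Discharge.** Lognormal AR(1) daily series (ρ = 0.9), level scaled to
  catchment area.

**What it does not emulate.** Covers are drawn independently of bedrock,
whereas real catchment land cover correlates with geology. A consequence,
combined with the printed coefficients, is that default synthetic per-km
rates span ≈0.01–0.999 where the study observed 0.75–0.996. (The printed
bedrock coefficients and the study's own bedrock marginal means are
mutually inconsistent — intercept gaps of ~6.6 logits versus marginal-mean
gaps under 1.5 — so no cover distribution can reproduce both; the
generator honours the coefficients.) Passing tests on synthetic data
therefore validate the estimators and fitters under the stated model, not
the realism of any particular river's numbers. Other simplifications: no
partial migration or stalling, no receiver outages, detection independent
between receivers, no transport-group structure.

## Problem sizes used in validation

Chosen to make each check sharp while keeping the full suite around a
minute of compute: estimator recovery at 200 replicates × 500 fish
(per-km rate 0.98 over 30 km, detection 0.9/0.9); landscape recovery at 50
replicates × 100 catchments with beta precision φ = 400 ("small noise":
response SD ≈ 0.015 at rate 0.9); the individual GLMM at one 8-river ×
2-year × 4,000-fish fit plus 100 null replicates of 6 × 2 × 600 for the
type-I check; hydrology on 365-day series.

## Known limitations

- With beta responses piled near 1 (shape `(1−μ)φ < 1`, a J-shaped
  density), finite-sample LRTs are anti-conservative: in the default
  extreme-rate landscape regime a pure-noise covariate survives step-down
  ~30–40% of the time. This is a property of the likelihood, not the
  fitter — `glmmTMB` reproduces the same statistics to 4 decimals — and it
  disappears in the mid-range regimes where the selection behaviour is
  validated. Treat step-down results with caution when many rates sit
  within ~0.001 of 1.
- The Laplace approximation can bias variance components at very few
  grouping levels (2–4 years); fixed-effect estimates and LRTs remain
  well calibrated in the simulations here.
- Success and detection-efficiency estimators are minimum estimates by
  design; under the reference conditions the success estimator centres
  ≈0.03 below true survival (survivors missed at the last receiver score
  as failures), within the binomial uncertainty of a single 500-fish
  cohort.
- Residual diagnostics are limited to quantile residuals; no
  cross-validation machinery beyond the `kfold_check` hold-out comparison.
- Only the strict two-receiver design is supported; multi-occasion CJS
  models are out of scope.
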