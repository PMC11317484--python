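# Methods

`aldiet` re-implements, as a reusable and tested toolkit, the analytic
pipeline of a prospective-cohort study linking a data-driven dietary
risk score and alcohol consumption to severe alcohol-related liver
disease (ALD). Because the source cohort (a UK biobank of ~300,000
middle-aged adults) cannot be redistributed, every stage is exercised on
synthetic cohorts whose generating hazard structure is known, so that
estimators can be validated by parameter recovery rather than by
re-analysis of restricted data.

## The synthetic cohort generator

The generator emulates the analysed cohort, not the raw recruitment
population: participants enter free of baseline liver disease and with
complete data unless configured otherwise.

**Dietary items.** Twenty ordinal questionnaire items (vegetables,
fruit, fish, meats, dairy/spread/bread/cereal types, added salt, tea,
coffee) are drawn through a one-factor latent-Gaussian copula: a shared
standard-normal factor with loading sqrt(rho) plus independent noise,
thresholded at each item's marginal level probabilities. The default
latent correlation rho = 0.15 yields achieved pairwise ordinal
correlations of at most ~0.14, consistent with the "modestly correlated
(r < 0.3)" structure of the real questionnaire. An exchangeable
single-factor copula is the simplest mechanism that achieves controlled
modest correlation; it does not attempt to model genuine dietary
co-consumption patterns (e.g. cuisine clusters), so tests passing under
it say nothing about selection behaviour under strongly blocked
correlation structures.

**The diet score.** The packaged score uses four items — processed
meat (+0.152/level), beef (+0.127/level), cereal intake
(−0.177/level, protective), added salt (+0.152/level). These
coefficients are the generator's own synthetic truth (the source
study's fitted coefficients were never published numerically). They
were calibrated once, by moment matching on a 200,000-row cohort, so
that the continuous score reproduces the published distribution:
mean 0.14, SD 0.34, and a near-exact 50/50 median split. The score
median under this discrete item coding is ~0.13 rather than the
published 0.079; with the exact item coding unpublished, the mean/SD
pair and the skew direction (mean > median) were prioritised.

**Alcohol.** Weekly units follow a sex-specific zero-inflated
log-normal (women: 12% never, log-mean 2.15, log-SD 0.95; men: 5%,
2.75, 0.85). These four parameters were set from the published margins
and reproduce: mean consumption 16.4 units/week (published 16.4),
risk-band prevalences ~61/32/7% (published 58.3/34.5/7.2), and ~8.6%
never-drinkers (published 8.0). Drinking-frequency categories are
assigned from noisy log-units through fixed cut points so volume and
frequency correlate, as in the real questionnaire.

**Covariates.** Age N(56.4, 8.1) truncated to 37–73, 52.6% women,
Townsend-like deprivation N(−1.44, 3.0), 94.9% white ethnicity,
smoking 55/35/10%, six activity categories, and raw metabolic measures
(waist, fasting glucose, blood pressures, triglycerides, HDL) with
distributions chosen so the five derived metabolic-syndrome flags have
prevalences near the published Table-1 margins. Covariates are
independent of the exposures by default; confounding is not simulated.

**Outcomes.** Failure times are inverse-transform draws from a
proportional-hazards model with constant baseline hazard (exponential;
Weibull optional via a shape parameter — the Cox analyses downstream
are baseline-hazard-agnostic, which is why exponential is the default).
Administrative censoring is uniform on 10.0–11.4 years, mirroring the
published follow-up IQR; no loss-to-follow-up process is modelled. The
true log-hazard is configurable as (a) null, (b) cell offsets on the
joint diet-by-alcohol categories (diet dichotomised at the realised
score median; alcohol binarised at >14 units, at the sex-specific
higher-risk band, or kept 3-level), or (c) linear in the continuous
score and weekly units with a product term. `calibrate_baseline_rate`
bisects the baseline hazard against an analytic conditional event
fraction, `mean(1 − exp(−rate · e^lp · C))`, which is monotone in the
rate; calibrating to the published 0.2% incidence at n = 303,269
reproduces ~539 events.

Missingness, when enabled, is injected completely at random per field;
the source analysis was complete-case, so MCAR suffices to exercise the
exclusion filter. One root seed feeds a single sequential generator, so
identical configurations give byte-identical cohort CSVs.

## Survival engine

The Cox partial likelihood is maximised by Newton–Raphson with
step-halving (ascent is therefore monotone by construction), Efron's
tie correction by default and Breslow retained for oracle
cross-checks; the two coincide exactly without ties. Convergence:
max |score| < 1e-8 or relative log-likelihood change < 1e-10, max 100
iterations (the source study states neither its tie handling nor
tolerances; these are declared package defaults). The covariance is
the inverse observed information at the optimum; all intervals are
Wald on the log-HR scale. The fitter accepts an optional quadratic
penalty matrix, which is how the P-spline smooth reuses the same
Newton machinery. Rank-deficient designs are rejected up front with
the offending columns named (pivoted-QR detection).

Proportional hazards are checked with scaled Schoenfeld residuals
(Grambsch–Therneau scaling) correlated against follow-up time, with a
t-distribution p-value. Discrimination uses Harrell's C with the
standard conventions: pairs are comparable when the shorter follow-up
ended in an event, risk ties count 0.5.

## Penalised item selection

The L1 path solver is cyclic coordinate descent with soft-thresholding
on the iteratively reweighted quadratic approximation to the partial
likelihood (Breslow risk sets for the working derivatives, as in
coxnet), warm-started down a 100-point log grid from lambda_max
(the KKT boundary, computed from the null-model score) to 0.001 of it.
Items are standardised internally so the penalty is fair across
ordinal ranges; coefficients are reported on the original scale. On a
pre-standardised design the path agrees with an independent coxnet
solver to ~1e-5, and the terminal (lambda = 0) solution matches the
unpenalised fitter to 1e-4.

Cross-validation is 10-fold, event-stratified (at 0.2% incidence
unstratified folds would frequently contain no events), with the
Verweij & van Houwelingen partial-likelihood deviance as the selection
loss and the held-out Harrell C-index reported alongside. **Selection
rule.** Both the deviance-minimising penalty and the one-SE penalty are
always computed; the packaged selection rule is the one-SE rule. This
was a deliberate design decision: in pilot simulations with four truly
informative items among twenty, the CV-minimum rule recovered the exact
true set essentially never (it systematically drags in noise items —
the well-known overselection behaviour of CV-tuned lasso), while the
one-SE rule recovered it in ~90%+ of replicates. When selection is
empty (weak signal) the pipeline falls back to the four largest
near-unpenalised coefficients, and widens in the same way if a sparse
selection makes the median split degenerate.

## Exposure derivation

Alcohol risk bands follow UK guidance exactly as worded: lower risk
<= 14 units/week for both sexes, increasing 15–34 (women) / 15–49
(men), higher >= 35 (women) / >= 50 (men). The worded bands are
integers; fractional totals in (14, 15) resolve as lower <= 14 <
increasing, preserving the "<=14" lower bound literally. Metabolic
flags are bit-exact to their quoted inequalities (waist strictly >
88/102 cm; glucose >= 5.6 mmol/l; SBP >= 130 and/or DBP >= 85 mmHg;
TG >= 1.7; HDL < 1.3/1.0 mmol/l), with physician diagnoses overriding
measurements for diabetes and hypertension, and missing measurements
propagating as missing flags unless a diagnosis or a single high
reading decides the flag.

Exclusions apply in a fixed order — baseline condition flag, missing
diet items, missing covariates, then the 2-year landmark rule — and the
log partitions removed rows exactly. The landmark rule removes only
participants whose *event* occurred within 2 years; early-censored
participants are retained. Descriptives report mean (SD) and n (%) per
joint group; Cohen's d contrasts alcohol units between diet-score
groups, and the Phi coefficient is computed on the 2x2 diet-group by
drinking-frequency table with the frequency band dichotomised at three
or more times per week (the source text does not state its table
construction; this is a declared convention).

## Interaction and attributable fractions

For a 2x2 joint exposure with doubly-unexposed reference, the additive
interaction is RERI = HR11 − HR10 − HR01 + 1 and the multiplicative
ratio is HR11 / (HR10 · HR01). The RERI CI uses the multivariate delta
method with gradient (−e^b10, −e^b01, e^b11) against the 3x3 dummy
covariance block; a percentile bootstrap of coefficients is available
as a method switch, and the two agree closely at moderate information.
The multiplicative CI is a linear contrast on the log scale. Both the
2x2 (alcohol binarised at >14 units) and the 3-level-cell
parameterisations are supported, because the published overall RERI is
consistent with either to within rounding. A continuous-by-continuous
variant evaluates RERI at a stated contrast (score units x weekly
units/7) from a model with a product term.

Attributable fractions default to Levin's formula over exposure
categories, PAF = sum p_c (HR_c − 1) / (1 + sum p_c (HR_c − 1)), with a
case-weighted alternative sum (cases_c/cases)(HR_c − 1)/HR_c when case
counts are supplied; CIs resample coefficients from the fit covariance
(10,000 draws, percentile). Note that applying Levin's formula to the
published prevalences and HRs yields 60.4% (alcohol) and 22.9% (diet),
not the published 67.1% / 28.8%; the published estimator is not stated
precisely enough to reproduce, so no published-PAF figure is treated as
a recovery target.

## Penalised-spline dose-response

The diet score enters through a uniform cubic B-spline basis (10 basis
functions; equally spaced knots extended three segments beyond the
range) on the empirical [5th, 95th] percentile range, with a
second-order difference penalty on adjacent coefficients. Uniform
rather than clamped knots matter: only with equally spaced knots does
the difference penalty vanish exactly on linear functions, so the fit
shrinks to log-linearity as the penalty grows. Because the partial
likelihood absorbs constants, the first basis column is dropped (the
basis is a partition of unity, so the span less constants is
unchanged). The penalty weight is chosen by AIC with effective degrees
of freedom tr((H + lambda P)^-1 H) over 30 log-spaced weights,
warm-started from heavy smoothing. Curves report HR(x) =
exp(s(x) − s(ref)) with pointwise delta-method bands; the reference
defaults to the lower truncation bound ("the lowest value of the
score"), taken as the post-truncation minimum. Stratified fits (alcohol
<= vs > 14 units/week) share a common truncated range; strata with
fewer than 10 events are returned flagged low-power. A
likelihood-ratio comparison against a linear term on the same
truncated score assesses nonlinearity, with df = effective df − 1.

## Pipeline

`run_pipeline` executes simulate → derive → select-score → score → fit
→ interact → paf → spline → render, persisting an exclusion log, the
score model, the lasso path, Cox summaries (with Schoenfeld p-values
and C-index), interaction and PAF results, spline curves, Tables 1–3
style TSVs, and a manifest (package version, seed, config hash
excluding the output path). Categorical covariates are reference-coded
(woman / never-smoker / white / walking / never-drinks); missing data
are handled complete-case; significance is two-sided 0.05 with no
multiplicity adjustment, mirroring the source analysis. Stage failures
abort with the stage name recorded in the manifest.

## Validation studies and problem sizes

The recovery studies in `aldiet.studies` fix the generating truth at
the published joint-cell hazard ratios and re-estimate across
replicates. Their problem sizes are package choices balancing
Monte-Carlo precision against desk-scale runtimes: RERI and joint-HR
recovery use 100 replicates of n = 50,000 with the baseline hazard
calibrated to ~1.5% events (inflated from the emulated 0.2% so each
cell carries enough events for stable estimates); selection
consistency uses 50 replicates of n = 4,000 at ~8% events with the
hazard log-linear in the default score scaled so the four true items
carry per-level log-hazards of ~0.57–0.80 (the asymptotic strong-signal
regime in which exact support recovery is expected to be routine); spline recovery uses 20
replicates of n = 20,000 under hazard doubling per 0.6 score units.
Replicate studies skip the baseline/landmark filters since the
generating process contains no reverse causation.

## Known limitations

- Item correlations are exchangeable; no blocked or negative dietary
  correlation structure.
- Covariates are independent of exposures, so adjusted and unadjusted
  recovery coincide up to noise; confounding behaviour is untested.
- No delayed entry, stratified baselines, time-varying covariates or
  competing risks.
- The score median under the synthetic item coding differs from the
  published median (0.13 vs 0.079); only mean/SD/split are calibrated.
- PAF interval estimation treats prevalences as fixed, resampling only
  the hazard-ratio coefficients.
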