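# Methods

`bmiyears` implements a life-course analysis of cumulative excess-bodyweight
exposure and cognitive function across three birth cohorts, as a tested,
reusable pipeline. The real cohort data such an analysis targets are
access-restricted; everything here therefore runs against a synthetic-data
generator with known structural truth, which makes every stage falsifiable
by parameter-recovery and calibration tests.

## Exposure metrics

Each person's serial BMI (nominal ages 10, 16, 23, 33, 42, 50 y) defines a
piecewise-linear trajectory. Within the analysis window (default 10–40 y,
intersected with the observed span — no extrapolation beyond the first or
last measurement, since extrapolated exposure would be fabricated) we
compute, for a threshold `c` (default 25 kg/m², the conventional
excess-bodyweight cut-off, applied at all ages; an age-specific schedule can
be passed instead):

- **onset age** — earliest `t` with `BMI(t) > c`, crossing times solved
  exactly on each linear segment: `t* = t0 + (c − b0)/(b1 − b0) (t1 − t0)`;
- **duration** (years) — total length of the sub-intervals above `c`;
- **cumulative severity** (BMI-years) — the exact integral
  `∫ max(BMI(t) − c, 0) dt`, summed triangle/trapezoid areas.

Exposure is defined by the strict inequality `BMI > c`; a trajectory
touching the threshold exactly contributes zero duration (a measure-zero
choice fixed for determinism). A fine-grid trapezoid oracle (`Δt = 0.001 y`)
written independently of the exact code validates both quantities on random
trajectories. For regression, duration is scaled per decade and severity to
unit sample SD; age-specific BMI z-scores use within-(age, cohort) strata
with the n−1 SD denominator (stated so z-scores are bit-reproducible), and
change exposures are the residuals of later-age BMI regressed on the
previous age.

When imputation is used, exposure metrics are recomputed passively inside
each completed dataset, keeping the imputation and analysis models
congenial.

## Latent cognition

Each four-test battery (childhood: verbal/non-verbal reasoning, maths,
reading; midlife: immediate/delayed recall, animal naming, letter-search
speed) is summarised by a one-factor model `x_j = λ_j g + e_j` with
`Var(g) = 1`, fitted by maximum likelihood on internally standardised
indicators (the tests sit on incommensurable score scales). Uniquenesses are
log-parametrised; a uniqueness collapsing toward zero raises a Heywood
error naming the indicator. Factor scores use the regression (Thomson)
method, `E[g | x_o] = λ_o' Σ_oo^{-1} x_o`, which is well defined when some
of a person's indicators are missing — the reason it is preferred over
Bartlett scores here. Factors are fitted per cohort and the pooled scores
re-standardised, mirroring a harmonised-instruments design. Tertiles of the
childhood score use empirical 1/3 and 2/3 cut-points (within cohort on
request); values exactly at a cut-point fall to the lower tertile.

With generating loadings (0.8, 0.7, 0.6, 0.5) the score–factor correlation
has a theoretical ceiling of `sqrt(s/(1+s))` with `s = Σ λ_j²/ψ_j = 3.63`,
i.e. ≈ 0.886; tests of score fidelity must be read against that ceiling,
not against 1.

## Multiple imputation

Chained equations visit incomplete variables in increasing-missingness
order: continuous variables by predictive mean matching (k = 5 donors, with
a posterior draw of the regression parameters), binary by logistic draw,
ordinal by proportional-odds draw; perfect separation falls back to donor
sampling with a logged warning. The predictor set defaults to all other
analysis variables plus indicator-coded cohort, congenial with the analysis
models. `m` defaults to 50 (the convention of sizing m as FMI × 100);
analyses and tests here run m = 5–10 for desk-scale turnaround, which is a
runtime choice, not a statistical one. Estimates pool by Rubin's rules
(total variance = within + (1 + 1/m) × between) with Barnard–Rubin
small-sample degrees of freedom and reported FMI.

## Regression program

Four exposure families (age-specific BMI z, residualised change, duration
per decade, severity per SD) each meet three nested adjustment sets:
model 1 = age at midlife assessment + sex; model 2 = + childhood cognition
(factor score); model 3 = + mother's and father's BMI, birthweight,
household overcrowding, SES, and education (indicator-coded, since
linearity over its four categories is not assumed). Pooled fits add cohort
indicators. Attenuation of an exposure coefficient across models 1→3 is the
fingerprint of confounding by early-life factors. The tertile-trajectory
analysis regresses each age's BMI z on childhood-cognition tertiles plus
covariates and plots adjusted predicted means per tertile — flat lines in a
null world, diverging fans when cognition predicts adult weight gain.

## Cross-lagged SEM with FIML

The structural model is declarative (YAML-loadable): two latent g factors
with their indicator blocks; observed structural nodes (childhood BMI z,
education, cumulative exposure, midlife BMI z); directed paths constrained
to a temporal ordering (childhood → education → exposure → midlife);
sex/overcrowding/SES entering every endogenous equation; and free residual
covariances (childhood cognition ↔ childhood BMI). The default edge set
includes all forward paths among the structural nodes; since the model is
declarative, alternative inventories (e.g. dropping midlife BMI as a node)
are run by editing the model file rather than the code.

Internally the spec compiles to a RAM parameterisation
`Σ = F(I−A)^{-1} S (I−A)^{-T} F'`. With missing data the estimator is
full-information maximum likelihood: cases grouped by missingness pattern,
each contributing the Gaussian log-likelihood of its observed sub-vector
(valid under MAR). Pattern sufficient statistics are cached and the
pattern loop batched by observed-set size, so a fit at n ≈ 10⁴ with ~10³
distinct patterns takes seconds. Gradients are analytic: the per-pattern
derivatives accumulate into a single matrix pair (G, g) on the observed
moment space, and the chain rule to all free parameters reduces to a
handful of matrix products. Optimisation is quasi-Newton (L-BFGS-B, bound
constraints keeping residual variances positive) to a projected-gradient
norm below 1e−5 on the per-case deviance scale; non-convergence raises
with the optimiser trace rather than returning estimates. Standard errors
come from the observed information matrix (central finite differences of
the analytic gradient).

Identification fixes the first loading of each latent to 1 — rather than
fixing latent variances to 1 — because the midlife factor is endogenous and
its total variance is a derived quantity; the fully standardised solution
(what gets reported) is identical under either convention. Observed columns
are divided by their observed SDs before fitting, a pure reparameterisation
that conditions the optimisation across indicators whose raw scales differ
by two orders of magnitude; standardised output is invariant to it, and a
flag disables it when raw-metric estimates are wanted.

Standardised coefficients multiply each path by implied SD(from)/SD(to);
their SEs, and the SEs of product-of-paths indirect effects, use the delta
method on the parameter covariance (bootstrap SEs are out of scope).
Ordinal covariates enter the Gaussian SEM numerically; categorical-indicator
estimation is a non-goal.

Fit indices need the saturated and independence reference models under the
same estimator: the saturated (μ, Σ) fit uses an EM algorithm over the same
pattern statistics; the independence model separates per variable and has a
closed form. Then `χ² = 2(ℓ_sat − ℓ_model)`,
`RMSEA = sqrt(max((χ²−df)/(df(n−1)), 0))`,
`CFI = 1 − max(χ²−df,0)/max(χ²_b−df_b, χ²−df, 0)`,
`TLI = ((χ²_b/df_b) − (χ²/df))/((χ²_b/df_b) − 1)`, with the conventional
good-fit read-outs RMSEA < 0.1, CFI > 0.9, TLI > 0.9.

## Synthetic data generator

Two generators with one seed discipline (a master `SeedSequence` spawning
named per-stage substreams, so any stage reproduces in isolation):

**Full cohort emulation** (`generate_cohorts`): three cohorts with an
additive upward shift of the mean BMI curve for later cohorts (default 0,
+0.7, +1.4 kg/m², giving the later cohorts earlier onset and more severe
cumulative exposure); person-level growth curves (random intercept loaded
on parental BMI and SES, random slope, occasion noise); ordinal SES,
overcrowding and education cut from latent normals at fixed population
quantiles; cognitive batteries as loadings × factor + unique noise rescaled
to instrument-like units; and a structural chain in which childhood
cognition affects adult BMI (ages ≥ 23) through achieved education plus a
small direct path. The default world has **zero** direct exposure→cognition
effect: associations between exposure metrics and midlife cognition arise
entirely from confounding by childhood cognition, education and family
background, which is exactly the structure the nested-adjustment analyses
are designed to expose. Cumulative exposure used in the cognition equation
is computed from the generated trajectories on the analysis scale, so any
configured exposure effect acts through the same metric the analysis
measures. Missingness is MAR by construction — per-variable rates (chosen
to resemble observed-n gradients of long-running cohorts: adolescent BMI
most incomplete at 30%, adult BMI 8–15%, childhood tests 13%, parents' BMI
12–20%, midlife tests complete by inclusion) with logistic dependence on
always-observed cohort, sex and SES only, intercepts solved so realised
proportions match the configured rates. MNAR mechanisms are deliberately
out of scope: MICE and FIML are valid under MAR, and stress-testing their
failure modes is a different study.

**Linear cross-lagged system** (`generate_sem_dataset`): the SEM's own
structural equations on standardised scales, residual variances derived
analytically so every variable has unit variance — the generating
coefficients are then exactly the standardised paths a correctly specified
fit should recover. Default truth: childhood-cognition → adult-weight
cross-lag −0.10 with strong weight tracking (0.35) and education mediation,
and **zero** reverse (weight → cognition) lags, the asymmetric structure a
cross-lagged model exists to separate. Optional MCAR masking at a given
cell rate.

What the generators do **not** emulate: the score distributions of real
instruments, attrition-by-education selection, measurement non-invariance
across cohorts, and MNAR missingness. Passing tests therefore demonstrate
the estimators' correctness and calibration under the assumptions the
methods themselves make, not robustness to their violation on real data.

## Problem sizes and numerical choices

Validation studies run at the sizes the package's own tests use: exposure
oracle on 1000 random trajectories; factor recovery at n = 2000; FIML
recovery and CI coverage over 50 replicates at n = 6000 with 20% MCAR on
the cross-lagged core model (the covariate block is exercised in the
pipeline SEM); fit-index regime over 20 replicates at n = 6000; imputation
bias over 5 replicates at n ≈ 5000, 30% MAR, m = 10; the end-to-end
pipeline at n = 1000 per cohort with m = 5 and 5 MICE cycles. Convergence
tolerances: factor fits to gradient norm < 1e−6; FIML to projected gradient
< 1e−5 (per-case deviance scale); EM for the saturated model to relative
log-likelihood change < 1e−8. Ties at tertile cut-points go to the lower
tertile; zero-variance strata, rank-deficient designs, Heywood cases and
non-identified model files raise errors naming the offending element rather
than warning.

## Known limitations

- FIML treats ordinal covariates and education as numeric; polychoric /
  weighted-least-squares estimation is not implemented.
- Delta-method SEs for indirect effects are symmetric and can undercover
  for small products near zero; bootstrap is not implemented.
- The saturated-model EM can be slow if the missingness-pattern count
  approaches the case count (extremely fragmented data).
- Cohorts are fitted separately in the SEM stage; multi-group SEM with
  cross-cohort equality constraints is out of scope.
- The trajectory model is strictly piecewise-linear between observed
  points; no growth-curve smoothing is applied, and whether paediatric
  overweight cut-offs should replace the adult threshold at ages 10–16 is
  exposed as configuration rather than assumed.
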