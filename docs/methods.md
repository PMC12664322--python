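# Methods

## The models

`budwormflight` implements the statistical analysis of tethered
flight-mill experiments on spruce budworm (*Choristoneura fumiferana*)
females tested once, over a 19-h night, at one of six chamber
temperatures (10-35 °C). Ten per-female responses are modelled, each as a
bespoke nonlinear mean function with a deviate family chosen among

* additive normal errors, `y = mu + eps`, `eps ~ N(0, sigma2_eps)`;
* mean-one multiplicative lognormal deviates, `y = mu * delta`, where
  `log delta ~ N(-sigma2/2, sigma2)` so `E[delta] = 1`;
* mean-one multiplicative Weibull deviates, `y = mu * xi`,
  `xi ~ Weibull(kappa, lambda)` with the scale tied to the shape,
  `lambda = 1 / Gamma(1 + 1/kappa)`, so `E[xi] = 1`.  `kappa = 1` is the
  exponential case and is used with the shape held fixed for flight
  duration.

The flight-performance means are a logistic (propensity, Bernoulli
likelihood), linear predictors in a pre-fitted temperature term
(`1/T^2` for onset, saturating `T/(T0+T)` for wingbeat, quadratic
`(T-T0)^2` for speed/duration/distance) plus morphological covariates
(forewing length `La`, total four-wing area `Stot`, wing load
`omega_tot`, flight muscle ratio `tau_t`) and barometric pressure `Ap`.
The cost means (mass loss, water loss, fuel use, remaining lipids) are
power laws `p1 * T^a * Wb^b * La^c ...`, with flown distance entering as
`D' = ln(D + e)` so that `D' = 1` for a non-flyer.  The optimum `T0` is a
free parameter of the final fits, initialized from the temperature-term
pre-fit.  Flight onset is modelled on its Box-Cox scale
(`psi' = (psi^0.09 - 1)/0.09`), the one response whose published final
model is written on the transformed variable; all other final fits use
the raw response.

## Estimation and model selection

Maximum likelihood is by multi-start Nelder-Mead (five jittered starts)
followed by a BFGS polish.  Shape parameters and power-law leading
coefficients are optimized on the log scale to enforce positivity; a
non-positive predicted mean under a multiplicative family makes the
objective infinite (infeasible) rather than being clipped, while
negative predicted means at *evaluation* time (temperature curves,
confidence bands) are truncated to zero and counted.  Standard errors
come from the inverse numerical Hessian of the negative log-likelihood
at the optimum (via `statsmodels.tools.numdiff`); they are withheld when
the Hessian is not positive definite.  Starting values are closed-form:
ordinary or log-scale least squares for the mean parameters, a few IRLS
steps for the logistic model, and method-of-moments (CV inversion
through the Gamma function) for the Weibull shape.

Candidate predictors are screened per response by a LASSO path on
internally standardized predictors (geometric grid of 100 penalties from
`lambda_max` down to `1e-4 lambda_max`; gaussian path via scikit-learn
coordinate descent, binomial via penalized logistic regression).  Only
the order of first entry matters downstream; a minimum-AICc stopping
point along the path is reported for completeness since the original
software's stopping rule is not documented.  Models are then built
incrementally: starting from the intercept-plus-shape null model, terms
are added one at a time in entry order, each step's AICc and support
`exp(-0.5 * delta_AICc)` are recorded, single-term removals from the full
model are attempted, and the minimum-AICc model wins (ties within 1e-6
resolved toward the smaller model).  The deviate family is chosen by
fitting each candidate family and keeping the one whose fitted deviates
maximize the Pearson correlation between observed (plotting positions
`(i - 0.5)/n`) and expected cumulative frequencies.  In practice this
criterion separates strongly skewed deviates (kappa near 1) from normal
ones essentially always, but discriminates weakly when the Weibull shape
exceeds ~2.5 and the distribution is nearly symmetric; the package
always reports all three correlations rather than just the winner.

Box-Cox exponents for the screening stage are chosen on a grid
(-2 to 2, step 0.01) by maximizing the Anderson-Darling normality
p-value (A^2 with the small-sample correction; p-values from the
standard approximation for the composite case with estimated mean and
variance).

## Water/fuel budget

The dry-fraction regression `Pd = (p1 + p2 T + p3 D' + p4 Wa) * delta`
(with `D' = ln(D+1)` for this regression only) is fitted by ML with
mean-one lognormal deviates; each female keeps her deviate
`delta_i = Pd_i / mean_i`.  Her initial dry fraction is back-calculated
at `T = 0`, `D = 0` as `Pi = delta_i (p1 + p4 Wa)`, water loss is
`Wwater = Wa (Pd - Pi)` clamped to 0.05 mg when non-positive (count
logged), and fuel use is the remainder `Wfuel = Wb - Wa - Wwater`,
negatives retained but flagged.  The fitted coefficients, not hard-coded
constants, are used throughout; the published intercept 0.3 and `Wa`
slope 0.009 serve as test targets.  For LASSO screening only, fuel
masses are offset by +0.18 mg and the cost responses use their Box-Cox
exponents (0.54, 0.51, 0.55).

## Uncertainty

95% regression bands use the Monte-Carlo likelihood-ratio method:
parameter vectors are drawn as independent normals around the estimates
scaled by their standard errors (no covariance is published, so
independence is an explicit limitation), draws whose likelihood-ratio
chi-square (df = number of varied parameters, including the shape) is
non-significant are kept, and the pointwise min/max envelope of the
accepted mean curves forms the band.  Replicates increase adaptively
(1000 up to 10,000) until about 100 accepted draws are collected.
Effect displays express observations relative to the prediction with the
focal predictor at its mean, averaged in 14 equal-width classes of the
focal predictor (15 when n >= 300).

## Synthetic data

The generator emulates the study design: 60 females per temperature
treatment by default (the experiment retained at least 54), morphology
drawn multivariate-lognormal with pairwise log-scale correlations 0.883
(mass-forewing), 0.922 (mass-area) and 0.964 (forewing-area) taken from
the published r^2 values, total wing area linear in forewing area
(slope 3.763, intercept 2.647) plus small measurement noise, a truncated
normal flight muscle ratio, and barometric pressure shared within test
days.  Covariate means and SDs are not published (they live in an
appendix table outside the main text), so the defaults are the package's
own assumptions: median initial mass 36 mg (log-SD 0.30), forewing
9.5 mm (log-SD 0.09), total wing area ~103 mm^2, muscle ratio 0.05,
pressure 101.3-102 kPa.  They were chosen once so that plug-in
predictions at the means land near the reported averages where those are
checkable (~40 Hz wingbeat at 25 °C, ~4.8 km mean distance and >90%
propensity near the optimum, ~0.5 mg water loss, lipids ~8.6% of initial
mass) and so that the implied estimate uncertainties are near the
published standard errors.

Outcomes are drawn from the ten equations at their published estimates
with the published deviate families.  Two coherence modes exist:
`independent` draws every outcome from its own equation (the right
choice for per-equation parameter recovery), while `coherent` derives
distance as speed x duration and builds the costs through the
dry-fraction mechanism -- a mean-one lognormal `delta_i` scales the
linear dry-fraction model (the unpublished temperature and distance
coefficients default to 0.0008 /°C and -0.003, labelled assumptions), so
that `Wa = Wb - Wloss`, `Wd = Pd Wa` and `Wwater + Wfuel = Wb - Wa` hold
exactly and the decomposition pipeline can be checked end to end.

Two discrepancies of the published equations surface in simulation and
are deliberately left visible rather than patched.  First, the duration
equation with its published coefficients predicts means of roughly 0.2-1
h (not ~3.5 h) at any plausible covariate means with pressure near
101-102 kPa, and goes negative below ~15 °C; simulated females whose
duration or distance mean is non-positive are recorded as non-flyers
with a `mean_truncated` flag, which depresses cold-temperature flight
fractions below the published propensity curve.  Second, because wing
area and mass are strongly correlated (r = 0.92), their opposing
propensity effects largely cancel in simulation, so the simulated
advantage of the full propensity model over the temperature-only model
is far smaller than the enormous published likelihood ratio; the tests
assert the ordering, not the published magnitude.  What passing tests
show is therefore that the *procedures* (ML fitting, AICc building,
family choice, budget decomposition, bands) recover known generating
structure at study-like sample sizes -- not that the synthetic data
reproduce every marginal feature of the real dataset.

## Problem sizes and numerical choices

Parameter-recovery checks refit each equation on simulated datasets at
the published sample sizes (282 for speed, 219 for mass loss, 214 for
fuel use, 216 for lipids), averaging over 80 seeded replicates in the
acceptance script (30-80 in the test suite); these sizes keep each full
run in the tens of seconds on one core.  The thermal-optimum estimator
of the speed model is right-skewed at this sample size (weak-curvature
replicates inflate it), so replicate means, not single fits, are
reported.  Mill logs treat flight duration as the cumulative count of
seconds containing at least one rotation (the original reduction
program is undocumented); a `span` rule (first-to-last rotation) is
available as a config switch.  The metres-per-rotation of the mill arm
is nowhere published and is therefore a required configuration parameter
with no default.  AICc ties are resolved toward the smaller model; the
Box-Cox grid step (0.01) matches the precision of the published
exponents.

## Known limitations

* Parameter draws for the confidence bands ignore estimate covariances.
* The back-calculated initial dry fractions near 0.6 are hard to
  reconcile with the published mean initial water content (~22.7 mg on a
  ~36 mg female); the package follows the published procedure as stated
  and flags, but retains, out-of-range values.
* The cumulative-frequency correlation criterion has little power to
  distinguish near-symmetric Weibull deviates from normal ones.
* Onset times implied by the published onset model are of the order of
  minutes, much shorter than the reported cold-temperature delays; the
  model is implemented exactly as published.
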