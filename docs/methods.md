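# Methods

`gcjoint` implements a shared-parameter joint model of longitudinal fecal
glucocorticoid (fGC) concentrations and adult survival for wild female
baboons, together with a synthetic-data generator that reproduces the
statistical structure of the study design. This note records the model, the
estimation machinery, the generator's stated world, and the design choices
made where the design was genuinely open.

## 1. The model

### Longitudinal submodel

Log fGC for female *i* at age *t* follows a linear mixed model

    y_i(t) = m_i(t) + eps_i(t) = X_i(t) beta + b0_i + b1_i t + eps_i(t),
    eps ~ N(0, sigma2),  (b0_i, b1_i) ~ N(0, Sigma_b)

The fixed effects are: intercept; age in years (unstandardized, so the
random slope has per-year units); reproductive state (pregnant / lactating
vs cycling, with the day of parturition plus the next three days recoded
pregnant); wet season (November–May) vs dry (June–October); alpha-female
indicator; and z-scored continuous covariates — 3-month rainfall anomaly,
30-day mean maximum temperature, adult group size and its square (scored
after squaring, with its own constants), proportional dominance rank, and
the two storage covariates (days to methanol extraction, days from
extraction to assay). The z-scoring constants are stored in the design and
reused verbatim at prediction time, so predictions are identical whether
covariates enter raw-with-constants or pre-scaled.

### Survival submodel

All-cause mortality follows a parametric proportional-hazards model with
left truncation at adult entry:

    h_i(t) = h0(t) exp( gamma' w_i(t) + f(alpha, M_i(t)) )

`log h0` is a cubic B-spline with two internal knots; the knot count is
part of the model specification, and their placement — the 33rd/67th
percentiles of observed death ages — is this package's design choice. The exogenous covariates `w_i(t)` —
bond strength with females (DSI_F), bond strength with males (DSI_M), and
the annual rainfall anomaly — are piecewise constant over 1-year steps
aligned to individual birthdays and are z-scored at assembly.

### Association structures

`f(alpha, M_i(t))` is one of: current value `alpha * m_i(t)`; current slope
`alpha * m_i'(t)`; cumulative exposure (area under the curve)
`alpha * integral of m_i(u) du`; or absent (null model).

The AUC integral runs from the **fixed adulthood age of 5 years** for every
female, not from her individual (staggered) entry age. If each female's own
entry age were the lower limit, the feature would be dominated by
`mean(m) * (t - entry_i)`, a function of when observation happened to begin
rather than of glucocorticoid exposure; the baseline hazard cannot absorb
an entry-indexed term, and in simulation the association coefficient then
collapses to zero. For females first observed after age 5 the linear
individual trajectory (with the first observed year's covariates) is
extrapolated back to age 5.

## 2. Estimation: MAP + Laplace

No Hamiltonian Monte Carlo backend is available in the target environment,
so `fit_joint` uses the estimation fallback designed into the package from
the start:

1. **Two-stage warm start.** The mixed submodel is fitted alone by
   profiled maximum likelihood (the 4 variance parameters are optimized on
   an unconstrained scale with beta profiled out by GLS, using the 2x2
   Woodbury identity per female); then gamma, alpha and the baseline
   coefficients are optimized with the longitudinal block held fixed.
2. **Laplace-marginal MAP.** For any value of the fixed parameters, the
   two random effects of each female are integrated out by a per-female
   Newton/Laplace step. The inner problem is strictly concave (Gaussian
   likelihood + Gaussian prior + a concave survival term), so the Newton
   iteration is safe and is vectorized across females with closed-form 2x2
   solves. The resulting marginal posterior (with log-Jacobians for the
   unconstrained variance parametrization) is maximized by preconditioned
   L-BFGS followed by damped Newton polishing on a central-finite-difference
   Hessian. The polish step matters: prior-dominated spline directions have
   curvature of order 1/25 and forward-difference gradients stall there.
3. **Curvature draws.** Posterior draws are sampled from the Gaussian
   N(theta_MAP, H^-1) on the unconstrained scale, transformed back, and
   arranged into chains so Rhat / ESS / MCSE diagnostics apply (for these
   independent draws Rhat ~ 1 by construction; the diagnostics become
   informative if a genuine sampler is substituted).

Survival integrals use 15-node Gauss–Legendre quadrature per smooth piece,
where pieces are year-of-life segments further split at the spline's
internal knots (the log-baseline is only C2 there). Against closed forms
(constant and Gompertz baselines) and an adaptive-quadrature oracle this is
accurate to better than 1e-8 relative.

This machinery approximates the posterior mode and curvature, not its full
shape: credible intervals are symmetric by construction, and skewness in
weakly identified parameters (e.g. the random-slope SD) is not captured.
Simulation calibration shows 90% intervals for the association coefficient
cover the truth at approximately the nominal rate at the default cohort
size (8/10 value mode, 10/10 AUC mode in the acceptance suite).

### Priors

Weakly informative, response-scaled in the spirit of rstanarm defaults:
`beta ~ N(0, (2.5 sd_y)^2)` (intercept centered at the response mean);
`gamma ~ N(0, 2.5^2)` on z-scored covariates; `alpha ~ N(0, 5^2)`;
random-effect SDs and sigma half-Normal(0, 1); random-effect correlation
uniform. The baseline spline prior separates level and shape: deviations of
the coefficients from their mean are N(0, 5^2), but the mean itself (the
overall log-hazard level) is nearly flat, N(0, 20^2). The level must be
free because the uncentered association `alpha * m(t)` carries the mean of
log fGC (~4.3): the baseline has to absorb `-alpha * mean(m)`, and a tight
prior on the level otherwise shrinks alpha itself (in simulation a true
alpha of 3 was estimated near 1 before this separation).

## 3. The synthetic-data generator

The generator's defaults are the study's stated world: 242 females over a
19.5-year window, adult entry at age >= 5 (35% of females are already adult
when observation starts, with entry ages uniform to 18; the rest enter at
their fifth birthday, staggered uniformly), right censoring at window end,
~6 social groups.

* **Sampling intensity.** Per-female-year fGC sample counts are
  Poisson(7.5) truncated to >= 1 (median 7, range floor 1, matching the
  printed calibration); sample times are uniform within the year (the
  within-year distribution is not stated anywhere; uniform is assumed).
* **Variance budget.** Total log-fGC variance 0.199 = (1/2.24)^2 is
  partitioned by the printed marginal/conditional R2 (0.138 / 0.213) into
  fixed 0.0275, random 0.0149, residual 0.1566. The non-intercept
  coefficient vector is rescaled once per cohort so the realized
  fixed-predictor variance equals 0.0275 on the delivered sample set
  (mortality truncates sampling and would otherwise shrink it ~13%; the
  recalibration takes one or two fixed-seed passes). The random-effect
  covariance is diag(0.0149 - 9e-6 * 190, 0.003^2): slope SD 0.003/yr, with
  the intercept variance set so the summed marginal variance is 0.0149 at a
  reference squared age of 190 yr^2, between the mean age squared (~156)
  and the mean squared age (~230) of the realized design — both the
  "0.0149 at the mean age" description and the empirical budget then hold
  within a few percent.
* **Weather.** Daily rainfall is gamma-distributed on wet days with
  month-specific totals (~350 mm/yr, wet season November–May) and lognormal
  year effects; maximum temperature is a seasonal sinusoid around 29 C.
* **Reproductive states** follow a semi-Markov chain
  cycling -> pregnant (178 d) -> lactating (~365 d) -> cycling, standard
  baboon durations; no infant-death branch.
* **Survival.** The baseline is Gompertz, a = 0.0121, b = 0.12 — chosen so
  the median adult age at death is ~18 years, consistent with the printed
  "5.4 years ~ 25% of life expectancy conditional on adulthood" — because
  its cumulative hazard has a closed form usable as an oracle. Death times
  are drawn by inverse-transform sampling with the same quadrature the
  joint model uses, root-finding on the cumulative hazard. The association
  feature is centered at the cohort-mean trajectory; this is equivalent to
  moving `exp(alpha * mean-path)` into the baseline, keeps the Gompertz
  calibration stable for every association mode and magnitude, and stays
  inside the proportional-hazards model class the spline baseline can fit.
  Default association: cumulative (AUC) with alpha = 0.115, the realistic
  magnitude regime. Exogenous survival effects default to
  gamma = (-0.25, -0.15, -0.10) on (DSI_F, DSI_M, rainfall anomaly / 100 mm),
  reproducing the direction and rough size of the reported social-bond and
  rainfall effects (their exact values are not printed).
* **Behavior.** Grooming counts are Poisson around lognormal dyad
  affinities scaled by observer effort; focal-sample counts are Poisson per
  group-month; agonistic outcomes follow a static latent linear hierarchy
  with a 5% upset probability. DSI values used in the survival generator
  are AR(1) latent paths, not recomputed from the simulated grooming — the
  behavior tables exist to exercise the sociality pipeline, and the
  generator's `w` path is the ground truth for recovery tests.

What a green test does **not** establish: the generator has no demographic
feedback (group sizes ignore simulated deaths), no group fissions, no male
dispersal, static latent dominance, and i.i.d.-in-time covariate noise —
so passing recovery tests demonstrate correctness of the estimation
machinery under the assumed model, not robustness to the many ways real
field data violate it.

## 4. Covariate and sociality construction

* "3 months" of rainfall is a 90-day window ending the day before
  sampling; the long-term mean uses all years of the record including the
  focal year (at a 25-to-43-year record the focal year shifts the mean
  negligibly).
* The dominance-hierarchy algorithm is not named in the source; ranks use
  an inconsistency-minimizing ordering (exhaustive for <= 8 females,
  David's-score seed plus adjacent-swap hill climbing above), verified
  against the exhaustive oracle on small matrices. Proportional rank is the
  fraction of same-group adult females dominated; a single female gets
  rank 1 with a warning; empty months carry the previous month forward.
* Zero-grooming dyads are excluded from the log-log bond-strength
  regression and from top-3 candidacy (log 0 is undefined, and a
  never-observed-grooming pair cannot be a "strongest partner"). The
  regression pools every co-resident adult dyad in the population for the
  year window; observer effort varies across groups, which is what
  identifies the slope. If all efforts are identical the slope is set to 0
  (centered log rates) with a warning.
* Missing DSI values are imputed with the age-class (integer year of life)
  mean; empty classes fall back to the global mean with a warning.

## 5. Dynamic prediction

Hypothetical females maintain a chosen percentile (default 90th/10th) of
log fGC in every age class up to a landmark age t0 = 14, with continuous
covariates at age-specific means and categoricals at reference. One
pseudo-observation per age-class midpoint defines the female (the source
does not state how many observations define its hypothetical females); the
observation noise is the fitted sigma2. Per posterior draw the random
effect is drawn from its exact Gaussian conditional given those
pseudo-observations — no further approximation — and
`S(t | t0) = exp(-(H(t) - H(t0)))` is evaluated on the grid; curves report
the pointwise median and 90% interval across draws. Conditioning on
survival to t0 is built into the ratio form; the random-effect conditional
ignores the survival information in "alive at t0" (a second-order effect
for these hazards). Exogenous survival covariates sit at their
standardized population mean of zero.

## 6. Numerical choices and degenerate inputs

* LMM variance parameters are bounded away from exact singularity
  (sd >= 1e-4 * sd_y) so zero-noise degenerate data keep GLS conditioning;
  with zero residuals the fixed effects still equal the least-squares
  solution to machine precision.
* The fitted mixed model uses ML, not REML; at 242 females the difference
  is negligible and ML composes with the joint posterior.
* Baseline-spline evaluation clips ages to the boundary-knot range, so an
  exit age at the right boundary is well defined.
* Cumulative-hazard evaluation raises with the offending age if the
  integrand overflows; the generator rejects non-finite hazards rather than
  silently censoring.
* `fit_joint` never fails silently: optimizer and curvature problems are
  returned in `failure_flags`.

## 7. Known limitations

Laplace rather than full MCMC (see section 2); single-biomarker,
all-cause mortality only; no competing risks; the current-slope association
is constant within a female (the trajectory is linear in age by
construction), so slope-mode fits on synthetic data identify alpha only
through between-female slope variation; assay measurement-error modelling
is out of scope.
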