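# Methods

## The estimation problem

The package estimates the effect of a dated community-wide event on school
achievement from aggregated results only: one mean score with a standard
error per school × testing domain × grade × year. Because every response
is itself an estimate with *known* sampling variance, the model is a
hierarchical meta-regression — each cell enters with weight `1/(τ² + σ_e²)`
— combined with an interrupted-time-series (ITS) design that contrasts
exposed schools against an unexposed control region sharing the same
socioeconomic profile. The control group absorbs time-varying shocks
common to the region (test changes, policy), so the interruption and
post-event trend coefficients isolate the event.

## Model and likelihood

For cell *i* with centred mean `y_i` and standard error `τ_i`:

    y_i ~ Normal( X_i β + θ_school(i) + θ_cohort(i),  τ_i² + σ_e² )
    θ_school ~ N(0, σ_s²),   θ_cohort ~ N(0, σ_sc²)  (nested in school)

The per-cell residual `θ_e ~ N(0, σ_e²)` is additive Gaussian at
observation level, so it is marginalized exactly into the observation
variance rather than sampled; the likelihood is identical and one latent
vector disappears.

Cohorts group the repeated measurements of the same students:
`cohort_id = year − (grade − 3)`, the calendar year the cohort sat (or
would have sat) Grade 3. Grade 7→9 progressions share an id the same way;
cohorts observed once are still grouped (the random effect then just
carries its prior).

Centring subtracts the regional reference mean for the matching year,
grade and domain. The reference is treated as a known constant — its pool
is far larger than any single cell — so standard errors are unchanged.
This is a documented approximation, not an exactness claim.

### Design matrix

Columns: intercept; the seven ITS terms (`T` from 0 in the first study
year; `I_post = 1` from the event year; `T_post = max(0, year − event_year)`;
moderate/high indicators against the no/low reference); ICSEA, total
enrolments and proportion of girls centred and scaled by sample SDs
(recorded so reports back-transform to natural units); a non-government
sector indicator; grade indicators with Grade 3 as reference. Grade enters
categorically because centring already removes the between-grade mean
structure and no functional form is assumed. ITS terms do not interact
with grade or domain: each domain gets its own model and grades are
pooled. Profiles join on (school, year) with last-observation-carried-
forward for gap years. A rank check rejects collinear designs by column
name; single-group fixture designs can bypass it (`check_rank=False`).

## Priors

* Fixed effects: `N(0, 50²)` — weakly informative on the centred-score
  scale (scores live within ±100 of the regional mean).
* SDs `σ_s, σ_sc, σ_e`: truncated normal `TN(10, 5²)` with support
  `(0, ∞)`. Zero is the natural truncation point for an SD; the location
  of 10 encodes that between-school spread of centred scores in a
  disadvantaged region is of that order. All priors are overridable, and
  each SD prior can instead be *fixed* at a value — fixing it at 0 removes
  the component from the likelihood, which is how the GLS limit and the
  no-cohort-effect sensitivity variant are expressed.

## Sampler

Conditional on the three SDs the model is jointly Gaussian, so MCMC is a
blocked Gibbs sweep with exact conditional draws — no gradients, no step
size, no divergences:

1. `β | rest`: multivariate normal with precision `X'WX + I/50²`
   (Cholesky solve; `W = diag(1/(τ² + σ_e²))`).
2. `θ_school`, `θ_cohort | rest`: independent Gaussian per group
   (bincount-accumulated sums).
3. Interweaving: for each column *j*, an exact 1-D conditional draw along
   the direction `β_j += d`, `θ −= d·x̄_group`. For group-constant columns
   this is the ancillarity–sufficiency interweaving move (the translation
   leaves the likelihood invariant); for columns with within-group
   variation the residual term enters through the deviations and the draw
   is still exact. Without this step the intercept-like effects and
   school-level covariates mix slowly against the school intercepts
   (R-hat ≈ 1.05 at 4×2000); with it R-hat ≤ 1.01 and bulk ESS in the
   hundreds on the default study.
4. `σ_s`, `σ_sc`: slice sampling against the *collapsed* likelihood with
   their own intercepts integrated out (each group contributes a rank-1
   term, so Woodbury gives an O(n) evaluation), followed by an exact
   redraw of the intercepts. Collapsing removes the funnel coupling that
   makes the conditional update mix slowly across hundreds of small
   groups.
5. `σ_e`: slice sampling of the observation-variance inflation
   (O(n) per evaluation).

Because the conditional updates are exact, the centred parameterization
with interweaving is used rather than the non-centred parameterization
that gradient samplers need for funnel geometry; the collapsed SD updates
serve the same purpose exactly.

Defaults: 4 chains × 2000 iterations, first half warmup, per-chain RNG
streams spawned from one seed (`numpy.random.SeedSequence`), so fits are
exactly reproducible. Diagnostics (split R-hat, bulk ESS via arviz) are
attached to every fit; R-hat > 1.01 raises a warning in the report, never
a silent chain drop. Divergence count is reported as 0 by construction.

### Reporting

`summarize` gives posterior mean, SD, percentile 95% CI and the tail
probabilities `P(β<0)`, `P(β>0)` (computed as draw fractions, constrained
to sum to 1). Scaled covariates are reported per natural unit by dividing
draws by the column scale. `predicted_margins` evaluates the linear
predictor per draw with ITS terms for each (year, group), random effects
at 0 and other covariates at reference values — sample means for
continuous columns (0 on the scaled scale) and the modal category
(government sector, Grade 3) for indicators, since no canonical reference
set exists. `effect_to_months` converts a score-point effect to months of
typical learning at 27 points per school year.

## Synthetic-data generator

The generator draws studies from exactly the model above, plus realistic
study structure, and returns the generating truth for recovery testing.
Defaults emulate the motivating study region:

* 69 schools: 34 no/low, 28 moderate, 7 high exposure. School type
  (primary grades {3,5}, secondary {7,9}, one combined school with all
  four) and sector follow the published per-group counts; covariate laws
  match the published medians/IQRs — ICSEA `N(974/962/922, 40²)` by group,
  enrolment lognormals with medians 108/165/204, proportion girls
  `Beta(mean 0.49, concentration 120)`. Yearly profiles jitter mildly
  around per-school anchors.
* Years 2008–2018, event year 2014, five domains, grades {3,5,7,9}.
* Reference means rise linearly from 420 at Grade 3 to 580 at Grade 9,
  flat across years by default.
* Cell sizes: lognormal around enrolments/4, floored at 5 students, so no
  cell has a degenerate SE. The emitted SE is exactly
  `within_school_sd/√n`, and the sampling noise added to the cell mean has
  that same SD — the reported SE is the true sampling SD. The default
  within-school SD of 70 points is the typical student-level spread of
  standardized literacy/numeracy scores; with median cells of ~70 students
  it yields SEs of ~8 points. Published aggregates do not report
  within-school SDs or cell sizes, so these are realistic stand-ins, not
  calibrated values.
* Default truth: trend −0.5/year; moderate pre-offset −2, interruption
  −2, post-trend +0.5; high pre-offset −10, interruption −10, post-trend
  +2; σ_school = σ_cohort = σ_e = 5 — effect magnitudes of the order the
  published study reports. Confounder effects apply to standardized
  covariates anchored at fixed constants so truth is seed-independent.
* Unbalanced panels via a missingness rate (default 0); exposure is a
  label, no spatial simulation; no individual-student records.

What passing recovery tests show — and do not show: the estimator is
correctly specified for, and well calibrated on, data generated by its own
assumed model with realistic sizes and noise. Real aggregated data can
violate those assumptions (non-normal within-school scores in small cells,
non-linear trends, autocorrelated shocks, time-varying school profiles),
and the tests say nothing about robustness to such violations.

## Sensitivity analyses

`run_variant` re-fits with exactly one modification: an alternative SD
prior set (defaults: `TN(0,5²)`, `TN(10,10²)`, diffuse `TN(10,50²)`),
removal of the cohort random effect, or exclusion of named schools
(refusing exclusions that empty an exposure group, which would leave its
coefficients unidentifiable). Variants re-use the base seed so differences
reflect the modification, not Monte-Carlo noise; `compare_variants` lays
the ITS coefficients side by side with sign-agreement flags. Near-zero
coefficients (e.g. a post-trend straddling 0) can legitimately flip sign
across variants; the flags surface this rather than hide it.

## Problem sizes and numerical choices

The default single-domain study has ~1,540 cells, 69 schools and ~900
school-cohorts; a 4×2000 fit takes seconds. The test suite uses 2×1000
fits for recovery replicates (20 replicates) and 2×800 for sensitivity
parity — sizes at which the checks are sharp while the whole suite runs in
about a minute. The acceptance script uses the same sizes. Slice sampling
uses width 2 with stepping-out capped at 64 doublings; SD chains
initialize at `prior_mean × U(0.5, 1.5)` (floored at 0.1) to overdisperse
chain starts for R-hat validity.

## Known limitations

* No random slopes, non-linear long-term trends, or autocorrelation
  structures — deliberately excluded to match the estimator's scope.
* The reference means are taken as known constants; their sampling noise
  is ignored.
* Cells with missing/nonpositive SEs are dropped (logged), never imputed:
  the SE is the meta-analytic weight and imputation would silently distort
  the weighting.
* One model per domain; no joint multi-domain model, no shrinkage priors,
  no model comparison.
* Exposure classification is an input label; deriving it (dispersion
  modelling, GIS) is out of scope.
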